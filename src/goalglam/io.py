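"""File formats, configuration, seeding and the end-to-end pipeline.

Trial tables are plain CSV/TSV (one row per trial) with a companion
long-format fixation table.  Every file written here carries a provenance
header (``# seed=… config_hash=…``) as comment lines that pandas skips on
read.  The pipeline wires the modules together: synthesise datasets, fit
each participant per frame, simulate out-of-sample behaviour and Δe tables,
run the behavioural analyses and the sampling verification, and record a
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import (
    choice_regression,
    delta_e_regression,
    gaze_influence,
    last_fixation_analysis,
    permutation_frame_test,
)
from .core import (
    EXPERIMENT_FRAMES,
    Fixation,
    GlamParams,
    Trial,
    TrialDataset,
)
from .fit import SamplerConfig, fit_participant
from .sampling import verify_propositions
from .simulate import SimulationConfig, delta_e_table, out_of_sample_predict
from .synth import PerceptualDesign, ValueDesign, default_params, generate_dataset

__all__ = [
    "TRIAL_COLUMNS",
    "FIXATION_COLUMNS",
    "RunConfig",
    "read_trials",
    "write_trials",
    "read_params",
    "write_params",
    "run_pipeline",
]

log = logging.getLogger("goalglam")

TRIAL_COLUMNS = [
    "participant_id", "experiment", "frame", "block", "trial_index",
    "r_left", "r_right", "dt_left_ms", "dt_right_ms", "rt_s", "choice",
    "confidence", "gsf",
]
FIXATION_COLUMNS = [
    "participant_id", "trial_index", "fix_index", "side", "onset_ms",
    "duration_ms",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _write_with_header(df: pd.DataFrame, path, meta: dict | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep=_sep(path), index=False)


def write_trials(datasets, trials_path, fixations_path=None, *,
                 seed=None, config_hash=None) -> None:
    """Write trial (and optionally fixation) tables for one or more
    participants, with a provenance header."""
    if isinstance(datasets, TrialDataset):
        datasets = [datasets]
    meta = {}
    if seed is not None:
        meta["seed"] = seed
    if config_hash is not None:
        meta["config_hash"] = config_hash
    trials = pd.concat([ds.to_dataframe() for ds in datasets], ignore_index=True)
    _write_with_header(trials[TRIAL_COLUMNS], trials_path, meta)
    if fixations_path is not None:
        fixs = pd.concat([ds.fixations_dataframe() for ds in datasets],
                         ignore_index=True)
        _write_with_header(fixs, fixations_path, meta)


def read_trials(trials_path, fixations_path=None) -> list:
    """Read trial tables back into :class:`TrialDataset` objects.

    Schema violations (missing columns, negative RT, unknown choice labels,
    non-monotone fixation onsets) raise a validation error naming the
    offending rows.
    """
    df = pd.read_csv(trials_path, sep=_sep(trials_path), comment="#")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{trials_path}: missing required columns {missing}")
    errors = []
    for i, row in df.iterrows():
        if not row["rt_s"] > 0:
            errors.append(f"row {i}: rt_s must be > 0, got {row['rt_s']}")
        if row["choice"] not in ("left", "right"):
            errors.append(f"row {i}: choice must be left/right, got "
                          f"{row['choice']!r}")
        if row["dt_left_ms"] < 0 or row["dt_right_ms"] < 0:
            errors.append(f"row {i}: negative dwell time")
    if errors:
        raise ValueError(f"{trials_path}: validation failed:\n  "
                         + "\n  ".join(errors[:20]))

    fix_by_key: dict = {}
    if fixations_path is not None:
        fdf = pd.read_csv(fixations_path, sep=_sep(fixations_path), comment="#")
        fmissing = [c for c in FIXATION_COLUMNS if c not in fdf.columns]
        if fmissing:
            raise ValueError(
                f"{fixations_path}: missing required columns {fmissing}")
        fdf = fdf.sort_values(["participant_id", "trial_index", "fix_index"])
        for (pid, tidx), grp in fdf.groupby(["participant_id", "trial_index"]):
            onsets = grp["onset_ms"].to_numpy()
            if np.any(np.diff(onsets) <= 0):
                raise ValueError(
                    f"{fixations_path}: non-monotone fixation onsets for "
                    f"participant {pid!r} trial {tidx}")
            fix_by_key[(str(pid), int(tidx))] = tuple(
                Fixation(side=r.side, onset_ms=float(r.onset_ms),
                         duration_ms=float(r.duration_ms))
                for r in grp.itertuples())

    datasets = []
    for (pid, exp), grp in df.groupby(["participant_id", "experiment"],
                                      sort=False):
        trials = []
        for row in grp.sort_values("trial_index").itertuples():
            trials.append(Trial(
                frame=row.frame, r_left=row.r_left, r_right=row.r_right,
                dt_left=row.dt_left_ms, dt_right=row.dt_right_ms,
                choice=row.choice, rt=row.rt_s, confidence=row.confidence,
                trial_index=int(row.trial_index), block=int(row.block),
                fixations=fix_by_key.get((str(pid), int(row.trial_index)), ()),
                gsf=int(row.gsf) if np.isfinite(row.gsf) else None))
        blocks = sorted({(t.block, t.frame) for t in trials})
        datasets.append(TrialDataset(participant_id=str(pid), experiment=exp,
                                     trials=trials, block_structure=blocks))
    return datasets


def write_params(params: GlamParams, path, *, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = params.to_dict()
    if meta:
        payload["_meta"] = meta
    path.write_text(json.dumps(payload, indent=2))


def read_params(path) -> GlamParams:
    payload = json.loads(Path(path).read_text())
    payload.pop("_meta", None)
    return GlamParams.from_dict(payload)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    experiment: str = "value"
    n_participants: int = 4
    seed: int = 0
    out_dir: str = "goalglam_run"
    fit_mode: str = "map"
    n_reps_behaviour: int = 50
    n_reps_delta_e: int = 10
    n_perm: int = 200
    run_sampling_check: bool = True
    sampling_configs: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run synth → fit → simulate → analyse → verify, writing every artifact
    under ``config.out_dir`` and a manifest listing outputs with the seed and
    config hash.  Stages whose outputs already exist are skipped, so a
    partially failed run resumes from the last completed stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    meta = {"seed": config.seed, "config_hash": h}
    manifest = {"config_hash": h, "seed": config.seed, "outputs": []}
    rng = np.random.default_rng(config.seed)
    frames = EXPERIMENT_FRAMES[config.experiment]

    # --- stage 1: synthetic data
    trials_path = out / "trials.csv"
    fix_path = out / "fixations.csv"
    params_true_path = out / "params_true.json"
    if trials_path.exists() and fix_path.exists() and params_true_path.exists():
        log.info("stage synth: outputs exist, skipping")
        datasets = read_trials(trials_path, fix_path)
        true_params = [GlamParams.from_dict(d) for d in
                       json.loads(params_true_path.read_text())]
    else:
        design = (ValueDesign() if config.experiment == "value"
                  else PerceptualDesign())
        true_params = [default_params(config.experiment, rng)
                       for _ in range(config.n_participants)]
        datasets = generate_dataset(design, true_params, rng)
        write_trials(datasets, trials_path, fix_path, **meta)
        params_true_path.write_text(json.dumps(
            [p.to_dict() for p in true_params], indent=2))
    manifest["outputs"] += [str(trials_path), str(fix_path),
                            str(params_true_path)]

    # --- stage 2: per-participant fits (even trials, per frame)
    fits_path = out / "fits.json"
    if fits_path.exists():
        log.info("stage fit: outputs exist, skipping")
        fits = json.loads(fits_path.read_text())
    else:
        fits = {}
        for k, ds in enumerate(datasets):
            fits[ds.participant_id] = {}
            for frame in frames:
                cfg = SamplerConfig(mode=config.fit_mode,
                                    seed=int(rng.integers(2**31)))
                summary = fit_participant(ds.even_trials(), frame, cfg)
                fits[ds.participant_id][frame] = {
                    "point": summary.point, "map": summary.map_estimate,
                    "waic": summary.waic, "converged": summary.converged,
                }
        fits_path.write_text(json.dumps(fits, indent=2))
    manifest["outputs"].append(str(fits_path))

    # --- stage 3: out-of-sample prediction and Δe tables
    pred_path = out / "oos_predictions.csv"
    de_path = out / "delta_e.csv"
    de_nobias_path = out / "delta_e_nobias.csv"
    if not (pred_path.exists() and de_path.exists() and de_nobias_path.exists()):
        preds, des, des_nb = [], [], []
        for ds in datasets:
            for frame in frames:
                odd = ds.odd_trials().frame_subset(frame)
                params = GlamParams(**{k: fits[ds.participant_id][frame]["point"][k]
                                       for k in ("nu", "gamma", "sigma", "tau")})
                sim = SimulationConfig(n_reps_behaviour=config.n_reps_behaviour,
                                       n_reps_delta_e=config.n_reps_delta_e)
                preds.append(out_of_sample_predict(odd, params, sim, rng))
                des.append(delta_e_table(odd, params, sim, rng))
                sim_nb = SimulationConfig(
                    n_reps_behaviour=config.n_reps_behaviour,
                    n_reps_delta_e=config.n_reps_delta_e, no_gaze_bias=True)
                des_nb.append(delta_e_table(odd, params, sim_nb, rng))
        _write_with_header(pd.concat(preds, ignore_index=True), pred_path, meta)
        _write_with_header(pd.concat(des, ignore_index=True), de_path, meta)
        _write_with_header(pd.concat(des_nb, ignore_index=True),
                           de_nobias_path, meta)
    manifest["outputs"] += [str(pred_path), str(de_path), str(de_nobias_path)]

    # --- stage 4: behavioural analyses
    analysis_path = out / "analysis.json"
    if not analysis_path.exists():
        de = pd.read_csv(de_path, comment="#")
        results = {}
        for frame in frames:
            cr = choice_regression(datasets, frame)
            results[f"choice_regression_{frame}"] = \
                cr.coefficients.to_dict(orient="records")
            lf = last_fixation_analysis(datasets, frame)
            results[f"last_fixation_{frame}"] = \
                lf.coefficients.to_dict(orient="records")
            der = delta_e_regression(de, frame)
            results[f"delta_e_regression_{frame}"] = \
                der.coefficients.to_dict(orient="records")
        gi = gaze_influence(datasets)
        results["gaze_influence_mean"] = float(gi["score"].mean())
        perm = permutation_frame_test(datasets, frames[0], frames[1],
                                      n_perm=config.n_perm, rng=rng)
        results["permutation_significant_runs"] = perm.significant_runs
        analysis_path.write_text(json.dumps(results, indent=2, default=float))
    manifest["outputs"].append(str(analysis_path))

    # --- stage 5: optimal-sampling verification
    if config.run_sampling_check:
        sampling_path = out / "sampling_report.csv"
        if not sampling_path.exists():
            report = verify_propositions(
                n_configs=config.sampling_configs, rng=rng)
            _write_with_header(report, sampling_path, meta)
        manifest["outputs"].append(str(sampling_path))

    manifest_path = out / "manifest.json"
    manifest["file_hashes"] = {
        p: hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
        for p in manifest["outputs"] if Path(p).exists()
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
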