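"""Desk-scale statistical analyses of goal-framed choice behaviour.

The headline pattern these analyses exist to detect is a *sign flip* between
frames: the slope of choice on evidence, the last-fixation effect, the
ΣValue effect on confidence (and on the simulated balance of evidence Δe)
all reverse sign between like/dislike (most/fewest) frames, while the effect
of relative dwell time on choice stays positive in both — gaze follows the
goal, not the value.

Hierarchical mixed-effects models are replaced throughout by a two-stage
scheme: a per-participant fit (logistic or linear, z-scored predictors)
followed by a group-level one-sample t-test on each coefficient.  This
preserves every sign/flip inference at desk scale without committing to a
mixed-model solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core import Trial, TrialDataset

__all__ = [
    "RegressionResult",
    "BinSeriesResult",
    "zscore",
    "choice_regression",
    "confidence_regression",
    "delta_e_regression",
    "gaze_influence",
    "last_fixation_analysis",
    "fixation_timeseries",
    "permutation_frame_test",
]


@dataclass
class RegressionResult:
    """Group-level coefficient table plus the per-participant matrix."""

    model: str
    coefficients: pd.DataFrame          # name, estimate, se, t (or z), p
    per_participant: pd.DataFrame | None = None
    flagged_participants: list = field(default_factory=list)

    def coef(self, name: str) -> float:
        row = self.coefficients.set_index("name").loc[name]
        return float(row["estimate"])

    def stat(self, name: str) -> float:
        row = self.coefficients.set_index("name").loc[name]
        return float(row["t"])


@dataclass
class BinSeriesResult:
    """Per-bin correlation series and permutation-test annotations."""

    table: pd.DataFrame                  # time_ms, r_a, r_b, diff, p, q, ...
    frames: tuple = ()
    n_permutations: int = 0

    @property
    def significant_runs(self) -> list:
        """(start_ms, end_ms) of flagged contiguous runs."""
        sig = self.table["significant"].to_numpy()
        t = self.table["time_ms"].to_numpy()
        runs, start = [], None
        for i, s in enumerate(sig):
            if s and start is None:
                start = i
            if not s and start is not None:
                runs.append((float(t[start]), float(t[i - 1])))
                start = None
        if start is not None:
            runs.append((float(t[start]), float(t[-1])))
        return runs


def zscore(x) -> np.ndarray:
    """Z-score, returning zeros (not NaN) for a constant input."""
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Per-participant fits
# ---------------------------------------------------------------------------

def _ridge_logistic(X, y, alpha=1.0):
    """Penalised logistic fit used when the MLE separates."""
    n, p = X.shape

    def nll(beta):
        z = X @ beta
        return (np.sum(np.logaddexp(0, z)) - y @ z) + 0.5 * alpha * beta @ beta

    res = optimize.minimize(nll, np.zeros(p), method="L-BFGS-B")
    return res.x


def _participant_logistic(X, y):
    """Logistic coefficients; returns (coefs, flagged)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            coefs = fit.params
            if np.all(np.isfinite(coefs)) and np.max(np.abs(coefs)) < 15:
                return np.asarray(coefs), False
        except Exception:
            pass
    return _ridge_logistic(np.asarray(X, float), np.asarray(y, float)), True


def _two_stage(per_participant: pd.DataFrame, names, model: str,
               flagged) -> RegressionResult:
    rows = []
    for name in names:
        vals = per_participant[name].to_numpy()
        est = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        if len(vals) > 1 and se > 0:
            t, p = stats.ttest_1samp(vals, 0.0)
        else:
            t, p = np.nan, np.nan
        rows.append({"name": name, "estimate": est, "se": se,
                     "t": float(t), "p": float(p)})
    return RegressionResult(model=model, coefficients=pd.DataFrame(rows),
                            per_participant=per_participant,
                            flagged_participants=flagged)


def _trial_features(ds: TrialDataset, frame: str | None,
                    exclude_last_n_fixations: int = 0) -> pd.DataFrame:
    trials = [t for t in ds.trials if frame is None or t.frame == frame]
    rows = []
    for t in trials:
        if exclude_last_n_fixations and t.fixations:
            fixs = t.fixations[:-exclude_last_n_fixations] or ()
            dt_l = sum(f.duration_ms for f in fixs if f.side == "left")
            dt_r = sum(f.duration_ms for f in fixs if f.side == "right")
        else:
            dt_l, dt_r = t.dt_left, t.dt_right
        rows.append({
            "choice": t.choice01,
            "dv": t.r_right - t.r_left,
            "abs_dv": abs(t.r_right - t.r_left),
            "sv": t.r_right + t.r_left,
            "rt": t.rt,
            "ddt": dt_r - dt_l,
            "conf": t.confidence,
            "gsf": t.gsf if t.gsf is not None else len(t.fixations) - 1,
        })
    return pd.DataFrame(rows)


def choice_regression(datasets, frame: str | None = None, *,
                      predictors=("dv", "rt", "sv", "ddt", "conf"),
                      exclude_last_n_fixations: int = 0) -> RegressionResult:
    """Two-stage logistic regression of P(choose right).

    Stage 1 fits each participant with z-scored predictors (ΔValue, RT,
    ΣValue, ΔDT, confidence by default); stage 2 tests each coefficient
    against zero across participants.  Participants whose MLE separates are
    refit with a ridge penalty and flagged.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two participants for the group test")
    per_rows, flagged = [], []
    for ds in datasets:
        df = _trial_features(ds, frame, exclude_last_n_fixations)
        if len(df) < 10:
            continue
        X = np.column_stack([np.ones(len(df))]
                            + [zscore(df[p]) for p in predictors])
        coefs, bad = _participant_logistic(X, df["choice"].to_numpy())
        if bad:
            flagged.append(ds.participant_id)
        per_rows.append({"participant_id": ds.participant_id,
                         "intercept": coefs[0],
                         **{p: coefs[i + 1] for i, p in enumerate(predictors)}})
    per = pd.DataFrame(per_rows)
    return _two_stage(per, list(predictors),
                      f"choice ~ {' + '.join(predictors)} [{frame or 'all'}]",
                      flagged)


def delta_e_regression(table: pd.DataFrame, frame: str | None = None) -> RegressionResult:
    """Pooled OLS of the simulated balance of evidence:
    Δe ~ |ΔValue| + simulated RT + ΣValue.

    Predictors are z-scored within participant; contaminated repetitions
    (Δe undefined) are excluded.
    """
    df = table.copy()
    if frame is not None:
        df = df[df["frame"] == frame]
    df = df[~df["contaminated"] & np.isfinite(df["delta_e"])].copy()
    for col in ("abs_diff_evidence", "sim_rt", "sum_evidence"):
        df[f"z_{col}"] = df.groupby("participant_id")[col].transform(zscore)
    X = sm.add_constant(df[["z_abs_diff_evidence", "z_sim_rt",
                            "z_sum_evidence"]].to_numpy())
    fit = sm.OLS(df["delta_e"].to_numpy(), X).fit()
    names = ["intercept", "abs_dv", "sim_rt", "sv"]
    coefs = pd.DataFrame({
        "name": names,
        "estimate": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })
    return RegressionResult(
        model=f"delta_e ~ abs_dv + sim_rt + sv [{frame or 'all'}]",
        coefficients=coefs.reset_index(drop=True))


def confidence_regression(data, frame: str | None = None, *,
                          predictors=("abs_dv", "rt", "sv", "ddt", "gsf")):
    """Confidence model dispatch.

    A Δe simulation table (DataFrame with a ``delta_e`` column) gets the
    pooled regression Δe ~ |ΔValue| + simulated RT + ΣValue; a list of trial
    datasets gets the two-stage linear model of rated confidence.
    """
    if isinstance(data, pd.DataFrame) and "delta_e" in data.columns:
        return delta_e_regression(data, frame)
    per_rows = []
    used = []
    for ds in data:
        df = _trial_features(ds, frame)
        if len(df) < 10 or not np.isfinite(df["conf"]).all():
            continue
        cols, names = [], []
        for p in predictors:
            z = zscore(df[p])
            if np.all(z == 0):
                warnings.warn(f"constant predictor {p!r} dropped for "
                              f"{ds.participant_id}")
                continue
            cols.append(z)
            names.append(p)
        X = np.column_stack([np.ones(len(df))] + cols)
        beta, *_ = np.linalg.lstsq(X, df["conf"].to_numpy(), rcond=None)
        row = {"participant_id": ds.participant_id, "intercept": beta[0]}
        row.update({n: beta[i + 1] for i, n in enumerate(names)})
        per_rows.append(row)
        used = names
    per = pd.DataFrame(per_rows)
    return _two_stage(per, used,
                      f"confidence ~ {' + '.join(used)} [{frame or 'all'}]", [])


def gaze_influence(datasets, frame: str | None = None,
                   min_trials: int = 30) -> pd.DataFrame:
    """Per-participant gaze-advantage score.

    Residual = actual choice (1 right / 0 left) minus the probability of
    choosing right from a ΔValue-only logistic fit of the participant's own
    behaviour; the score is the mean residual for ΔGaze > 0 minus the mean
    for ΔGaze < 0, halved.  Positive = gaze advantage.
    """
    rows = []
    for ds in datasets:
        trials = [t for t in ds.trials if frame is None or t.frame == frame]
        trials = [t for t in trials if t.dt_left + t.dt_right > 0]
        if len(trials) < min_trials:
            continue
        dv = zscore([t.r_right - t.r_left for t in trials])
        y = np.array([t.choice01 for t in trials], float)
        X = np.column_stack([np.ones(len(y)), dv])
        coefs, flagged = _participant_logistic(X, y)
        p_right = expit(X @ coefs)
        resid = y - p_right
        dgaze = np.array([(t.dt_right - t.dt_left) / (t.dt_right + t.dt_left)
                          for t in trials])
        pos, neg = resid[dgaze > 0], resid[dgaze < 0]
        if len(pos) == 0 or len(neg) == 0:
            score = np.nan
        else:
            score = 0.5 * (pos.mean() - neg.mean())
        rows.append({"participant_id": ds.participant_id, "score": score,
                     "n_trials": len(trials), "flagged": flagged})
    return pd.DataFrame(rows)


def last_fixation_analysis(datasets, frame: str | None = None) -> RegressionResult:
    """Logistic slope of P(last fixation is on the chosen item) on the
    evidence advantage of the last-fixated item (raw scale, z-scored within
    participant).  A positive group slope in the like/most frame and a
    negative one in dislike/fewest is the goal-relevant signature."""
    per_rows, flagged = [], []
    for ds in datasets:
        trials = [t for t in ds.trials
                  if (frame is None or t.frame == frame) and t.fixations]
        if len(trials) < 10:
            continue
        x, y = [], []
        for t in trials:
            last = t.fixations[-1].side
            e_last = t.r_right if last == "right" else t.r_left
            e_other = t.r_left if last == "right" else t.r_right
            x.append(e_last - e_other)
            y.append(1.0 if last == t.choice else 0.0)
        y = np.array(y)
        X = np.column_stack([np.ones(len(y)), zscore(x)])
        if y.min() == y.max():
            # degenerate: last fixation always (never) on the chosen item
            flagged.append(ds.participant_id)
            per_rows.append({"participant_id": ds.participant_id,
                             "intercept": np.inf if y.min() == 1 else -np.inf,
                             "slope": 0.0, "intercept_dominated": True})
            continue
        coefs, bad = _participant_logistic(X, y)
        if bad:
            flagged.append(ds.participant_id)
        per_rows.append({"participant_id": ds.participant_id,
                         "intercept": coefs[0], "slope": coefs[1],
                         "intercept_dominated": False})
    per = pd.DataFrame(per_rows)
    finite = per[np.isfinite(per["slope"]) & ~per["intercept_dominated"]]
    return _two_stage(finite, ["slope"],
                      f"P(lastfix = chosen) ~ evidence advantage [{frame or 'all'}]",
                      flagged)


# ---------------------------------------------------------------------------
# Fixation time series
# ---------------------------------------------------------------------------

def _gaze_matrix(datasets, frame: str, bin_ms: float, window_ms: float):
    """(n_trials x n_bins) gaze-side matrix (1 right, 0 left, NaN no fixation)
    plus the per-trial raw evidence difference (right - left)."""
    n_bins = int(round(window_ms / bin_ms))
    centers = (np.arange(n_bins) + 0.5) * bin_ms
    rows, dvs = [], []
    for ds in datasets:
        for t in ds.trials:
            if t.frame != frame or not t.fixations:
                continue
            g = np.full(n_bins, np.nan)
            for f in t.fixations:
                sel = (centers >= f.onset_ms) & (centers < f.onset_ms + f.duration_ms)
                g[sel] = 1.0 if f.side == "right" else 0.0
            g[centers > t.rt * 1000.0] = np.nan
            rows.append(g)
            dvs.append(t.r_right - t.r_left)
    if not rows:
        return np.empty((0, n_bins)), np.empty(0), centers
    return np.vstack(rows), np.asarray(dvs), centers


def _nancorr_bins(G: np.ndarray, x: np.ndarray, min_n: int = 2):
    """Pearson r between each column of G (with NaNs) and x."""
    mask = np.isfinite(G)
    n = mask.sum(axis=0)
    Gz = np.where(mask, G, 0.0)
    xs = x[:, None] * mask
    with np.errstate(invalid="ignore", divide="ignore"):
        mg = Gz.sum(axis=0) / n
        mx = xs.sum(axis=0) / n
        cov = (Gz * x[:, None]).sum(axis=0) / n - mg * mx
        vg = (Gz ** 2).sum(axis=0) / n - mg ** 2
        vx = (xs ** 2).sum(axis=0) / n - mx ** 2
        r = cov / np.sqrt(vg * vx)
    r[(n < min_n) | ~np.isfinite(r)] = np.nan
    return r, n


def fixation_timeseries(datasets, frame: str, *, bin_ms: float = 10.0,
                        window_ms: float = 2000.0) -> pd.DataFrame:
    """Per-bin Pearson correlation between gaze side and evidence difference.

    Trials are pooled across participants and aligned to stimulus onset;
    bins a trial does not reach (or where no fixation is active) contribute
    nothing; bins with fewer than two trials or zero variance are NaN.
    """
    G, dv, centers = _gaze_matrix(datasets, frame, bin_ms, window_ms)
    r, n = _nancorr_bins(G, dv)
    return pd.DataFrame({"time_ms": centers, "r": r, "n_trials": n})


def permutation_frame_test(datasets, frame_a: str, frame_b: str, *,
                           bin_ms: float = 10.0, window_ms: float = 2000.0,
                           n_perm: int = 200, alpha: float = 0.01,
                           min_run: int = 6, min_trials_per_bin: int = 10,
                           rng=None, mode: str = "label") -> BinSeriesResult:
    """Permutation test of the between-frame difference in the gaze-evidence
    correlation time series, FDR-corrected (Benjamini-Hochberg, q <= alpha),
    flagging only runs of at least ``min_run`` consecutive significant bins.

    ``mode='label'`` shuffles frame labels across trials (exchangeable
    null); ``mode='instant'`` shuffles the instantaneous gaze samples within
    each bin.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution")
    rng = np.random.default_rng() if rng is None else rng
    Ga, dva, centers = _gaze_matrix(datasets, frame_a, bin_ms, window_ms)
    Gb, dvb, _ = _gaze_matrix(datasets, frame_b, bin_ms, window_ms)
    ra, na = _nancorr_bins(Ga, dva)
    rb, nb = _nancorr_bins(Gb, dvb)
    obs = ra - rb
    G = np.vstack([Ga, Gb])
    dv = np.concatenate([dva, dvb])
    n_a = Ga.shape[0]
    null = np.empty((n_perm, len(centers)))
    for k in range(n_perm):
        if mode == "label":
            perm = rng.permutation(G.shape[0])
            pa, pb = perm[:n_a], perm[n_a:]
            r1, _ = _nancorr_bins(G[pa], dv[pa])
            r2, _ = _nancorr_bins(G[pb], dv[pb])
        elif mode == "instant":
            Gs = G.copy()
            for j in range(Gs.shape[1]):
                Gs[:, j] = Gs[rng.permutation(Gs.shape[0]), j]
            r1, _ = _nancorr_bins(Gs[:n_a], dva)
            r2, _ = _nancorr_bins(Gs[n_a:], dvb)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        null[k] = r1 - r2
    valid = np.isfinite(obs) & np.all(np.isfinite(null), axis=0)
    p = np.full(len(centers), np.nan)
    with np.errstate(invalid="ignore"):
        exceed = np.sum(np.abs(null) >= np.abs(obs)[None, :], axis=0)
    p[valid] = (1.0 + exceed[valid]) / (n_perm + 1.0)
    q = np.full(len(centers), np.nan)
    if valid.any():
        _, qv, *_ = multipletests(p[valid], method="fdr_bh")
        q[valid] = qv
    enough = (na >= min_trials_per_bin) & (nb >= min_trials_per_bin)
    candidate = valid & enough & (q <= alpha)
    significant = _flag_runs(candidate, min_run)
    table = pd.DataFrame({
        "time_ms": centers, "r_a": ra, "r_b": rb, "diff": obs,
        "n_a": na, "n_b": nb, "p": p, "q": q,
        "candidate": candidate, "significant": significant,
    })
    return BinSeriesResult(table=table, frames=(frame_a, frame_b),
                           n_permutations=n_perm)


def _flag_runs(candidate: np.ndarray, min_run: int) -> np.ndarray:
    out = np.zeros_like(candidate, bool)
    i = 0
    n = len(candidate)
    while i < n:
        if candidate[i]:
            j = i
            while j < n and candidate[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out
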