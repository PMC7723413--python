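"""Synthetic datasets with the statistical structure of the two experiments.

The value task emulates snack choices: 60 items with BDM bids on a £0-3
scale, a median split into high/low value, 15 high-high + 15 low-low + 30
mixed pairs, each pair shown twice per frame with sides counterbalanced,
240 trials in 6 alternating like/dislike blocks of 40.

The perceptual task emulates dot-numerosity choices: three numerosity levels
(50/80/110 total target dots), ten percentage differences (2-20% in 2%
steps), distractor dots at 80% of the target count (40/64/88), most/fewest
frames alternating by block.

Gaze is generated as an alternating fixation stream: an initial unbiased
exploration window, after which dwell is biased toward the goal-relevant
item (the one with higher goal-transformed evidence).  Choices, RTs and the
balance of evidence come from path simulation of the GLAM race; confidence
is an affine map of Δe plus Gaussian noise, clipped to a 1-10 rating scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core import (
    EXPERIMENT_FRAMES,
    EXPERIMENT_SCALES,
    Fixation,
    GlamParams,
    Trial,
    TrialDataset,
    goal_relevant_evidence,
)
from .simulate import SimulationConfig, simulate_paths

__all__ = [
    "ValueDesign",
    "PerceptualDesign",
    "GazeGenConfig",
    "ConfidenceMap",
    "generate_value_design",
    "generate_perceptual_design",
    "generate_gaze",
    "generate_dataset",
    "default_params",
]


@dataclass(frozen=True)
class ValueDesign:
    n_items: int = 60
    bid_scale: tuple = (0.0, 3.0)
    n_high_pairs: int = 15
    n_low_pairs: int = 15
    n_mixed_pairs: int = 30
    presentations_per_frame: int = 2   # left/right counterbalanced
    n_blocks: int = 6
    block_size: int = 40
    bid_distribution: str = "uniform"  # "uniform" | "beta"

    experiment = "value"

    def __post_init__(self) -> None:
        n_pairs = self.n_high_pairs + self.n_low_pairs + self.n_mixed_pairs
        n_trials = n_pairs * self.presentations_per_frame * 2
        if n_trials != self.n_blocks * self.block_size:
            raise ValueError(
                f"{n_trials} trials do not fill {self.n_blocks} blocks "
                f"of {self.block_size}")
        if self.n_items % 2:
            raise ValueError("n_items must be even for a median split")
        if 2 * self.n_high_pairs > self.n_items // 2:
            raise ValueError("not enough high-value items for the pair counts")
        if 2 * self.n_low_pairs > self.n_items // 2:
            raise ValueError("not enough low-value items for the pair counts")


@dataclass(frozen=True)
class PerceptualDesign:
    numerosity_levels: tuple = (50, 80, 110)
    difference_levels: tuple = tuple(range(2, 21, 2))  # percent of total
    distractor_fraction: float = 0.8
    repetitions: int = 2               # per side arrangement, per frame
    n_blocks: int = 6
    block_size: int = 40

    experiment = "perceptual"

    def distractors(self, numerosity: int) -> int:
        return int(round(self.distractor_fraction * numerosity))

    def dot_split(self, numerosity: int, diff_pct: float) -> tuple:
        """Target counts for a pair: N +/- N*d/200, rounded half-up.

        The two circles differ by d% of the numerosity level (22 dots for
        the 20% pair at numerosity 110) and every count stays inside the
        40-133 evidence scale of the fewest-frame transform.
        """
        delta = numerosity * diff_pct / 200.0
        hi = int(np.floor(numerosity + delta + 0.5))
        lo = int(np.floor(numerosity - delta + 0.5))
        return hi, lo


@dataclass(frozen=True)
class GazeGenConfig:
    """Goal-biased alternating fixation process.

    After ``unbiased_duration_ms`` of equiprobable exploration, fixations on
    the goal-relevant item last ``2 * goal_dwell_share`` times the base mean
    and those on the other item ``2 * (1 - goal_dwell_share)`` times it, so
    the long-run dwell share toward the goal item equals
    ``goal_dwell_share``.
    """

    unbiased_duration_ms: float = 600.0
    goal_dwell_share: float = 0.60
    fixation_mean_ms: float = 400.0
    fixation_shape: float = 3.0
    horizon_ms: float = 12000.0
    #: window over which the race's gaze ratio is integrated; matching it to
    #: a typical trial duration keeps the recorded dwell split and the drift
    #: input sharing the same trial-level variability
    integration_window_ms: float = 2500.0

    def __post_init__(self) -> None:
        if not 0.5 <= self.goal_dwell_share <= 1.0:
            raise ValueError("goal_dwell_share must be in [0.5, 1]")
        if self.fixation_mean_ms <= 0 or self.fixation_shape <= 0:
            raise ValueError("fixation duration parameters must be positive")


@dataclass(frozen=True)
class ConfidenceMap:
    """Affine map from balance of evidence to a 1-10 confidence rating."""

    intercept: float = 2.0
    slope: float = 6.0
    noise_sd: float = 1.0
    scale: tuple = (1, 10)

    def __call__(self, delta_e, rng) -> np.ndarray:
        raw = (self.intercept + self.slope * np.asarray(delta_e, float)
               + self.noise_sd * rng.standard_normal(np.shape(delta_e)))
        return np.clip(np.round(raw), self.scale[0], self.scale[1])


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

def _blocked_order(per_frame_trials: dict, frames: tuple, design, rng) -> list:
    """Interleave frames by block, shuffling within frame, and enforce that
    the pair ending one block does not open the next."""
    first = frames[int(rng.integers(0, 2))]
    frame_seq = [first if i % 2 == 0 else
                 frames[1 - frames.index(first)] for i in range(design.n_blocks)]
    pools = {}
    for fr in frames:
        t = list(per_frame_trials[fr])
        rng.shuffle(t)
        pools[fr] = t
    blocks = []
    for b, fr in enumerate(frame_seq):
        chunk = [pools[fr].pop() for _ in range(design.block_size)]
        blocks.append((b + 1, fr, chunk))
    # last pair of a block must differ from the first of the next
    for (b1, f1, c1), (b2, f2, c2) in zip(blocks, blocks[1:]):
        if c1[-1]["pair_id"] == c2[0]["pair_id"]:
            for j in range(1, len(c2)):
                if c2[j]["pair_id"] != c1[-1]["pair_id"]:
                    c2[0], c2[j] = c2[j], c2[0]
                    break
    trials = []
    idx = 0
    for b, fr, chunk in blocks:
        for row in chunk:
            idx += 1
            row = dict(row)
            row["block"] = b
            row["trial_index"] = idx
            trials.append(row)
    return trials, [(b, fr) for b, fr, _ in blocks]


def generate_value_design(rng, design: ValueDesign = ValueDesign()) -> dict:
    """Skeleton of the value experiment for one participant.

    Returns a dict with ``trials`` (rows of frame/block/trial_index/
    r_left/r_right/pair_id), ``block_structure``, ``bids`` and the bid
    ``median``.
    """
    lo, hi = design.bid_scale
    if design.bid_distribution == "uniform":
        bids = rng.uniform(lo, hi, design.n_items)
    elif design.bid_distribution == "beta":
        bids = lo + (hi - lo) * rng.beta(2, 2, design.n_items)
    else:
        raise ValueError(f"unknown bid distribution {design.bid_distribution!r}")
    bids = np.round(bids, 2)
    median = float(np.median(bids))
    order = np.argsort(bids)
    low_items = order[: design.n_items // 2]
    high_items = order[design.n_items // 2:]

    def disjoint_pairs(items, n_pairs):
        items = rng.permutation(items)
        return [(int(items[2 * k]), int(items[2 * k + 1])) for k in range(n_pairs)]

    pairs = disjoint_pairs(high_items, design.n_high_pairs)
    pairs += disjoint_pairs(low_items, design.n_low_pairs)
    pairs += list(zip(rng.permutation(high_items)[: design.n_mixed_pairs],
                      rng.permutation(low_items)[: design.n_mixed_pairs]))
    pairs = [(int(a), int(b)) for a, b in pairs]

    per_frame = {}
    for frame in EXPERIMENT_FRAMES["value"]:
        rows = []
        for pid, (a, b) in enumerate(pairs):
            for flip in range(design.presentations_per_frame):
                left, right = (a, b) if flip % 2 == 0 else (b, a)
                rows.append({"frame": frame, "pair_id": pid,
                             "r_left": float(bids[left]),
                             "r_right": float(bids[right])})
        per_frame[frame] = rows
    trials, block_structure = _blocked_order(
        per_frame, EXPERIMENT_FRAMES["value"], design, rng)
    return {"trials": trials, "block_structure": block_structure,
            "bids": bids, "median": median,
            "pair_categories": (["high"] * design.n_high_pairs
                                + ["low"] * design.n_low_pairs
                                + ["mixed"] * design.n_mixed_pairs)}


def generate_perceptual_design(rng,
                               design: PerceptualDesign = PerceptualDesign()) -> dict:
    """Skeleton of the perceptual experiment for one participant."""
    conditions = [(n, d) for n in design.numerosity_levels
                  for d in design.difference_levels]
    per_frame = {}
    for frame in EXPERIMENT_FRAMES["perceptual"]:
        rows = []
        for pid, (n, d) in enumerate(conditions):
            hi, lo = design.dot_split(n, d)
            for rep in range(design.repetitions):
                for flip in range(2):
                    left, right = (hi, lo) if flip == 0 else (lo, hi)
                    rows.append({"frame": frame, "pair_id": pid,
                                 "r_left": float(left), "r_right": float(right),
                                 "numerosity": n, "diff_pct": d,
                                 "n_distractors": design.distractors(n)})
        per_frame[frame] = rows
    trials, block_structure = _blocked_order(
        per_frame, EXPERIMENT_FRAMES["perceptual"], design, rng)
    return {"trials": trials, "block_structure": block_structure,
            "conditions": conditions}


# ---------------------------------------------------------------------------
# Gaze
# ---------------------------------------------------------------------------

def generate_gaze(r_left: float, r_right: float, frame: str,
                  config: GazeGenConfig, rng, *,
                  scale: tuple | None = None) -> list:
    """Alternating fixation stream biased toward the goal-relevant item.

    Fixations strictly alternate sides from a random start.  Durations are
    Gamma distributed; inside the unbiased window both sides share the base
    mean, afterwards the goal side's mean is scaled up and the other side's
    down so the dwell share approaches ``goal_dwell_share``.
    """
    if scale is None:
        scale = (EXPERIMENT_SCALES["value"] if frame in ("like", "dislike")
                 else EXPERIMENT_SCALES["perceptual"])
    smin, smax = scale
    e_left = goal_relevant_evidence(r_left, frame, smax, smin)
    e_right = goal_relevant_evidence(r_right, frame, smax, smin)
    if e_left == e_right:
        goal_side = "left" if rng.uniform() < 0.5 else "right"
    else:
        goal_side = "left" if e_left > e_right else "right"
    side = "left" if rng.uniform() < 0.5 else "right"
    shape = config.fixation_shape
    base = config.fixation_mean_ms
    share = config.goal_dwell_share
    fixations = []
    t = 0.0
    while t < config.horizon_ms:
        if t < config.unbiased_duration_ms:
            mean = base
        else:
            mean = 2 * share * base if side == goal_side else 2 * (1 - share) * base
        dur = rng.gamma(shape, mean / shape)
        dur = max(dur, 1.0)
        fixations.append(Fixation(side=side, onset_ms=t, duration_ms=dur))
        t += dur
        side = "left" if side == "right" else "right"
    return fixations, goal_side


def _truncate(fixations, rt_ms: float):
    """Clip a fixation stream at the response time; return dwell sums."""
    out = []
    dt = {"left": 0.0, "right": 0.0}
    for f in fixations:
        if f.onset_ms >= rt_ms:
            break
        dur = min(f.duration_ms, rt_ms - f.onset_ms)
        out.append(Fixation(side=f.side, onset_ms=f.onset_ms, duration_ms=dur))
        dt[f.side] += dur
    gsf = max(len(out) - 1, 0)
    return tuple(out), dt["left"], dt["right"], gsf


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def default_params(experiment: str, rng) -> GlamParams:
    """Plausible per-participant generating parameters for each experiment.

    Drift scaling gives ~2-4 s response times on the millisecond time base;
    tau is matched to the evidence scale of the task (pounds vs dots).
    """
    if experiment == "value":
        tau = rng.uniform(0.7, 1.6)
    else:
        tau = rng.uniform(0.03, 0.08)
    return GlamParams(
        nu=rng.uniform(3.5e-4, 6.5e-4),
        gamma=rng.uniform(0.1, 0.5),
        sigma=rng.uniform(0.008, 0.014),
        tau=tau,
    )


def generate_dataset(design, params_per_participant, rng, *,
                     gaze_config: GazeGenConfig = GazeGenConfig(),
                     confidence_map: ConfidenceMap = ConfidenceMap(),
                     sim_config: SimulationConfig | None = None,
                     contaminant_rt_bounds: tuple = (0.3, 10.0)) -> list:
    """Generate complete synthetic datasets, one per participant.

    ``design`` is a :class:`ValueDesign` or :class:`PerceptualDesign`.
    ``params_per_participant`` is a list of :class:`GlamParams`.  Each
    participant gets an independent child RNG stream, so adding participants
    never perturbs earlier ones.  Returns a list of :class:`TrialDataset`.
    """
    sim_config = sim_config or SimulationConfig()
    experiment = design.experiment
    smin, smax = EXPERIMENT_SCALES[experiment]
    datasets = []
    streams = rng.spawn(len(params_per_participant))
    for pidx, (params, prng) in enumerate(zip(params_per_participant, streams)):
        if experiment == "value":
            skel = generate_value_design(prng, design)
        else:
            skel = generate_perceptual_design(prng, design)
        rows = skel["trials"]
        n = len(rows)
        streams_fix = []
        d_l = np.empty(n)
        d_r = np.empty(n)
        for i, row in enumerate(rows):
            fixations, _goal = generate_gaze(
                row["r_left"], row["r_right"], row["frame"], gaze_config, prng,
                scale=(smin, smax))
            streams_fix.append(fixations)
            _, w_l, w_r, _ = _truncate(fixations, gaze_config.integration_window_ms)
            g_left = w_l / (w_l + w_r)
            e_l = goal_relevant_evidence(row["r_left"], row["frame"], smax, smin)
            e_r = goal_relevant_evidence(row["r_right"], row["frame"], smax, smin)
            a_l = g_left * e_l + (1 - g_left) * params.gamma * e_l
            a_r = (1 - g_left) * e_r + g_left * params.gamma * e_r
            d_l[i] = params.nu * expit(params.tau * (a_l - a_r))
            d_r[i] = params.nu * expit(-params.tau * (a_l - a_r))
        choice, rt_s, e_fin_l, e_fin_r = simulate_paths(
            d_l, d_r, params, prng, dt=sim_config.dt,
            max_time=sim_config.max_time)
        delta_e = np.abs(e_fin_r - e_fin_l)
        contaminated = prng.uniform(size=n) < params.contaminant_rate
        k = int(contaminated.sum())
        if k:
            choice = np.where(contaminated, prng.integers(0, 2, size=n), choice)
            rt_s = np.where(contaminated,
                            prng.uniform(*contaminant_rt_bounds, size=n), rt_s)
            delta_e = np.where(contaminated, np.nan, delta_e)
        confidence = confidence_map(np.nan_to_num(delta_e), prng)
        if k:
            confidence = np.where(
                contaminated,
                prng.integers(confidence_map.scale[0],
                              confidence_map.scale[1] + 1, size=n),
                confidence)
        trials = []
        for i, row in enumerate(rows):
            fixs, dt_l, dt_r, gsf = _truncate(streams_fix[i], rt_s[i] * 1000.0)
            trials.append(Trial(
                frame=row["frame"], r_left=row["r_left"], r_right=row["r_right"],
                dt_left=dt_l, dt_right=dt_r,
                choice="right" if choice[i] else "left",
                rt=float(rt_s[i]), confidence=float(confidence[i]),
                trial_index=row["trial_index"], block=row["block"],
                fixations=fixs, gsf=gsf))
        datasets.append(TrialDataset(
            participant_id=f"synth-{pidx:02d}", experiment=experiment,
            trials=trials, block_structure=skel["block_structure"]))
    return datasets
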