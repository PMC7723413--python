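"""Core data types and likelihood for the gaze-weighted linear accumulator model (GLAM).

The GLAM is a linear stochastic race between the two options of a binary
choice.  Each option ``i`` accumulates evidence with a constant drift
``nu * R_i`` plus Gaussian noise of standard deviation ``sigma`` until one
accumulator reaches a fixed boundary (1), which determines the choice and the
response time.  ``R_i`` is built from the trial's *goal-relevant* evidence and
the relative gaze the participant allocated to each option:

    A_i  = g_i * r_i + (1 - g_i) * gamma * r_i      (gaze-discounted evidence)
    R*_i = A_i - A_j                                (relative evidence, binary)
    R_i  = 1 / (1 + exp(-tau * R*_i))               (logistic scaling)

Goal relevance means the raw evidence is re-mapped when the task frame asks
for the *least* liked item or the circle with the *fewest* dots, so that the
to-be-selected option always carries the larger evidence.

Because the drift is constant within a trial, the first-passage time of each
accumulator is Wald (inverse-Gaussian) distributed, which gives an analytic
choice/RT likelihood for the race: the winning accumulator's density times the
survival function of the loser, mixed with a small uniform contaminant
process.

Units: the accumulator operates on a millisecond time base (drift per ms,
noise per sqrt-ms), which keeps realistic response times inside the
conventional prior ``nu ~ U(1e-10, 0.01)``.  Response times cross the API in
seconds; conversion happens here and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import expit, logsumexp
from scipy.stats import invgauss

__all__ = [
    "MS_PER_S",
    "VALUE_SCALE",
    "PERCEPTUAL_SCALE",
    "EXPERIMENT_SCALES",
    "EXPERIMENT_FRAMES",
    "Frame",
    "GlamParams",
    "Fixation",
    "Trial",
    "TrialDataset",
    "EvidenceTerms",
    "goal_relevant_evidence",
    "relative_gaze",
    "average_absolute_evidence",
    "relative_evidence_binary",
    "scaled_evidence",
    "compute_evidence_terms",
    "drift_rates",
    "fpt_density",
    "fpt_logpdf",
    "fpt_logsf",
    "race_choice_probability",
    "trial_likelihood",
    "dataset_nll",
]

MS_PER_S = 1000.0

Frame = Literal["like", "dislike", "most", "fewest"]

#: (scale_min, scale_max) of the raw evidence in each experiment.
VALUE_SCALE = (0.0, 3.0)          # BDM bids in pounds
PERCEPTUAL_SCALE = (40.0, 133.0)  # target dot counts

EXPERIMENT_SCALES = {"value": VALUE_SCALE, "perceptual": PERCEPTUAL_SCALE}
EXPERIMENT_FRAMES = {"value": ("like", "dislike"), "perceptual": ("most", "fewest")}

_FRAMES = ("like", "dislike", "most", "fewest")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlamParams:
    """The four free GLAM parameters plus the fixed boundary.

    Parameters
    ----------
    nu
        Drift scaling (evidence units per ms), > 0.
    gamma
        Gaze-bias weight applied to the unattended option, in [-1, 1].
        ``gamma = 1`` removes the gaze bias entirely.
    sigma
        Accumulator noise standard deviation per sqrt-ms, > 0.
    tau
        Evidence-scaling sensitivity of the logistic transform, >= 0.
        ``tau = 0`` makes choices insensitive to evidence (drift ratio 1).
    boundary
        Decision threshold, fixed at 1.
    contaminant_rate
        Mixture weight of the random-choice / uniform-RT contaminant process.
    """

    nu: float
    gamma: float
    sigma: float
    tau: float
    boundary: float = 1.0
    contaminant_rate: float = 0.05

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if not -1.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [-1, 1], got {self.gamma}")
        if self.boundary != 1.0:
            raise ValueError("boundary is fixed at 1")
        if not 0.0 <= self.contaminant_rate < 1.0:
            raise ValueError(
                f"contaminant_rate must be in [0, 1), got {self.contaminant_rate}"
            )

    def with_(self, **kwargs) -> "GlamParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "nu": self.nu,
            "gamma": self.gamma,
            "sigma": self.sigma,
            "tau": self.tau,
            "boundary": self.boundary,
            "contaminant_rate": self.contaminant_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GlamParams":
        return cls(**{k: d[k] for k in
                      ("nu", "gamma", "sigma", "tau", "boundary", "contaminant_rate")
                      if k in d})


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixation:
    side: str          # "left" | "right"
    onset_ms: float
    duration_ms: float


@dataclass
class Trial:
    """One behavioural trial: evidence, gaze, choice, RT, confidence.

    ``dt_left`` / ``dt_right`` are dwell times in ms; ``rt`` is in seconds.
    ``trial_index`` is 1-based within participant (odd trials are held out of
    fitting for out-of-sample prediction).
    """

    frame: str
    r_left: float
    r_right: float
    dt_left: float
    dt_right: float
    choice: str
    rt: float
    confidence: float = np.nan
    trial_index: int = 0
    block: int = 0
    fixations: tuple = ()
    gsf: int | None = None

    def __post_init__(self) -> None:
        if self.frame not in _FRAMES:
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.choice not in ("left", "right"):
            raise ValueError(f"choice must be 'left' or 'right', got {self.choice!r}")
        if not self.rt > 0:
            raise ValueError(f"rt must be > 0, got {self.rt}")
        if self.dt_left < 0 or self.dt_right < 0:
            raise ValueError("dwell times must be >= 0")
        if self.dt_left + self.dt_right > self.rt * MS_PER_S + 1e-6:
            raise ValueError(
                f"dwell times ({self.dt_left + self.dt_right:.1f} ms) exceed "
                f"rt ({self.rt * MS_PER_S:.1f} ms)"
            )
        onsets = [f.onset_ms for f in self.fixations]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("fixation onsets must be strictly increasing")
        for f in self.fixations:
            if f.side not in ("left", "right"):
                raise ValueError(f"fixation side must be left/right, got {f.side!r}")

    @property
    def choice01(self) -> int:
        """1 if right was chosen, 0 if left."""
        return 1 if self.choice == "right" else 0


@dataclass
class TrialDataset:
    """All trials of one participant in one experiment."""

    participant_id: str
    experiment: str  # "value" | "perceptual"
    trials: list = field(default_factory=list)
    block_structure: list = field(default_factory=list)  # [(block, frame), ...]

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_SCALES:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        frames = set(EXPERIMENT_FRAMES[self.experiment])
        for t in self.trials:
            if t.frame not in frames:
                raise ValueError(
                    f"trial frame {t.frame!r} does not belong to "
                    f"{self.experiment!r} experiment"
                )

    @property
    def scale(self) -> tuple:
        return EXPERIMENT_SCALES[self.experiment]

    def __len__(self) -> int:
        return len(self.trials)

    def subset(self, trials: Iterable[Trial]) -> "TrialDataset":
        return TrialDataset(self.participant_id, self.experiment, list(trials),
                            self.block_structure)

    def frame_subset(self, frame: str) -> "TrialDataset":
        return self.subset(t for t in self.trials if t.frame == frame)

    def even_trials(self) -> "TrialDataset":
        """Trials with even 1-based index — the fitting half."""
        return self.subset(t for t in self.trials if t.trial_index % 2 == 0)

    def odd_trials(self) -> "TrialDataset":
        """Trials with odd 1-based index — the prediction half."""
        return self.subset(t for t in self.trials if t.trial_index % 2 == 1)

    def rt_bounds(self) -> tuple:
        rts = [t.rt for t in self.trials]
        return (min(rts), max(rts))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append({
                "participant_id": self.participant_id,
                "experiment": self.experiment,
                "frame": t.frame,
                "block": t.block,
                "trial_index": t.trial_index,
                "r_left": t.r_left,
                "r_right": t.r_right,
                "dt_left_ms": t.dt_left,
                "dt_right_ms": t.dt_right,
                "rt_s": t.rt,
                "choice": t.choice,
                "confidence": t.confidence,
                "gsf": t.gsf if t.gsf is not None else len(t.fixations) - 1,
            })
        return pd.DataFrame(rows)

    def fixations_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            for k, f in enumerate(t.fixations):
                rows.append({
                    "participant_id": self.participant_id,
                    "trial_index": t.trial_index,
                    "fix_index": k,
                    "side": f.side,
                    "onset_ms": f.onset_ms,
                    "duration_ms": f.duration_ms,
                })
        return pd.DataFrame(
            rows, columns=["participant_id", "trial_index", "fix_index",
                           "side", "onset_ms", "duration_ms"])

    def arrays(self) -> dict:
        """Column arrays for vectorised likelihood work."""
        return {
            "r_left": np.array([t.r_left for t in self.trials], float),
            "r_right": np.array([t.r_right for t in self.trials], float),
            "dt_left": np.array([t.dt_left for t in self.trials], float),
            "dt_right": np.array([t.dt_right for t in self.trials], float),
            "choice": np.array([t.choice01 for t in self.trials], int),
            "rt": np.array([t.rt for t in self.trials], float),
            "frame": np.array([t.frame for t in self.trials], object),
            "trial_index": np.array([t.trial_index for t in self.trials], int),
        }


@dataclass(frozen=True)
class EvidenceTerms:
    """Intermediate quantities of the evidence pipeline for one trial."""

    g_left: float
    g_right: float
    a_left: float
    a_right: float
    rstar_left: float
    rstar_right: float
    r_left_scaled: float
    r_right_scaled: float


# ---------------------------------------------------------------------------
# Evidence pipeline
# ---------------------------------------------------------------------------

def goal_relevant_evidence(r, frame: str, scale_max: float, scale_min: float = 0.0):
    """Re-map raw evidence onto the goal-relevant scale for the given frame.

    ``like`` / ``most`` frames leave evidence untouched.  The ``dislike``
    frame mirrors the value scale (``scale_max - r``, so a £3 item becomes
    £0); the ``fewest`` frame mirrors the dot-count scale
    (``scale_max - r + scale_min``), so the fullest circle (133 dots) maps to
    the emptiest (40 dots).  Both transforms are involutions.
    """
    if frame not in _FRAMES:
        raise ValueError(f"unknown frame {frame!r}")
    r = np.asarray(r, dtype=float)
    if np.any(r < scale_min - 1e-9) or np.any(r > scale_max + 1e-9):
        bad = r[(r < scale_min - 1e-9) | (r > scale_max + 1e-9)]
        raise ValueError(
            f"evidence {np.atleast_1d(bad)[0]!r} outside scale "
            f"[{scale_min}, {scale_max}] for frame {frame!r}"
        )
    if frame in ("like", "most"):
        out = r
    elif frame == "dislike":
        out = scale_max - r
    else:  # fewest
        out = scale_max - r + scale_min
    return out if out.ndim else float(out)


def relative_gaze(dt_left, dt_right):
    """Relative dwell time g_i = DT_i / (DT_left + DT_right)."""
    dt_left = np.asarray(dt_left, dtype=float)
    dt_right = np.asarray(dt_right, dtype=float)
    if np.any(dt_left < 0) or np.any(dt_right < 0):
        raise ValueError("dwell times must be >= 0")
    total = dt_left + dt_right
    if np.any(total <= 0):
        raise ValueError("both dwell times are zero; flag or exclude the trial")
    g_left = dt_left / total
    if g_left.ndim:
        return g_left, 1.0 - g_left
    return float(g_left), float(1.0 - g_left)


def average_absolute_evidence(g, r, gamma):
    """Gaze-discounted average evidence A = g*r + (1-g)*gamma*r."""
    g = np.asarray(g, dtype=float)
    r = np.asarray(r, dtype=float)
    out = g * r + (1.0 - g) * gamma * r
    return out if out.ndim else float(out)


def relative_evidence_binary(a_left, a_right):
    """Binary relative evidence R*_i = A_i - A_j (antisymmetric)."""
    a_left = np.asarray(a_left, dtype=float)
    rstar_left = a_left - np.asarray(a_right, dtype=float)
    if rstar_left.ndim:
        return rstar_left, -rstar_left
    return float(rstar_left), float(-rstar_left)


def scaled_evidence(rstar, tau):
    """Logistic scaling R = 1 / (1 + exp(-tau * R*)); tau=0 gives 0.5."""
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    out = expit(tau * np.asarray(rstar, dtype=float))
    return out if out.ndim else float(out)


def compute_evidence_terms(trial: Trial, params: GlamParams, *,
                           scale: tuple | None = None,
                           apply_transform: bool = True) -> EvidenceTerms:
    """Run the full evidence pipeline for one trial."""
    if scale is None:
        scale = VALUE_SCALE if trial.frame in ("like", "dislike") else PERCEPTUAL_SCALE
    smin, smax = scale
    if apply_transform:
        e_left = goal_relevant_evidence(trial.r_left, trial.frame, smax, smin)
        e_right = goal_relevant_evidence(trial.r_right, trial.frame, smax, smin)
    else:
        e_left, e_right = trial.r_left, trial.r_right
    g_left, g_right = relative_gaze(trial.dt_left, trial.dt_right)
    a_left = average_absolute_evidence(g_left, e_left, params.gamma)
    a_right = average_absolute_evidence(g_right, e_right, params.gamma)
    rstar_left, rstar_right = relative_evidence_binary(a_left, a_right)
    return EvidenceTerms(
        g_left=g_left, g_right=g_right,
        a_left=a_left, a_right=a_right,
        rstar_left=rstar_left, rstar_right=rstar_right,
        r_left_scaled=scaled_evidence(rstar_left, params.tau),
        r_right_scaled=scaled_evidence(rstar_right, params.tau),
    )


def drift_rates(terms: EvidenceTerms, params: GlamParams) -> tuple:
    """Per-ms drifts (left, right) of the two accumulators."""
    return params.nu * terms.r_left_scaled, params.nu * terms.r_right_scaled


# ---------------------------------------------------------------------------
# Wald (inverse-Gaussian) first-passage time
# ---------------------------------------------------------------------------

def _ig_mu_scale(drift, sigma, boundary):
    """scipy.invgauss parameterisation for FPT mean b/d and shape (b/sigma)^2."""
    lam = (boundary / sigma) ** 2
    mean = boundary / drift
    return mean / lam, lam


def fpt_density(t, drift, sigma, boundary: float = 1.0):
    """Wald first-passage density at time ``t`` (same time unit as 1/drift).

    A diffusion with positive drift and noise SD ``sigma`` per sqrt-time-unit
    crosses the absorbing boundary at a Wald-distributed time with mean
    ``boundary/drift`` and shape ``(boundary/sigma)**2``.
    """
    drift = np.asarray(drift, dtype=float)
    if np.any(drift <= 0):
        raise ValueError("drift must be > 0 for a proper first-passage density")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    t = np.asarray(t, dtype=float)
    mu, lam = _ig_mu_scale(drift, sigma, boundary)
    out = np.where(t > 0, invgauss.pdf(np.maximum(t, 1e-300), mu, scale=lam), 0.0)
    return out if out.ndim else float(out)


def fpt_logpdf(t, drift, sigma, boundary: float = 1.0):
    mu, lam = _ig_mu_scale(np.asarray(drift, float), sigma, boundary)
    return invgauss.logpdf(t, mu, scale=lam)


def fpt_logsf(t, drift, sigma, boundary: float = 1.0):
    mu, lam = _ig_mu_scale(np.asarray(drift, float), sigma, boundary)
    return invgauss.logsf(t, mu, scale=lam)


def race_choice_probability(d_chosen, d_other, sigma, boundary: float = 1.0,
                            upper: float | None = None) -> float:
    """P(the ``chosen`` accumulator wins the race), by quadrature."""
    mu_c, lam = _ig_mu_scale(d_chosen, sigma, boundary)
    mu_o, _ = _ig_mu_scale(d_other, sigma, boundary)

    def integrand(t):
        return (invgauss.pdf(t, mu_c, scale=lam)
                * invgauss.sf(t, mu_o, scale=lam))

    if upper is None:
        upper = 50.0 * max(boundary / d_chosen, boundary / d_other)
    p, _err = integrate.quad(integrand, 0, upper, limit=200)
    return float(p)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _race_loglik(d_left, d_right, choice, rt_ms, sigma, boundary):
    """log density (per ms) of (choice, rt) under the pure Wald race."""
    d_chosen = np.where(choice == 1, d_right, d_left)
    d_other = np.where(choice == 1, d_left, d_right)
    return (fpt_logpdf(rt_ms, d_chosen, sigma, boundary)
            + fpt_logsf(rt_ms, d_other, sigma, boundary))


def trial_likelihood(trial: Trial, params: GlamParams,
                     rt_bounds: tuple, *,
                     scale: tuple | None = None,
                     apply_transform: bool = True,
                     contaminant_in_likelihood: bool = True) -> float:
    """Density (per second) of the observed (choice, rt) for one trial.

    The race term is the winning accumulator's Wald density times the losing
    accumulator's survival function; a uniform contaminant over
    choice x [rt_min, rt_max] is mixed in with weight ``contaminant_rate``.
    """
    lo, hi = rt_bounds
    if not hi > lo:
        raise ValueError(f"degenerate rt_bounds {rt_bounds}")
    terms = compute_evidence_terms(trial, params, scale=scale,
                                   apply_transform=apply_transform)
    d_left, d_right = drift_rates(terms, params)
    rt_ms = trial.rt * MS_PER_S
    race_per_s = MS_PER_S * np.exp(
        _race_loglik(np.asarray(d_left), np.asarray(d_right),
                     np.asarray(trial.choice01), rt_ms,
                     params.sigma, params.boundary))
    w = params.contaminant_rate if contaminant_in_likelihood else 0.0
    unif = 0.5 / (hi - lo) if lo <= trial.rt <= hi else 0.0
    return float((1.0 - w) * race_per_s + w * unif)


def dataset_nll(dataset: TrialDataset, params: GlamParams, *,
                apply_transform: bool = True,
                contaminant_in_likelihood: bool = True,
                rt_bounds: tuple | None = None) -> float:
    """Negative log likelihood of a participant's dataset (vectorised).

    Trials with zero total dwell time are excluded with a warning.  A trial
    with zero density makes the result +inf and a diagnostic warning lists
    the offending trial indices.
    """
    ll = pointwise_loglik(dataset, params, apply_transform=apply_transform,
                          contaminant_in_likelihood=contaminant_in_likelihood,
                          rt_bounds=rt_bounds)
    if ll.size == 0:
        return 0.0
    if np.any(np.isneginf(ll)):
        idx = np.flatnonzero(np.isneginf(ll))
        warnings.warn(f"zero-likelihood trials at positions {idx.tolist()}")
        return float("inf")
    return float(-np.sum(ll))


def pointwise_loglik(dataset: TrialDataset, params: GlamParams, *,
                     apply_transform: bool = True,
                     contaminant_in_likelihood: bool = True,
                     rt_bounds: tuple | None = None) -> np.ndarray:
    """Per-trial log likelihood (density per second), for NLL and WAIC."""
    if len(dataset) == 0:
        return np.empty(0)
    arr = dataset.arrays()
    keep = (arr["dt_left"] + arr["dt_right"]) > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} trial(s) with zero total dwell time")
    smin, smax = dataset.scale
    r_l, r_r = arr["r_left"][keep], arr["r_right"][keep]
    frames = arr["frame"][keep]
    if apply_transform:
        e_l = np.empty_like(r_l)
        e_r = np.empty_like(r_r)
        for fr in np.unique(frames):
            m = frames == fr
            e_l[m] = goal_relevant_evidence(r_l[m], fr, smax, smin)
            e_r[m] = goal_relevant_evidence(r_r[m], fr, smax, smin)
    else:
        e_l, e_r = r_l, r_r
    g_l, g_r = relative_gaze(arr["dt_left"][keep], arr["dt_right"][keep])
    a_l = average_absolute_evidence(g_l, e_l, params.gamma)
    a_r = average_absolute_evidence(g_r, e_r, params.gamma)
    rstar_l, _ = relative_evidence_binary(a_l, a_r)
    d_l = params.nu * scaled_evidence(rstar_l, params.tau)
    d_r = params.nu * scaled_evidence(-rstar_l, params.tau)
    rt_ms = arr["rt"][keep] * MS_PER_S
    log_race_s = np.log(MS_PER_S) + _race_loglik(
        d_l, d_r, arr["choice"][keep], rt_ms, params.sigma, params.boundary)
    # numerical overflow in extreme parameter corners -> zero race density
    log_race_s = np.where(np.isnan(log_race_s), -np.inf, log_race_s)
    w = params.contaminant_rate if contaminant_in_likelihood else 0.0
    if w == 0.0:
        return log_race_s
    if rt_bounds is None:
        rt_bounds = dataset.rt_bounds()
    lo, hi = rt_bounds
    if not hi > lo:
        raise ValueError(f"degenerate rt_bounds {rt_bounds}")
    in_bounds = (arr["rt"][keep] >= lo) & (arr["rt"][keep] <= hi)
    log_unif = np.where(in_bounds, np.log(0.5 / (hi - lo)), -np.inf)
    stacked = np.stack([np.log1p(-w) + log_race_s, np.log(w) + log_unif])
    return logsumexp(stacked, axis=0)
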