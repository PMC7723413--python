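"""Stochastic simulation of the GLAM race.

Two routes to the same race:

* ``simulate_choice_rt`` samples the two Wald first-passage times directly
  (exact under the constant-drift diffusion) — used for out-of-sample
  behavioural prediction.
* ``simulate_path`` integrates the two accumulators by Euler–Maruyama and
  records the state of both at the moment the winner crosses the boundary —
  needed for the balance of evidence Δe = |E_right - E_left| at crossing,
  the model's confidence proxy.

Both mix in the contaminant process (random choice, uniform RT over the
participant's observed RT range) with the model's contaminant weight.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MS_PER_S,
    GlamParams,
    Trial,
    TrialDataset,
    average_absolute_evidence,
    compute_evidence_terms,
    drift_rates,
    goal_relevant_evidence,
    relative_evidence_binary,
    relative_gaze,
    scaled_evidence,
)

__all__ = [
    "SimulationConfig",
    "PathResult",
    "sample_wald_fpt",
    "simulate_choice_rt",
    "simulate_race",
    "simulate_path",
    "simulate_paths",
    "out_of_sample_predict",
    "delta_e_table",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol settings for model simulation.

    Defaults follow the study protocol: 50 repetitions per trial for
    behavioural out-of-sample prediction, 10 repetitions per trial for the
    balance-of-evidence tables, 0.01 s Euler step.
    """

    n_reps_behaviour: int = 50
    n_reps_delta_e: int = 10
    dt: float = 0.01            # Euler step, seconds
    seed: int | None = None
    no_gaze_bias: bool = False
    max_time: float = 100.0     # runaway guard, seconds

    def __post_init__(self) -> None:
        if self.n_reps_behaviour < 1 or self.n_reps_delta_e < 1:
            raise ValueError("repetition counts must be >= 1")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class PathResult:
    """Outcome of one simulated accumulation path."""

    choice: str
    rt: float              # seconds
    e_final_left: float
    e_final_right: float
    delta_e: float
    contaminated: bool = False


def sample_wald_fpt(drift, sigma, boundary, rng, size=None):
    """Sample Wald first-passage times (same time unit as 1/drift)."""
    drift = np.asarray(drift, float)
    lam = (boundary / sigma) ** 2
    mean = boundary / drift
    # Michael-Schucany-Haas transform
    z = rng.standard_normal(size if size is not None else drift.shape)
    y = z ** 2
    x = (mean + mean ** 2 * y / (2 * lam)
         - mean / (2 * lam) * np.sqrt(4 * mean * lam * y + (mean * y) ** 2))
    u = rng.uniform(size=np.shape(x))
    return np.where(u <= mean / (mean + x), x, mean ** 2 / x)


def _dataset_evidence(dataset: TrialDataset, *, apply_transform=True,
                      no_gaze_bias=False):
    """Vectorised evidence pipeline for a whole dataset.

    Returns transformed per-side evidence, relative gaze, and the raw
    covariates (ΣValue, |ΔValue| on the untransformed scale) used by the
    Δe regressions.
    """
    arr = dataset.arrays()
    smin, smax = dataset.scale
    r_l, r_r = arr["r_left"], arr["r_right"]
    frames = arr["frame"]
    if apply_transform:
        e_l = np.empty_like(r_l)
        e_r = np.empty_like(r_r)
        for fr in np.unique(frames):
            m = frames == fr
            e_l[m] = goal_relevant_evidence(r_l[m], fr, smax, smin)
            e_r[m] = goal_relevant_evidence(r_r[m], fr, smax, smin)
    else:
        e_l, e_r = r_l.copy(), r_r.copy()
    if no_gaze_bias:
        g_l = np.full(len(r_l), 0.5)
        g_r = g_l
    else:
        g_l, g_r = relative_gaze(arr["dt_left"], arr["dt_right"])
    return {"e_left": e_l, "e_right": e_r, "g_left": g_l, "g_right": g_r,
            "sum_evidence": r_l + r_r, "abs_diff_evidence": np.abs(r_r - r_l),
            "frame": frames, "trial_index": arr["trial_index"]}


def _drifts(ev, params: GlamParams):
    a_l = average_absolute_evidence(ev["g_left"], ev["e_left"], params.gamma)
    a_r = average_absolute_evidence(ev["g_right"], ev["e_right"], params.gamma)
    rstar_l, _ = relative_evidence_binary(a_l, a_r)
    d_l = params.nu * scaled_evidence(rstar_l, params.tau)
    d_r = params.nu * scaled_evidence(-rstar_l, params.tau)
    return d_l, d_r


def simulate_race(d_left, d_right, params: GlamParams, rng,
                  rt_bounds: tuple | None = None):
    """Sample (choice01, rt_s, contaminated) for arrays of per-ms drifts."""
    d_left = np.asarray(d_left, float)
    t_l = sample_wald_fpt(d_left, params.sigma, params.boundary, rng)
    t_r = sample_wald_fpt(np.asarray(d_right, float), params.sigma,
                          params.boundary, rng)
    choice = (t_r < t_l).astype(int)
    rt_s = np.minimum(t_l, t_r) / MS_PER_S
    contaminated = np.zeros(d_left.shape, bool)
    w = params.contaminant_rate
    if w > 0:
        if rt_bounds is None:
            raise ValueError("rt_bounds required when contaminant_rate > 0")
        lo, hi = rt_bounds
        contaminated = rng.uniform(size=d_left.shape) < w
        n_bad = int(contaminated.sum())
        if n_bad:
            choice = np.where(contaminated,
                              rng.integers(0, 2, size=d_left.shape), choice)
            rt_s = np.where(contaminated,
                            rng.uniform(lo, hi, size=d_left.shape), rt_s)
    return choice, rt_s, contaminated


def simulate_choice_rt(trial: Trial, params: GlamParams, rng, *,
                       rt_bounds: tuple | None = None,
                       scale: tuple | None = None,
                       apply_transform: bool = True):
    """Simulate one (choice, rt, contaminated) outcome for a trial."""
    terms = compute_evidence_terms(trial, params, scale=scale,
                                   apply_transform=apply_transform)
    d_l, d_r = drift_rates(terms, params)
    c, rt, bad = simulate_race(np.array([d_l]), np.array([d_r]), params, rng,
                               rt_bounds=rt_bounds)
    return ("right" if c[0] else "left", float(rt[0]), bool(bad[0]))


def simulate_paths(d_left, d_right, params: GlamParams, rng, *,
                   dt: float = 0.01, max_time: float = 100.0):
    """Euler–Maruyama race for arrays of per-ms drifts.

    Returns (choice01, rt_s, e_left, e_right) at the crossing step.  When
    both accumulators cross in the same step the larger overshoot wins.
    Paths that fail to cross within ``max_time`` are resampled once, then
    raise.
    """
    d_left = np.atleast_1d(np.asarray(d_left, float))
    d_right = np.atleast_1d(np.asarray(d_right, float))
    n = d_left.shape[0]
    out_choice = np.full(n, -1)
    out_rt = np.full(n, np.nan)
    out_el = np.full(n, np.nan)
    out_er = np.full(n, np.nan)
    todo = np.arange(n)
    for attempt in range(2):
        if todo.size == 0:
            break
        c, rt, el, er, crossed = _run_paths(
            d_left[todo], d_right[todo], params, rng, dt, max_time)
        done = todo[crossed]
        out_choice[done] = c[crossed]
        out_rt[done] = rt[crossed]
        out_el[done] = el[crossed]
        out_er[done] = er[crossed]
        todo = todo[~crossed]
    if todo.size:
        raise RuntimeError(
            f"{todo.size} path(s) failed to reach the boundary within "
            f"{max_time} s after resampling")
    return out_choice, out_rt, out_el, out_er


def _run_paths(d_left, d_right, params, rng, dt, max_time):
    n = d_left.shape[0]
    dt_ms = dt * MS_PER_S
    step_sd = params.sigma * np.sqrt(dt_ms)
    var_step = step_sd ** 2
    mu_l = d_left * dt_ms
    mu_r = d_right * dt_ms
    b = params.boundary
    e_l = np.zeros(n)
    e_r = np.zeros(n)
    choice = np.full(n, -1)
    rt = np.full(n, np.nan)
    fin_l = np.full(n, np.nan)
    fin_r = np.full(n, np.nan)
    active = np.arange(n)
    max_steps = int(np.ceil(max_time / dt))
    for step in range(1, max_steps + 1):
        k = active.size
        if k == 0:
            break
        prev_l = e_l[active].copy()
        prev_r = e_r[active].copy()
        e_l[active] = prev_l + mu_l[active] + step_sd * rng.standard_normal(k)
        e_r[active] = prev_r + mu_r[active] + step_sd * rng.standard_normal(k)
        # Brownian-bridge correction: an excursion may touch the boundary
        # inside the step even when the endpoint stays below it; ignoring
        # those excursions biases first-passage times upward by O(sigma*sqrt(dt)).
        cl = _crossed(prev_l, e_l[active], b, var_step, rng)
        cr = _crossed(prev_r, e_r[active], b, var_step, rng)
        hit = cl | cr
        if np.any(hit):
            idx = active[hit]
            left_hit = cl[hit]
            right_hit = cr[hit]
            both = left_hit & right_hit
            # tie: larger overshoot wins (bridge-crossers sit below b,
            # so an endpoint-crosser beats them deterministically)
            win_right = np.where(
                both, e_r[idx] - b > e_l[idx] - b, right_hit)
            choice[idx] = win_right.astype(int)
            rt[idx] = step * dt
            # bridge-crossers end the step below b: lift them to the boundary
            fin_l[idx] = np.where(win_right, e_l[idx], np.maximum(e_l[idx], b))
            fin_r[idx] = np.where(win_right, np.maximum(e_r[idx], b), e_r[idx])
            active = active[~hit]
    crossed = choice >= 0
    return choice, rt, fin_l, fin_r, crossed


def _crossed(prev, new, b, var_step, rng):
    """Did the path touch the boundary during this step (bridge-corrected)?"""
    endpoint = new >= b
    below = ~endpoint
    out = endpoint.copy()
    if np.any(below):
        gap = (b - prev[below]) * (b - new[below])
        p_touch = np.exp(-2.0 * np.maximum(gap, 0.0) / var_step)
        out[below] = rng.uniform(size=int(below.sum())) < p_touch
    return out


def simulate_path(trial: Trial, params: GlamParams,
                  config: SimulationConfig, rng, *,
                  rt_bounds: tuple | None = None,
                  scale: tuple | None = None,
                  apply_transform: bool = True) -> PathResult:
    """Simulate one accumulation path for a trial and return its Δe."""
    w = params.contaminant_rate
    if w > 0 and rng.uniform() < w:
        if rt_bounds is None:
            raise ValueError("rt_bounds required when contaminant_rate > 0")
        lo, hi = rt_bounds
        return PathResult(
            choice="right" if rng.integers(0, 2) else "left",
            rt=float(rng.uniform(lo, hi)),
            e_final_left=np.nan, e_final_right=np.nan,
            delta_e=np.nan, contaminated=True)
    terms = compute_evidence_terms(trial, params, scale=scale,
                                   apply_transform=apply_transform)
    if config.no_gaze_bias:
        terms = compute_evidence_terms(
            replace_gaze(trial), params, scale=scale,
            apply_transform=apply_transform)
    d_l, d_r = drift_rates(terms, params)
    c, rt, el, er = simulate_paths(d_l, d_r, params, rng,
                                   dt=config.dt, max_time=config.max_time)
    return PathResult(choice="right" if c[0] else "left", rt=float(rt[0]),
                      e_final_left=float(el[0]), e_final_right=float(er[0]),
                      delta_e=float(abs(er[0] - el[0])), contaminated=False)


def replace_gaze(trial: Trial) -> Trial:
    """Copy of a trial with the dwell-time split forced to 50/50."""
    total = trial.dt_left + trial.dt_right
    return Trial(frame=trial.frame, r_left=trial.r_left, r_right=trial.r_right,
                 dt_left=total / 2, dt_right=total / 2, choice=trial.choice,
                 rt=trial.rt, confidence=trial.confidence,
                 trial_index=trial.trial_index, block=trial.block)


def out_of_sample_predict(dataset_odd: TrialDataset, params: GlamParams,
                          config: SimulationConfig, rng, *,
                          apply_transform: bool = True) -> pd.DataFrame:
    """Per-trial predicted choice frequencies and mean RTs.

    Each held-out (odd-numbered) trial is re-simulated ``n_reps_behaviour``
    times with the participant's fitted parameters, contaminant reps
    included, and aggregated into P(choose right) and mean RT.
    """
    ev = _dataset_evidence(dataset_odd, apply_transform=apply_transform,
                           no_gaze_bias=config.no_gaze_bias)
    d_l, d_r = _drifts(ev, params)
    n_trials = d_l.shape[0]
    reps = config.n_reps_behaviour
    rt_bounds = dataset_odd.rt_bounds() if params.contaminant_rate > 0 else None
    D_l = np.repeat(d_l, reps)
    D_r = np.repeat(d_r, reps)
    choice, rt, contaminated = simulate_race(D_l, D_r, params, rng,
                                             rt_bounds=rt_bounds)
    choice = choice.reshape(n_trials, reps)
    rt = rt.reshape(n_trials, reps)
    contaminated = contaminated.reshape(n_trials, reps)
    return pd.DataFrame({
        "participant_id": dataset_odd.participant_id,
        "trial_index": ev["trial_index"],
        "frame": ev["frame"],
        "p_choose_right": choice.mean(axis=1),
        "mean_rt": rt.mean(axis=1),
        "n_reps": reps,
        "n_contaminated": contaminated.sum(axis=1),
        "sum_evidence": ev["sum_evidence"],
        "abs_diff_evidence": ev["abs_diff_evidence"],
        "diff_evidence_transformed": ev["e_right"] - ev["e_left"],
    })


def delta_e_table(dataset_odd: TrialDataset, params: GlamParams,
                  config: SimulationConfig, rng, *,
                  apply_transform: bool = True) -> pd.DataFrame:
    """Balance-of-evidence table: one row per (trial x repetition).

    Δe is taken from Euler path simulation at the moment of crossing.
    Covariates ΣValue and |ΔValue| are computed from the raw, untransformed
    evidence so frame effects stay interpretable.  Contaminated reps carry
    Δe = NaN and are flagged (they are excluded from the Δe regressions).
    """
    ev = _dataset_evidence(dataset_odd, apply_transform=apply_transform,
                           no_gaze_bias=config.no_gaze_bias)
    d_l, d_r = _drifts(ev, params)
    n_trials = d_l.shape[0]
    reps = config.n_reps_delta_e
    D_l = np.repeat(d_l, reps)
    D_r = np.repeat(d_r, reps)
    n_total = D_l.shape[0]
    w = params.contaminant_rate
    contaminated = (rng.uniform(size=n_total) < w) if w > 0 else np.zeros(n_total, bool)
    choice = np.empty(n_total, int)
    rt = np.empty(n_total)
    delta_e = np.full(n_total, np.nan)
    clean = ~contaminated
    if clean.any():
        c, r, el, er = simulate_paths(D_l[clean], D_r[clean], params, rng,
                                      dt=config.dt, max_time=config.max_time)
        choice[clean] = c
        rt[clean] = r
        delta_e[clean] = np.abs(er - el)
    if contaminated.any():
        lo, hi = dataset_odd.rt_bounds()
        k = int(contaminated.sum())
        choice[contaminated] = rng.integers(0, 2, size=k)
        rt[contaminated] = rng.uniform(lo, hi, size=k)
    return pd.DataFrame({
        "participant_id": dataset_odd.participant_id,
        "trial_index": np.repeat(ev["trial_index"], reps),
        "frame": np.repeat(ev["frame"], reps),
        "rep": np.tile(np.arange(reps), n_trials),
        "delta_e": delta_e,
        "sim_rt": rt,
        "sim_choice": np.where(choice == 1, "right", "left"),
        "sum_evidence": np.repeat(ev["sum_evidence"], reps),
        "abs_diff_evidence": np.repeat(ev["abs_diff_evidence"], reps),
        "contaminated": contaminated,
    })
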