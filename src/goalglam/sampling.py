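"""Normative model of goal-dependent information acquisition.

An agent faces ``n`` options with unknown values ``v_i ~ N(mu, sigma_mu^2)``
i.i.d. and has observed one noisy signal per item, ``x_i = v_i + eps_i``
with ``eps_i ~ N(0, sigma_eps^2)``.  Beliefs update by conjugate-normal
Bayes.  The agent may buy one extra signal about a single item before
committing.

Two goals are compared:

* *selection* — pick the single best item; the value of resampling item
  ``i`` is the expected maximum posterior mean after the extra signal.
* *elimination* — discard one item and keep the average of the rest; the
  value of resampling is the expected kept-average after discarding
  optimally.

The model's predictions: for selection the optimal extra signal targets the
currently best or second-best item (and the two are exactly tied); for
elimination it targets the worst or second-worst.  With n = 2 every item is
equally worth resampling.  ``verify_propositions`` checks these equalities
and strict inequalities numerically over random signal configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SamplingProblem",
    "posterior_beliefs",
    "value_of_resampling_best",
    "value_of_resampling_eliminate",
    "verify_propositions",
]


@dataclass(frozen=True)
class SamplingProblem:
    """Prior, signal noise, and the first-round signals (one per item)."""

    prior_mean: float
    prior_var: float
    noise_var: float
    signals: tuple

    def __post_init__(self) -> None:
        if self.prior_var <= 0 or self.noise_var <= 0:
            raise ValueError("variances must be positive")
        if len(self.signals) < 2:
            raise ValueError("need at least two items")

    @property
    def n(self) -> int:
        return len(self.signals)


def posterior_beliefs(problem: SamplingProblem):
    """Posterior mean per item and the (shared) posterior variance after one
    signal each: conjugate-normal update."""
    x = np.asarray(problem.signals, float)
    sv, nv = problem.prior_var, problem.noise_var
    means = (nv * problem.prior_mean + sv * x) / (sv + nv)
    var = 1.0 / (1.0 / sv + 1.0 / nv)
    return means, float(var)


def _second_signal_geometry(problem: SamplingProblem, i: int):
    """Linear map y -> updated mean of item i, plus predictive sd of y."""
    means, var = posterior_beliefs(problem)
    sv, nv = problem.prior_var, problem.noise_var
    x = np.asarray(problem.signals, float)
    prec2 = 1.0 / sv + 2.0 / nv
    # mean after two signals on i: (mu/sv + (x_i + y)/nv) / prec2
    intercept = (problem.prior_mean / sv + x[i] / nv) / prec2
    slope = (1.0 / nv) / prec2
    pred_sd = np.sqrt(var + nv)   # predictive sd of the second signal
    return means, intercept, slope, float(means[i]), pred_sd


def _expect_over_signal(fn, center, sd, method, n_nodes, n_draws, rng):
    if method == "quadrature":
        t, w = np.polynomial.hermite.hermgauss(n_nodes)
        y = center + np.sqrt(2.0) * sd * t
        return float(np.sum(w * fn(y)) / np.sqrt(np.pi))
    if method == "mc":
        rng = np.random.default_rng() if rng is None else rng
        y = center + sd * rng.standard_normal(n_draws)
        return float(np.mean(fn(y)))
    raise ValueError(f"unknown method {method!r}")


def value_of_resampling_best(problem: SamplingProblem, i: int, *,
                             method: str = "quadrature", n_nodes: int = 64,
                             n_draws: int = 1_000_000, rng=None) -> float:
    """V(i): expected maximum posterior mean after one extra signal on ``i``.

    Computed by Gauss-Hermite quadrature over the predictive distribution of
    the second signal (``method='mc'`` gives the Monte-Carlo cross-check,
    ``method='closed'`` the exact two-term formula)."""
    means, a, b, m_i, sd = _second_signal_geometry(problem, i)
    others = np.delete(means, i)
    c = float(others.max())
    if method == "closed":
        # E[max(c, A + B z)] with z ~ N(0,1): exact
        A = a + b * m_i
        B = b * sd
        z0 = (c - A) / B
        return float(c * norm.cdf(z0) + A * norm.sf(z0) + B * norm.pdf(z0))
    fn = lambda y: np.maximum(c, a + b * y)
    return _expect_over_signal(fn, m_i, sd, method, n_nodes, n_draws, rng)


def value_of_resampling_eliminate(problem: SamplingProblem, i: int, *,
                                  method: str = "quadrature", n_nodes: int = 64,
                                  n_draws: int = 1_000_000, rng=None) -> float:
    """V-hat(i): expected kept-average after discarding the worst-looking
    item once the extra signal on ``i`` is in."""
    means, a, b, m_i, sd = _second_signal_geometry(problem, i)
    others = np.delete(means, i)
    c_min = float(others.min()) if others.size else np.inf
    total_others = float(others.sum())
    n = problem.n

    if method == "closed":
        A = a + b * m_i
        B = b * sd
        z0 = (c_min - A) / B
        # E[min(c_min, A + B z)]
        emin = float(c_min * norm.sf(z0) + A * norm.cdf(z0) - B * norm.pdf(z0))
        emean_i = A  # martingale: E[updated mean] = current mean
        return (total_others + emean_i - emin) / (n - 1)

    def fn(y):
        m2 = a + b * y
        kept = total_others + m2 - np.minimum(c_min, m2)
        return kept / (n - 1)

    return _expect_over_signal(fn, m_i, sd, method, n_nodes, n_draws, rng)


def _check_ordering(vals_quad, vals_exact, top_two, rest, tol, margin):
    """Equality of the top two and strictness over the rest.

    Equality is asserted on the quadrature values within ``tol``.  A strict
    inequality is asserted only when the *exact* (closed-form) gap exceeds
    ``margin`` — i.e. when the ordering is resolvable at quadrature
    accuracy; unresolvable near-ties are suspended and reported.
    """
    a, b = top_two
    eq = abs(vals_quad[a] - vals_quad[b]) <= tol
    suspended = False
    strict = True
    for j in rest:
        exact_gap = min(vals_exact[a], vals_exact[b]) - vals_exact[j]
        if exact_gap < margin:
            suspended = True
            continue
        if not (vals_quad[a] - vals_quad[j] > tol
                and vals_quad[b] - vals_quad[j] > tol):
            strict = False
    return bool(eq), bool(strict), bool(suspended)


def verify_propositions(ns=(2, 3, 4, 5), n_configs: int = 100, *,
                        prior_mean: float = 0.0, prior_var: float = 1.0,
                        noise_var: float = 1.0, tol: float = 1e-3,
                        strict_margin: float | None = None,
                        n_nodes: int = 64, rng=None) -> pd.DataFrame:
    """Numerically check the two optimal-resampling propositions.

    For each random signal configuration the verifier asserts, conditional
    on the signals: (selection) V(best) = V(second-best) within ``tol`` and
    strictly greater than every other V(i); (elimination) V-hat(worst) =
    V-hat(second-worst) within ``tol`` and strictly greater than the rest.
    Values are computed by Gauss-Hermite quadrature; a strictness check is
    suspended (and reported) when the exact gap is smaller than
    ``strict_margin`` (default ``2 * tol``), i.e. below what quadrature
    accuracy can resolve.  With n = 2 all values must coincide.
    """
    rng = np.random.default_rng() if rng is None else rng
    margin = 2 * tol if strict_margin is None else strict_margin
    sig_sd = np.sqrt(prior_var + noise_var)
    rows = []
    for n in ns:
        for cfg in range(n_configs):
            x = prior_mean + sig_sd * rng.standard_normal(n)
            prob = SamplingProblem(prior_mean, prior_var, noise_var, tuple(x))
            means, _ = posterior_beliefs(prob)
            order_desc = np.argsort(-means)
            V = np.array([value_of_resampling_best(prob, i, n_nodes=n_nodes)
                          for i in range(n)])
            Vx = np.array([value_of_resampling_best(prob, i, method="closed")
                           for i in range(n)])
            Vh = np.array([value_of_resampling_eliminate(prob, i, n_nodes=n_nodes)
                           for i in range(n)])
            Vhx = np.array([value_of_resampling_eliminate(prob, i, method="closed")
                            for i in range(n)])
            if n == 2:
                sel_eq = abs(V[0] - V[1]) <= tol
                sel_strict, sel_susp = True, False
                eli_eq = abs(Vh[0] - Vh[1]) <= tol
                eli_strict, eli_susp = True, False
            else:
                sel_eq, sel_strict, sel_susp = _check_ordering(
                    V, Vx, (order_desc[0], order_desc[1]), order_desc[2:],
                    tol, margin)
                eli_eq, eli_strict, eli_susp = _check_ordering(
                    Vh, Vhx, (order_desc[-1], order_desc[-2]), order_desc[:-2],
                    tol, margin)
            rows.append({
                "n": n, "config": cfg,
                "selection_equality": bool(sel_eq),
                "selection_strict": bool(sel_strict),
                "selection_suspended": bool(sel_susp),
                "elimination_equality": bool(eli_eq),
                "elimination_strict": bool(eli_strict),
                "elimination_suspended": bool(eli_susp),
                "passed": bool(sel_eq and sel_strict and eli_eq and eli_strict),
            })
    return pd.DataFrame(rows)
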