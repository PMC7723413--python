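# Methods

This note records the modelling assumptions, parameter conventions and
design choices behind `goalglam`, and what the synthetic-data experiments
can and cannot show.

## The accumulator model

The GLAM is a linear stochastic race: each option accumulates evidence with
constant drift `ν·R_i` and Gaussian increments of standard deviation `σ`
until one accumulator reaches the boundary (fixed at 1). `R_i` is built
from the trial-level relative gaze `g_i = DT_i / (DT_left + DT_right)` and
the goal-relevant evidence `r_i` through the gaze discount
`A_i = g_i r_i + (1−g_i) γ r_i`, the binary relative evidence
`R*_i = A_i − A_j`, and the logistic scaling `R_i = 1/(1+e^{−τR*_i})`.
The model deliberately ignores within-trial attentional dynamics: gaze
enters only as the whole-trial dwell ratio, which is what licenses the
constant-drift assumption and the analytic first-passage likelihood.

**First-passage form.** With constant drift the crossing time of one
accumulator is Wald (inverse-Gaussian) with mean `b/(ν R_i)` and shape
`(b/σ)²`. The joint density of (choice, RT) is the winner's Wald density
times the loser's survival function; summed over choices and integrated
over time it is exactly 1 because both drifts are positive (`R_i ∈ (0,1)`).

**Time units.** The accumulator operates per millisecond: `ν` is evidence
per ms, `σ` evidence per √ms. This convention makes the conventional
uniform priors (`ν ~ U(1e-10, 0.01)`) compatible with realistic response
times — e.g. `ν = 5e-4`, `R ≈ 0.6` gives a mean first passage of ~3.3 s.
Response times cross every public API in seconds; the conversion lives in
`core.py` only. The Euler path-simulation step is 0.01 s (10 ms).

**Contaminant process.** A mixture component with weight 0.05 describes
lapses: choice uniform over {left, right}, RT uniform over the
participant's observed [min, max]. It is applied both in simulation and —
by default, switchable — inside the likelihood. Contaminated simulation
repetitions carry no defined balance of evidence and are excluded from the
Δe regressions (flag retained).

**Degenerate inputs.** Trials with zero total dwell time cannot enter the
likelihood (relative gaze undefined); they are excluded with a warning.
Non-decision time is not a model parameter (an optional offset would be
straightforward but is deliberately absent from the default model).

## Path simulation and the balance of evidence

`simulate_paths` integrates both accumulators by Euler–Maruyama and applies
a Brownian-bridge correction within each step: an excursion can touch the
boundary even when the step's endpoint lies below it, with probability
`exp(−2(b−E_prev)(b−E_new)/(σ²Δt))`. Without the correction, first-passage
times are biased upward by O(σ√Δt), which at a 10 ms step is large enough
to fail a KS ≤ 0.02 comparison against the exact Wald race; with it, 1e5
paths agree with exact Wald sampling at KS ≈ 0.007. When both accumulators
cross in the same step the larger overshoot wins (a measure-zero event in
the continuum; the deterministic rule keeps runs reproducible). Paths that
fail to cross within 100 s are resampled once, then raise.

Δe = |E_right − E_left| at the crossing step is the confidence proxy. A
bridge-crossing winner is lifted to the boundary; the loser's level is its
step endpoint.

## Estimation

Fitting is per participant and per frame, on **even-numbered trials only**
(1-based indexing, so the held-out odd set includes the first trial);
prediction and Δe simulation use the odd trials. Priors are uniform:
`ν ~ U(1e-10, 0.01)`, `γ ~ U(−1, 1)` (a config switch restricts to [0, 1]),
`σ ~ U(1e-10, 5)`, `τ ~ U(0, 5)`.

Two modes share one likelihood:

* **map** — multistart L-BFGS-B on the negative log posterior in a
  rescaled space (`log10 ν`, `γ`, `log10 σ`, `τ`), followed by a Laplace
  approximation at the mode whose draws feed WAIC. Finite-difference
  Hessians are clipped and their eigenvalues floored at 0.25 so that flat
  directions yield prior-scale, not unbounded, proposal spread; draws are
  rejected/clipped to the prior support. Deterministic given a seed, ~1 s
  per 500-trial fit.
* **mcmc** — emcee's affine-invariant ensemble sampler (16 walkers,
  tune/draw counts mirroring the 4-chain/1000-tune/2000-draw convention),
  with the walker ensemble split into four pseudo-chains for Gelman–Rubin
  R̂ and ESS via arviz. A fit with |R̂−1| ≥ 0.05 or ESS ≤ 100 on any
  parameter is *flagged*, not raised.

WAIC is computed on the deviance scale from the pointwise log likelihood
over posterior draws (`−2(lppd − p_waic)`, lower is better). Model
comparison (goal-relevant vs untransformed evidence) requires bitwise
identical trial sets. For the perceptual task, fits first drop RT outliers
(> 3 within-participant SDs or > 20 s).

At an identifiable operating point (`ν = 5e-4`, `σ = 0.01`, `τ = 1.5`,
`γ = 0.3`; 500 trials) MAP recovery is tight (γ within ±0.1, τ within
±10%). Identifiability collapses when accumulated noise dominates drift
(e.g. `σ ≈ 0.8` per √ms): choices approach chance and γ/τ become
unrecoverable at any desk-scale trial count — recovery claims in the tests
are therefore made in the identifiable regime.

## Synthetic experiments

The generator reproduces the two designs' printed structure exactly:

* **Value task** — 60 items with bids Uniform(0, 3) rounded to £0.01 (a
  Beta(2,2) alternative is available; the uniform default maximises design
  feasibility and is not data-derived), median split, 15 high-high +
  15 low-low + 30 mixed pairs, each pair twice per frame with sides
  counterbalanced, 6 alternating blocks of 40 (240 trials, 120 per frame),
  and the rule that a block's last pair never opens the next block.
* **Perceptual task** — numerosity levels 50/80/110, ten difference levels
  (2–20% in 2% steps), circle counts `round(N ± N·d/200)` so the pair
  differs by d% of the level and every count stays inside the 40–133
  evidence scale, distractor dots at 80% of the level (40/64/88). Each
  condition appears four times per frame (two side arrangements × two
  repetitions), giving the same 240-trial, 6-block structure and the
  33,600-row Δe protocol at 28 participants.

**Gaze.** Fixations strictly alternate sides from a random start with
Gamma-distributed durations (mean 400 ms, shape 3). During an initial
600 ms unbiased window both sides share the base mean; afterwards the mean
duration on the goal-relevant item (higher *transformed* evidence) is
scaled to `2·share` and the other side to `2·(1−share)`, so the long-run
dwell share toward the goal item equals `share` (default 0.60). The race's
gaze input is the dwell ratio over the first 2.5 s of the stream — a window
matched to typical RTs — and the recorded dwell times come from truncating
the stream at the simulated RT. The two therefore share trial-level
variability (which is what lets dwell-time differences predict simulated
choice, as in real data) but are not identical; the residual discrepancy
acts as mild measurement noise on gaze and slightly attenuates fitted γ on
fully synthetic datasets.

**Confidence** is an affine map of Δe (default `2 + 6·Δe` plus N(0, 1)
noise) rounded and clipped to a 1–10 rating scale; the endpoints are a
declared convention, not an inference. Contaminated trials draw a uniform
rating.

**Default participant parameters** are drawn per participant:
`ν ~ U(3.5e-4, 6.5e-4)`, `γ ~ U(0.1, 0.5)`, `σ ~ U(0.008, 0.014)`, and
`τ ~ U(0.7, 1.6)` for the £-scale task or `τ ~ U(0.03, 0.08)` for the
dot-scale task (τ trades off against the evidence scale; these choices put
accuracy near 0.85 and 0.67 respectively, in the range typical of such
tasks). Each participant receives an independent child RNG stream spawned
from the master seed, so adding participants never perturbs earlier ones
and seeded runs are bit-reproducible.

**What passing tests do and do not show.** The generator reproduces the
qualitative structure the analyses assume — goal-contingent gaze bias after
random initial exploration, GLAM-consistent choices/RTs, Δe-linked
confidence — but not saccade kinematics, within-trial attentional dynamics
(the aDDM's territory), item identity/satiety effects, or empirical bid
distributions. Sign-flip results on synthetic data demonstrate that the
pipeline detects the effects *when present as modelled*, not that human
data contain them.

## Behavioural analyses

Hierarchical mixed-effects models are replaced throughout by a two-stage
scheme: per-participant fits on within-participant z-scored predictors,
then a group-level one-sample t-test per coefficient. This preserves every
sign/flip inference at desk scale without a mixed-model solver. Logistic
fits that separate fall back to an L2-penalised fit (penalty 1.0 on
z-scored predictors) and are flagged.

The Δe regression is pooled OLS of `Δe ~ |ΔValue| + simulated RT + ΣValue`
with predictors z-scored within participant, contaminated repetitions
excluded, and ΣValue/|ΔValue| always computed from *raw* (untransformed)
values so frame effects remain interpretable; accumulation itself uses
transformed evidence. GSF is omitted from the simulated-confidence model
because the model carries no gaze dynamics.

The fixation time series pools all trials over participants, bins gaze
position (0 = left, 1 = right) at 10 ms over a 2 s post-onset window
without temporal normalisation, and correlates each bin with the raw
evidence difference. The between-frame permutation test shuffles **frame
labels across trials** (the stricter exchangeable null; an
instantaneous-sample shuffle is available as `mode="instant"`), builds a
200-draw null for the per-bin correlation difference, corrects with
Benjamini–Hochberg at q ≤ 0.01 (BH chosen over BY), and flags only runs of
at least 6 consecutive significant bins (60 ms). Bins with fewer than 10
contributing trials in either frame are reported but never flagged.
Permutation p-values are bounded below by 1/(n_perm+1).

## Optimal information sampling

The normative model is conjugate-normal: values `v_i ~ N(μ, σ_μ²)` i.i.d.,
signals `x_i = v_i + ε_i`, `ε_i ~ N(0, σ_ε²)`. After one signal per item,
the value of resampling item `i` is, for the selection goal, the expected
maximum posterior mean after the extra signal; for the elimination goal the
expected kept-average after discarding the posterior-worst item. Both
reduce to expectations of a two-piece linear function of the predictive
signal, computed by 64-node Gauss–Hermite quadrature, with an exact
two-term closed form and a 10⁶-draw Monte-Carlo estimator as independent
cross-checks.

The verifier asserts, conditional on every sampled signal configuration:
selection values tie at the top two and strictly dominate the rest;
elimination values tie at the bottom two and strictly dominate the rest;
with n = 2 all values coincide. Equalities are asserted at 1e-3 — the
kinked integrand limits 64-node quadrature to ~1e-4 accuracy, and numpy's
Hermite weights overflow beyond ~256 nodes, so tighter claims would be
spurious. Strictness is asserted only where the exact closed-form gap
exceeds 2e-3; genuinely unresolvable near-ties are suspended and reported
rather than failed.

## Numerical conventions and limitations

* Wald sampling uses the Michael–Schucany–Haas transform; likelihood
  corners that overflow (e.g. σ near its 1e-10 prior edge) are mapped to
  zero race density and absorbed by the contaminant mixture.
* The pipeline's provenance headers (`# seed=…, config_hash=…`) ride on
  comment lines that pandas skips; the config hash excludes output paths.
* Problem sizes in the test suite (10–31 synthetic participants, 100–200
  permutations, 1e5 simulation paths) match the simulation protocol's
  printed totals where those exist (37,200 and 33,600 Δe rows) and
  otherwise are chosen as the smallest sizes at which the checked effects
  are stable across seeds.
* Known limitations: binary choice only (no multi-alternative race); no
  collapsing bounds or non-decision time; gaze generation is a descriptive
  stand-in for real scan paths; the ΣValue→Δe effect in the value task is
  genuinely small at the protocol scale (|t| ≈ 2–5), so single-seed runs
  near the significance boundary are expected.
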