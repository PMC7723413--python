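# goalglam

Gaze-weighted accumulator modelling of **goal-framed binary choice**.

When people choose between two options — snacks they have bid on, or circles
filled with dots — they look longer at the option that matters for the task
at hand. If asked which item they *like most* they gaze at the higher-value
item; if asked which they would *reject*, or which circle holds *fewer*
dots, the same people gaze at the lower-value option. `goalglam` implements
a computational account of this behaviour and the analyses needed to detect
it, end to end on synthetic data: a Gaze-weighted Linear Accumulator Model
(GLAM) driven by *goal-relevant* evidence, balance-of-evidence confidence,
Bayesian parameter estimation with out-of-sample prediction, the
behavioural/eye-tracking statistics, and a normative model of optimal
information sampling.

## The model

Each option `i ∈ {left, right}` races toward a fixed boundary (b = 1):

```
E_i(t) = E_i(t-1) + ν·R_i + ε_t,     ε_t ~ N(0, σ)
```

where `R_i` condenses the trial's evidence and gaze:

```
A_i  = g_i·r_i + (1 − g_i)·γ·r_i          gaze-discounted evidence
R*_i = A_i − A_j                          relative evidence (binary choice)
R_i  = 1 / (1 + exp(−τ·R*_i))             logistic scaling
```

`g_i` is the relative dwell time on option `i`, `γ ∈ [−1, 1]` the
multiplicative discount on the unattended option, `ν` the drift scaling,
`σ` the accumulator noise, and `τ` the evidence sensitivity. Because the
drift is constant within a trial, first-passage times are Wald
(inverse-Gaussian) distributed and the choice/RT likelihood is analytic:
winner's density × loser's survival function, mixed with a 5% uniform
contaminant.

The key ingredient is **goal-relevant evidence**: in frames that ask for
the *least* wanted option the raw evidence is mirrored before it enters the
race — `r_dislike = 3 − r_like` on the £0–3 bid scale and
`r_fewest = 133 − r_most + 40` on the 40–133 dot scale — so the
to-be-selected option always carries the larger evidence.

The **balance of evidence** `Δe = |E_right(t_final) − E_left(t_final)|` at
the moment of crossing serves as a confidence proxy. Because attention
multiplies evidence, Δe grows with the summed value of the options in
like/most frames and shrinks in dislike/fewest frames — a sign flip that
vanishes when gaze is forced to be symmetric, and which the package's
simulations reproduce.

A separate module implements the normative companion model: a Bayesian
agent with one noisy signal per item who may buy one more signal. Choosing
the *best* item makes resampling the current top two items (exactly
equally) optimal; choosing which item to *discard* flips the target to the
bottom two.

## Worked example

```python
import numpy as np
import goalglam as gg

rng = np.random.default_rng(0)

# one synthetic participant in the value task
params = gg.GlamParams(nu=5e-4, gamma=0.3, sigma=0.01, tau=1.2)
ds = gg.generate_dataset(gg.ValueDesign(), [params], rng)[0]
print(f"{len(ds)} trials, frames: {sorted(set(t.frame for t in ds.trials))}")

# fit the dislike frame on even-numbered trials (MAP mode)
fit = gg.fit_participant(ds.even_trials(), "dislike", gg.SamplerConfig(seed=1))
print("recovered:", {k: round(v, 4) for k, v in fit.map_estimate.items()})
print("WAIC:", round(fit.waic, 1))

# simulate the balance of evidence on held-out odd trials
tab = gg.delta_e_table(ds.odd_trials().frame_subset("dislike"), fit.params,
                       gg.SimulationConfig(), rng)
print(f"delta-e rows: {len(tab)}, mean delta-e: {tab.delta_e.mean():.3f}")
```

prints

```
240 trials, frames: ['dislike', 'like']
recovered: {'nu': 0.0006, 'gamma': 0.0057, 'sigma': 0.0086, 'tau': 0.8528}
WAIC: 241.4
delta-e rows: 600, mean delta-e: 0.603
```

The participant completes 240 trials (120 per frame, six alternating blocks
of 40). Fitting uses only the 120 even-numbered trials; the 60 held-out odd
dislike trials are each re-simulated 10 times (600 rows), and the mean Δe of
about 0.6 — on the boundary scale of 1 — is the model's average confidence
signal for those choices. `nu`, `sigma` and `tau` land near the generating
values; γ is less sharply identified from a single 120-trial frame, which is
why the full analyses pool 30+ participants.

A full pipeline (synthesise → fit → simulate → analyse → verify) is one
call, or one shell command:

```bash
goalglam run-all --experiment value --participants 4 --seed 7 --out-dir demo_run
goalglam verify-sampling --configs 100 --seed 1 --out sampling_report.csv
```

## Layout

| module | contents |
|---|---|
| `goalglam.core` | data types, evidence pipeline, analytic Wald-race likelihood |
| `goalglam.simulate` | Wald sampling, Euler paths with bridge correction, Δe protocol |
| `goalglam.fit` | MAP/Laplace and ensemble-MCMC estimation, WAIC, recovery studies |
| `goalglam.synth` | experiment designs, goal-biased gaze, full synthetic datasets |
| `goalglam.analysis` | two-stage regressions, gaze influence, fixation time series, permutation/FDR |
| `goalglam.sampling` | normative optimal-information-acquisition model and verifier |
| `goalglam.io` / `goalglam.cli` | trial-table formats, pipeline orchestration, CLI |

See `docs/methods.md` for modelling assumptions, units, tunable parameters
and known limitations.
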