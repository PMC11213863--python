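# msddm

Hierarchical drift-diffusion analysis of multisensory decision-making
across the adult lifespan.

## What this is for

In a two-alternative audiovisual categorisation task (face vs car;
visual, auditory or audiovisual stimuli at high or low phase coherence),
older and younger adults differ not just in speed and accuracy but in the
latent components of the decision process. This package implements the
full analysis chain that separates those components with a hierarchical
Bayesian drift-diffusion model (DDM), for researchers studying
multisensory integration and ageing:

* **synthetic cohorts** — a generative model of the 216-trial design
  (3 blocks × 72; V/A/AV × HC/LC × face/car; 3000 ms deadline) with
  age-structured diffusion parameters and exact ground truth, so every
  downstream stage is testable without behavioural data;
* **preprocessing** — the 50%-accuracy participant criterion and the
  per-participant median ± 2.5 MAD response-time filter, with exact
  accounting;
* **hierarchical fitting** — the eight accuracy-coded model variants (each
  subset of {δ, θ, τ} free to vary over condition × coherence × age
  group), sampled by adaptive Metropolis-within-Gibbs with interweaved
  non-centered moves, under the study protocol of 5 chains × 11,000
  iterations (1,000 burn-in, thinned by 2 → 25,000 retained draws);
* **diagnostics** — classic Gelman–Rubin Ȓ against the 1.02 threshold,
  DIC model comparison (ΔDIC > 10 = substantial), highest-density
  regions, and quantitative posterior predictive checks;
* **multisensory metrics** — AV−V contrasts, the optimal-combination
  drift gap, the measure of inverse effectiveness (MoIE), and their
  Pearson correlations with age;
* **power analysis** — noncentral-F sample-size computation for the
  behavioural regressions.

## The model

Evidence on each trial accumulates as a Wiener process with drift δ
(evidence/s) and unit diffusion coefficient between absorbing boundaries
0 and θ, starting at z·θ with z fixed at ½; response time is the
first-passage time plus non-decision time τ. Accuracy coding maps the
upper boundary to the correct response. The likelihood is the Wiener
first-passage-time joint density f(t, boundary | δ, θ, τ), evaluated by
the standard small-time/large-time series with adaptive truncation.
Participant-level parameters are drawn from group-level normal
distributions per conditional-dependency cell — at most 12 group means
per parameter family (V/A/AV × HC/LC × older/younger adults).

Derived quantities follow the multisensory-integration literature: the
audiovisual drift is compared with the optimal combination of the
unisensory drifts, `δ_AV − √(δ_V² + δ_A²)`, and inverse effectiveness is
quantified as `(X_LC^AV − X_LC^US) − (X_HC^AV − X_HC^US)` with the best
unisensory cell (highest δ, lowest θ, lowest τ) as reference.

## Worked example

```python
from msddm import (WienerParams, choice_probability, mean_decision_time,
                   simulate_trials)

p = WienerParams(delta=2.0, theta=1.5, tau=0.3)
print(choice_probability(p, "upper"))   # 0.9526
print(mean_decision_time(p))            # 0.3394 s
rt, correct, _ = simulate_trials(p, 100_000, deadline_ms=30_000, seed=3)
print(correct.mean())                   # 0.9521
```

A drift of 2 evidence/s against a 1.5-unit boundary yields a 95.3%
correct rate in closed form and a mean decision time of 339 ms
((θ/2δ)·tanh(δθ/2)); 100,000 simulated trials reproduce both to
Monte-Carlo precision (0.9521, 341 ms).

The `examples/` directory walks through every capability as a short
narrative script; for instance `python examples/05_model_selection_and_ppc.py`
fits the no-variation and all-varying variants to the same synthetic
cohort and prints

```
variant 1 (          none): DIC    1758.8  (D_bar    1739.9, pD   18.9)
variant 8 (delta+theta+tau): DIC    1346.5  (D_bar    1258.5, pD   88.0)

selected: variant_8  (ΔDIC to runner-up 412.3, substantial: True)
```

— the data were generated with cell-varying parameters, so the
all-varying variant wins by far more than the 10-unit threshold, at the
cost of a larger effective parameter count pD.

`python examples/07_power_analysis.py` prints the a-priori sample size
for the behavioural regressions: three predictors, f² = 0.10, α = .05,
power .95 → **N = 176** (power 0.9504 at 176, 0.9492 at 175).

A complete run — simulate, preprocess, fit, diagnose, predictive check,
metrics — is one call (or `msddm run` from the shell):

```python
from msddm import RunConfig, run_pipeline
run_pipeline(RunConfig(seed=1, out_dir="run", n_participants=8,
                       variants=(8,), n_chains=3, n_iter=1500, burn_in=500))
```

which writes the trial tables, posterior draws, diagnostics, predictive
check and benefit correlations into `run/` with a MANIFEST of checksums.

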