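# destchoice

Multinomial-logit modelling of pedestrian destination choice, built around a
virtual experiment: participants plan a five-destination trip through an
environment with six labelled destinations (A–F), choosing one destination at
a time while a hypothetical time budget ticks down. Each choice costs

```
T(j) = w_d · d + w_o · o + ε,      ε ~ N(μ, σ²)
```

hypothetical minutes, where `d` is the distance to the chosen destination,
`o` its current head-count (occupancy), and `w_d`, `w_o` the environment's
cost weights. Destinations cannot be revisited, so the choice set shrinks as
the trip progresses; the trip ends after five choices or when the budget runs
out.

The package is for researchers in pedestrian dynamics and discrete choice who
want to analyse such sequential stated-choice data — or to study the analysis
pipeline itself on synthetic cohorts with known ground truth.

## The model

Each decision is a multinomial-logit choice over the available destinations.
The utility of alternative *i* is

```
U_i = β_occ · n̂_i + β_dist · d̂_i  [+ β_des · q̂_i]
```

with choice probability `P_i = exp(U_i) / Σ_j exp(U_j)`. Predictors are
normalised per decision by the maximum over the alternatives at that
decision, so each lies in [0, 1] and the coefficients compare relative effect
strengths. The optional third term applies when participants plan (or are
given) a destination **schedule**: the destination at 1-based position *p* of
the remaining schedule has raw desirability `q = e^(−p)`, visited
destinations are removed from the schedule, off-schedule destinations get
zero, and `β_des ≥ 0` measures schedule adherence pressure.

On top of the model the package provides:

- **Calibration** — bounded maximum-likelihood fits (Nelder-Mead simplex by
  default, L-BFGS-B with the analytic score for resampling loops), AIC, and
  the zero-parameter random-model reference AIC.
- **Inference** — percentile bootstrap confidence intervals (participant or
  decision resampling), a permutation test for between-condition coefficient
  differences (statistic: sum of squared coefficient differences), and the
  likelihood-ratio test for the desirability term.
- **Clustering** — two participant-clustering procedures: thresholding a
  bimodal per-participant cumulative quantity, and hierarchical clustering of
  per-individual coefficient estimates; both evaluated by summed-cluster AIC
  against the aggregate fit.
- **Schedule adherence** — Levenshtein distance between planned schedules and
  realised destination sequences.
- **Simulation** — a full in-silico replica of the experiment
  (`simulate_cohort`) producing trajectories plus a ground-truth sidecar, for
  parameter-recovery and null-calibration studies.

Three synthetic environments ship with the package (`open`, `closed`,
`photo`); their distance and occupancy tables are invented values that obey
the experiment's structural constraints (integer distances in [0, 10],
positive integer occupancies, budgets of 60 or 15 hypothetical minutes) and
are **not** any study's recorded tables.

## Worked example

```python
from destchoice import (CohortSpec, ModelParams, bundled_environment,
                        bootstrap_ci, fit_mle, random_model_aic, simulate_cohort)

env = bundled_environment("open")
spec = CohortSpec(
    n=166, environment=env, condition="base",
    components=((ModelParams(-3.95, -0.40), 1.0),), seed=7,
)
trajectories, _ = simulate_cohort(spec)
fit = fit_mle(trajectories)
boot = bootstrap_ci(trajectories, B=2000, seed=7)
print(f"decisions: {fit.n_observations}")
print(f"beta_occ  = {fit.params.beta_occ:+.2f}  95% CI {boot.intervals['beta_occ']}")
print(f"beta_dist = {fit.params.beta_dist:+.2f}  95% CI {boot.intervals['beta_dist']}")
print(f"fitted AIC = {fit.aic:.1f}   random AIC = {random_model_aic(trajectories):.1f}")
```

prints

```
decisions: 825
beta_occ  = -3.97  95% CI (-4.420384106796714, -3.538886564081041)
beta_dist = -0.32  95% CI (-0.6231693761363585, -0.011637100316761545)
fitted AIC = 1613.7   random AIC = 2177.4
```

166 simulated participants made 825 recorded decisions (a few trips overran
the 60-minute budget before the fifth choice). The fitted busyness
coefficient `β_occ = −3.97` recovers the generating value −3.95 — crowded
destinations are strongly avoided — and `β_dist = −0.32` recovers −0.40, a
weaker aversion to distant destinations; both bootstrap intervals cover the
truth. The fitted AIC improves on the random (all-zero-coefficient) model by
roughly 560 units, so the model explains far more than chance.

A command-line interface mirrors the stages:

```sh
destchoice simulate --env open --n 100 --seed 1 --out cohort.csv
destchoice fit --input cohort.csv
destchoice bootstrap --input cohort.csv -B 10000 --seed 1
destchoice permtest --a base.csv --b closed.csv --n-perm 10000
destchoice cluster-hier --input cohort.csv --cut 1.75
destchoice adherence --input schedule_cohort.csv
destchoice run-all --n 150 --seed 1 --out report/
```

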