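# Methods

This note documents the statistical machinery in `destchoice`: the model, its
estimation and inference procedures, what the synthetic-data generator does
and does not emulate, and the numerical and design choices made where the
procedure was genuinely open.

## The choice model

Every recorded decision is one data point. At decision *j* a participant at
position *s* faces the set of not-yet-visited destinations; alternative *i*
carries three raw predictors: distance `d(s, i)` (integer, arbitrary units in
[0, 10]), occupancy `o(j, i)` (positive integer head-count, a function of the
decision index only), and — in schedule conditions — desirability
`q = e^(−p)` for 1-based position *p* in the participant's remaining
schedule. Each predictor is normalised **per decision** by its maximum over
the alternatives at that decision; an all-zero predictor stays all-zero
(no signal rather than division by zero). Utilities are linear,

    U_i = β_occ n̂_i + β_dist d̂_i [+ β_des q̂_i],

and choice probabilities are the softmax of the utilities, computed with a
max-utility shift so extreme coefficients cannot overflow. `β_des` is
constrained non-negative: it measures adherence to a plan, and a negative
value would mean systematically doing the plan's opposite.

Two desirability conventions are implemented, because the zero-for-absent
rule and the standard six-destination worked example (which assigns `e^(−6)`
to the destination missing from a five-entry schedule) contradict each other
in the source material. The default `rule` variant zeroes off-schedule
destinations; the `worked_example` variant appends them to the schedule's
tail before positions are assigned. They coincide whenever the schedule
covers every destination. Similarly, `q̂` normalisation is per-decision by
default (consistent with `n̂` and `d̂`); no formula for it is given in the
source analysis.

## Calibration

Coefficients are estimated by direct maximisation of the log-likelihood
inside a box (default ±20 per coefficient, `β_des` floored at 0). The default
optimiser is Nelder-Mead from the null start `(0, 0[, 0.1])` with tolerances
1e−8 and at most 2000 iterations — matching a default-settings generic
optimiser — with the box enforced by clip-and-penalise. An L-BFGS-B option
using the analytic multinomial-logit score (`x_chosen − E_p[x]` summed over
decisions) handles the resampling loops, where tens of thousands of refits
are needed; the two optimisers agree to ~1e−4 on cohort-sized data. The box
matters mostly for per-individual fits: with at most five decisions the
likelihood often separates perfectly and the unconstrained MLE diverges, so
estimates pinned at ±20 are expected, legitimate output there. The bound's
magnitude is consistent with the largest per-cluster coefficient magnitudes
reported for this kind of data (≈ −17).

Model fit is summarised by AIC = 2k − 2 logL (k = 2, or 3 with the
desirability term). The reference "random model" fixes all coefficients at
zero; its log-likelihood is Σ_j ln(1/m_j) with m_j the choice-set size at
decision j — the recorded (shrinking) set size by default, or a fixed
six-option set under the `full` policy, in which case the AIC has the closed
form 2N ln 6 + 2k_random. Both policies are supported because published
random-model AICs for this experiment are consistent with the full-set
convention even though the experiment forbids revisits; `k_random` defaults
to 0.

## Inference

**Bootstrap.** Percentile intervals from B resampled refits. The resampling
unit defaults to the participant (whole trajectories), preserving
within-participant dependence; decision-level resampling is available for
sensitivity checks. Replicates that fail to converge are redrawn up to a
retry cap, after which the result is flagged. Measured over 50 simulated
cohorts (n = 200, β = (−4, −0.5), B = 500), the intervals cover the truth at
a rate inside [0.90, 0.99] (see `tests/test_acceptance.py`).

**Permutation test.** Statistic: Σ_k (β̂_k^A − β̂_k^B)². Permutations
re-allocate participants between the two conditions keeping both sample
sizes fixed. The p-value is the proportion of permuted statistics ≥ the
observed one (ties count as exceeding); a zero count is reported at the
test's resolution 1/n_perm, so p ∈ (0, 1]. Internally participants are
pooled in sorted-id order and the smaller group's size is drawn first, which
makes the p-value exactly invariant to swapping the group labels. Note the
exchangeability caveat: cohorts simulated with *independent* shared-noise
realisations are not exchangeable across groups (participants within a
cohort share a noise realisation), so null-calibration studies split a
single simulated cohort — mirroring the experiment, where both compared
conditions see one pre-computed noise realisation per environment.

**Likelihood-ratio test.** 2·ΔlogL between the three- and two-parameter fits
of the same data, referred to χ² with df = Δk. Because `β_des` sits on the
boundary of its parameter space under the null, the plain χ²(1) reference is
conservative; the ½χ²₀ + ½χ²₁ mixture is available via
`boundary_mixture=True`. If the nested fit beats the full fit beyond
tolerance the test raises and asks for a refit seeded at the nested solution
rather than silently clamping.

All stochastic procedures draw from a single seeded generator per call and
embed the seed in their result objects.

## Clustering

**Threshold clustering.** Per participant, the chosen alternatives' raw
distance (or occupancy) is summed over decisions and divided by the decision
count, so short and full trips are comparable (raw values, not the
per-decision-normalised predictors — the quantity lives on the original
scale). The cohort's histogram (default 20 equal-width bins) is tested for
bimodality: the two highest local maxima must each hold ≥ 5% of the sample
and be separated by a valley whose lowest bin is ≤ ½ of the smaller mode.
These prominence requirements are this package's design — a bare
two-local-maxima rule declares modes on nearly every jagged unimodal
histogram at n ≈ 200. If bimodal, the midpoint of the two modes' bin centres
is the threshold and participants split below/at-or-above it; otherwise no
clustering is attempted.

**Calibration clustering.** The model is fitted per participant and the
estimate vectors are clustered agglomeratively (Euclidean distance).
Complete linkage is the default, matching the reference implementation's
default; single, average and Ward are available. For *recovery* studies —
deciding which of two known behavioural components each participant belongs
to — Ward linkage is the recommended setting: per-individual estimates from
five decisions are noisy and box-bounded, and a two-cluster complete-linkage
cut tends to split off a small outlier fringe instead of the two components
(agreement ≈ 0.6 versus ≥ 0.8 for Ward on two-component mixtures with
β_occ = −8 vs −1). Cluster labels are renumbered by decreasing size, making
assignments independent of input order. Participants whose individual fit
fails to converge are excluded from the assignment (and hence from the
clustered comparison).

**Clustered vs aggregate AIC.** The clustered model's AIC is the sum of the
per-cluster AICs over every non-empty cluster, singletons included; the
comparison fit on all assigned participants uses the same model
specification. A single all-inclusive cluster reproduces the aggregate AIC
exactly; a random split of a homogeneous cohort costs ≈ 2k penalty units.

## Schedule adherence

Plain Levenshtein distance (unit-cost substitutions, insertions, deletions;
no transpositions) between the planned schedule and the realised chosen
sequence, computed by a two-row dynamic programme and validated in the test
suite against an independent edit-distance library on every sequence pair of
length ≤ 4 over the six-letter alphabet. Insertions/deletions matter because
trips cut short by the budget are shorter than the five-entry schedule. The
summary reports per-participant distances, their histogram and mean;
participants without a schedule are excluded and listed.

## The synthetic-data generator

`simulate_cohort` replays the experiment's mechanics: up to five sequential
choices sampled from the model's probabilities over the shrinking choice
set, desirability re-indexed as destinations are visited, and the budget
decremented by `w_d d + w_o o + ε` after each choice. A choice that overruns
the budget is still recorded before the trip ends (participants committed to
it before learning they were out of time); a flag drops it instead. Noise is
realised once per (decision, position, destination) per environment and
shared by all participants by default — two participants making the same
choices experience identical remaining times, as in the experiment — with
fresh per-participant draws available for general simulation studies.
Mixture cohorts draw each participant's true coefficients from weighted
components; a sidecar records the truth for recovery tests.

Schedules: the `given` policy hands everyone one fixed sequence (default
"DEBAC"); the `chosen` policy stands in for the participant's planning step
with a uniformly random ordered 5-subset of destinations — no behavioural
model of plan formation is claimed. Conditions and sample sizes used in the
validation studies follow the experiment: six destinations, budgets of 60
minutes (open/closed) and 15 minutes (photo), noise ε ~ N(0, 2) and
N(1.5, 0.75) respectively (variance parametrisation; the stored
`noise_sigma` is the standard deviation), and cohort sizes of 112–166
participants per condition.

What the generator does **not** emulate: the published experiment's actual
distance/occupancy tables and cost weights (the shipped environment files
are invented, structurally valid stand-ins), learning effects across
repeated attempts, demographic covariates, plan-formation behaviour, and any
dynamic crowd movement (absent from the experiment itself). Tests passing on
synthetic cohorts therefore validate the *pipeline* — estimator
consistency, interval coverage, test calibration, clustering recovery — not
any substantive claim about real pedestrians.

## Problem sizes in the validation suite

The test suite's simulation studies use 50 cohorts of 200 participants for
recovery/coverage (B = 500 bootstrap replicates), 200 runs at 200
permutations for null calibration of the permutation test, 200 runs for the
LRT null, and n = 200 two-component mixtures for clustering recovery; the
acceptance script uses the per-condition published sample sizes with
B = 2000 and 2000 permutations, and reports the clustering-recovery summary
as the median over 10 replicate mixtures. These sizes give stable rates
(binomial 99% bands) while keeping a full run in the minutes range on one
CPU.

## Known limitations

- Per-individual fits on ≤ 5 decisions are dominated by the box bound under
  separation; downstream clustering treats the estimates as behavioural
  fingerprints, not as consistent estimates.
- The percentile bootstrap makes no small-sample correction (no BCa).
- The permutation p-value's `count/n_perm` convention is mildly
  anticonservative (expected rejection ≈ α + 1/(n_perm+1) under the null);
  the effect is negligible at n_perm = 10⁴.
- Threshold clustering's bimodality rule is heuristic; with few participants
  (< ~100) its detection power is limited, and the bin count (default 20)
  influences which modes are found.
- The `full` choice-set policy is provided for the random-model reference
  only; simulating with it can produce revisits, which the trajectory
  container rejects by design.
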