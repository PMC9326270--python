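"""Resampling-based inference on the calibrated choice model.

Three procedures:

* percentile bootstrap confidence intervals for the coefficient estimates,
  resampling participants (whole trajectories) with replacement by default so
  within-participant dependence is preserved;
* a permutation test for a difference in choice behaviour between two
  experimental conditions, using the sum of squared coefficient differences
  as the statistic and re-allocating participants between conditions while
  keeping each condition's participant count fixed;
* a likelihood-ratio test for whether the schedule-desirability term improves
  fit, with the statistic 2*(logL_full - logL_nested) referred to a
  chi-squared distribution.

All procedures draw from a single seeded generator and record the seed in the
result, so every interval and p-value is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2

from .calibration import DEFAULT_BOUND, MODEL_SPECS, FitResult, fit_arrays
from .model import DecisionArrays, ParticipantTrajectory

__all__ = [
    "BootstrapResult",
    "PermutationResult",
    "LRTResult",
    "bootstrap_ci",
    "permutation_test",
    "likelihood_ratio_test",
]

_PARAM_NAMES = {2: ("beta_occ", "beta_dist"), 3: ("beta_occ", "beta_dist", "beta_des")}


@dataclass(frozen=True)
class BootstrapResult:
    B: int
    level: float
    intervals: dict[str, tuple[float, float]]
    estimates: dict[str, float]
    seed: int
    unit: str
    n_failed: int = 0
    flagged: bool = False

    def covers(self, name: str, value: float) -> bool:
        lo, hi = self.intervals[name]
        return lo <= value <= hi


@dataclass(frozen=True)
class PermutationResult:
    observed_statistic: float
    n_permutations: int
    p_value: float
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    boundary_mixture: bool = False


def _arrays_for(trajectories: Sequence[ParticipantTrajectory], model_spec: str) -> DecisionArrays:
    try:
        k = MODEL_SPECS[model_spec]
    except KeyError:
        raise ValueError(f"unknown model_spec {model_spec!r}") from None
    return DecisionArrays.from_trajectories(trajectories, k=k)


def bootstrap_ci(
    trajectories: Iterable[ParticipantTrajectory],
    model_spec: str = "two_param",
    B: int = 10_000,
    level: float = 0.95,
    unit: str = "participant",
    seed: int = 0,
    method: str = "lbfgs",
    bounds: float = DEFAULT_BOUND,
    max_retries: int = 100,
) -> BootstrapResult:
    """Percentile bootstrap intervals for the coefficient estimates.

    Units (participants by default, single decisions optionally) are
    resampled with replacement to the original unit count and the model is
    refit on each replicate; the interval per coefficient is the
    (1±level)/2 percentile pair of the replicate estimates.  Replicates whose
    fit does not converge are redrawn, up to ``max_retries`` extra draws in
    total; exceeding the cap flags the result.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    trajectories = list(trajectories)
    arrays = _arrays_for(trajectories, model_spec)
    rng = np.random.default_rng(seed)
    point = fit_arrays(arrays, method=method, bounds=bounds)
    init = point.params.as_array()

    n_units = (
        len(arrays.participant_ids) if unit == "participant" else arrays.n_decisions
    )
    if unit not in ("participant", "decision"):
        raise ValueError(f"unknown bootstrap unit {unit!r}")

    replicates = np.empty((B, arrays.k))
    failures = 0
    b = 0
    while b < B:
        codes = rng.integers(0, n_units, size=n_units)
        if unit == "participant":
            sample = arrays.subset_participants(codes)
        else:
            sample = DecisionArrays(
                X=arrays.X[codes],
                mask=arrays.mask[codes],
                chosen=arrays.chosen[codes],
                participant=arrays.participant[codes],
                participant_ids=arrays.participant_ids,
            )
        fit = fit_arrays(sample, init=init, method=method, bounds=bounds)
        if fit.converged:
            replicates[b] = fit.params.as_array()
            b += 1
        else:
            failures += 1
            if failures > max_retries:
                replicates[b] = fit.params.as_array()  # keep, but flag
                b += 1
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(replicates, alpha, axis=0)
    hi = np.quantile(replicates, 1.0 - alpha, axis=0)
    names = _PARAM_NAMES[arrays.k]
    return BootstrapResult(
        B=B,
        level=level,
        intervals={n: (float(l), float(h)) for n, l, h in zip(names, lo, hi)},
        estimates=dict(zip(names, map(float, init))),
        seed=seed,
        unit=unit,
        n_failed=failures,
        flagged=failures > max_retries,
    )


def _sum_sq_diff(a: np.ndarray, b: np.ndarray) -> float:
    return float(((a - b) ** 2).sum())


def permutation_test(
    group_a: Iterable[ParticipantTrajectory],
    group_b: Iterable[ParticipantTrajectory],
    model_spec: str = "two_param",
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "lbfgs",
    bounds: float = DEFAULT_BOUND,
) -> PermutationResult:
    """Permutation test for a between-condition difference in coefficients.

    The statistic is the sum of squared differences between the two groups'
    coefficient estimates.  Each permutation re-allocates participants
    between the groups uniformly at random while keeping both groups'
    participant counts (and hence the overall amount of data per condition)
    fixed, and refits both groups.  The p-value is the proportion of
    permutations with a statistic at least as large as the observed one (ties
    count as exceeding); a count of zero is reported at the test's
    resolution, 1/n_perm.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    k = MODEL_SPECS[model_spec]
    membership = {t.participant_id: 0 for t in group_a}
    for t in group_b:
        if t.participant_id in membership:
            raise ValueError(
                f"participant id {t.participant_id!r} appears in both groups"
            )
        membership[t.participant_id] = 1
    # canonical pooled order (sorted by participant id) makes the permutation
    # stream, and hence the p-value, exactly invariant to swapping the groups
    pooled = sorted(group_a + group_b, key=lambda t: t.participant_id)
    arrays = DecisionArrays.from_trajectories(pooled, k=k)
    n_total = len(pooled)
    side = np.array([membership[pid] for pid in arrays.participant_ids])
    m_small = int(min((side == 0).sum(), (side == 1).sum()))

    def both_fits(ca: np.ndarray, cb: np.ndarray) -> float:
        fa = fit_arrays(arrays.subset_participants(ca), method=method, bounds=bounds)
        fb = fit_arrays(arrays.subset_participants(cb), method=method, bounds=bounds)
        if not (fa.converged and fb.converged):
            raise _NonConvergent
        return _sum_sq_diff(fa.params.as_array(), fb.params.as_array())

    observed = both_fits(np.flatnonzero(side == 0), np.flatnonzero(side == 1))
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    retries = 0
    while done < n_perm:
        perm = rng.permutation(n_total)
        try:
            stat = both_fits(perm[:m_small], perm[m_small:])
        except _NonConvergent:
            retries += 1
            if retries > n_perm:  # give up redrawing; treat as non-exceeding
                done += 1
            continue
        if stat >= observed:
            count += 1
        done += 1
    p = max(count, 1) / n_perm
    return PermutationResult(
        observed_statistic=observed, n_permutations=n_perm, p_value=p, seed=seed
    )


class _NonConvergent(Exception):
    pass


def likelihood_ratio_test(
    fit_full: FitResult, fit_nested: FitResult, boundary_mixture: bool = False
) -> LRTResult:
    """Likelihood-ratio test between nested fits of the same data.

    The statistic is 2*(logL_full - logL_nested) on df = k_full - k_nested
    degrees of freedom.  Because beta_des is constrained non-negative its
    null value sits on the parameter boundary; the plain chi-squared
    reference (default) is then conservative-anticonservative in the usual
    way, and ``boundary_mixture=True`` uses the ½·χ²₀ + ½·χ²₁ mixture
    instead (df must be 1).
    """
    if fit_full.k <= fit_nested.k:
        raise ValueError("full model must have more parameters than nested model")
    if fit_full.n_observations != fit_nested.n_observations:
        raise ValueError("fits must be on the same data")
    stat = 2.0 * (fit_full.max_log_likelihood - fit_nested.max_log_likelihood)
    if stat < -1e-6:
        raise ValueError(
            "nested log-likelihood exceeds full log-likelihood; refit the full "
            "model initialised at the nested solution"
        )
    stat = max(stat, 0.0)
    df = fit_full.k - fit_nested.k
    if boundary_mixture:
        if df != 1:
            raise ValueError("boundary mixture reference requires df = 1")
        p = 1.0 if stat == 0.0 else 0.5 * float(chi2.sf(stat, 1))
    else:
        p = float(chi2.sf(stat, df))
    return LRTResult(statistic=stat, df=df, p_value=p, boundary_mixture=boundary_mixture)
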