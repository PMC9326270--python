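"""Maximum-likelihood calibration of the destination-choice model.

Fits are performed by direct maximisation of the multinomial-logit
log-likelihood inside a box.  The default optimiser is the derivative-free
Nelder-Mead simplex started from the null model (0, 0[, 0.1]); an L-BFGS-B
option with the analytic gradient is provided for the resampling loops, where
thousands of refits are needed.  The non-negativity of the schedule
coefficient beta_des is enforced by the box lower bound (clip-and-penalise
under the simplex).  Model fit is summarised by the Akaike information
criterion, AIC = 2k - 2 logL, with one data point per recorded decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .model import DecisionArrays, ModelParams, ParticipantTrajectory

__all__ = ["FitResult", "fit_mle", "fit_arrays", "random_model_aic",
           "DEFAULT_BOUND", "MODEL_SPECS"]

DEFAULT_BOUND = 20.0
MODEL_SPECS = {"two_param": 2, "three_param": 3}

_PENALTY = 1e6  # simplex clip-and-penalise weight per unit of box violation²


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood calibration."""

    params: ModelParams
    max_log_likelihood: float
    n_observations: int
    k: int
    aic: float
    converged: bool
    init: tuple[float, ...]
    method: str
    n_iterations: int

    def __post_init__(self) -> None:
        expected = 2.0 * self.k - 2.0 * self.max_log_likelihood
        if not math.isclose(self.aic, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("aic must equal 2k - 2*logL")

    def to_dict(self) -> dict:
        return {
            "beta_occ": self.params.beta_occ,
            "beta_dist": self.params.beta_dist,
            "beta_des": self.params.beta_des,
            "log_likelihood": self.max_log_likelihood,
            "n_observations": self.n_observations,
            "k": self.k,
            "aic": self.aic,
            "converged": self.converged,
            "method": self.method,
        }


def _default_init(k: int) -> np.ndarray:
    return np.array([0.0, 0.0, 0.1][:k])


def _box(k: int, bounds: float | Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    if np.isscalar(bounds):
        box = [(-float(bounds), float(bounds))] * k
    else:
        box = [tuple(map(float, b)) for b in bounds]
    if k == 3:
        lo, hi = box[2]
        box[2] = (max(lo, 0.0), hi)  # beta_des >= 0
    return box


def fit_arrays(
    arrays: DecisionArrays,
    init: Sequence[float] | None = None,
    bounds: float | Sequence[tuple[float, float]] = DEFAULT_BOUND,
    method: str = "nelder-mead",
) -> FitResult:
    """Fit on a pre-built array view (used by the resampling loops)."""
    k = arrays.k
    x0 = np.asarray(init, dtype=float) if init is not None else _default_init(k)
    if x0.shape != (k,):
        raise ValueError(f"init must have {k} components")
    box = _box(k, bounds)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])

    if method == "nelder-mead":
        def neg_ll(beta: np.ndarray) -> float:
            clipped = np.clip(beta, lo, hi)
            penalty = _PENALTY * float(((beta - clipped) ** 2).sum())
            return -arrays.log_likelihood(clipped) + penalty

        res = minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
        )
        beta = np.clip(res.x, lo, hi)
        ll = arrays.log_likelihood(beta)
        converged = bool(res.success)
        n_iter = int(res.nit)
    elif method == "lbfgs":
        def neg_ll_grad(beta: np.ndarray) -> tuple[float, np.ndarray]:
            ll, grad = arrays.log_likelihood_grad(beta)
            return -ll, -grad

        res = minimize(
            neg_ll_grad, x0, jac=True, method="L-BFGS-B", bounds=box,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        beta = np.clip(res.x, lo, hi)
        ll = -float(res.fun)
        converged = bool(res.success)
        n_iter = int(res.nit)
    else:
        raise ValueError(f"unknown optimiser {method!r}")

    params = ModelParams.from_array(beta)
    return FitResult(
        params=params,
        max_log_likelihood=ll,
        n_observations=arrays.n_decisions,
        k=k,
        aic=2.0 * k - 2.0 * ll,
        converged=converged,
        init=tuple(map(float, x0)),
        method=method,
        n_iterations=n_iter,
    )


def fit_mle(
    trajectories: Iterable[ParticipantTrajectory],
    model_spec: str = "two_param",
    init: Sequence[float] | None = None,
    bounds: float | Sequence[tuple[float, float]] = DEFAULT_BOUND,
    method: str = "nelder-mead",
) -> FitResult:
    """Maximum-likelihood fit of the choice model to a set of trajectories.

    ``model_spec`` is ``two_param`` (occupancy + distance) or ``three_param``
    (plus schedule desirability, coefficient constrained non-negative).
    Non-convergence is flagged on the result, not raised; empty data raises.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("cannot fit an empty dataset")
    try:
        k = MODEL_SPECS[model_spec]
    except KeyError:
        raise ValueError(f"unknown model_spec {model_spec!r}") from None
    arrays = DecisionArrays.from_trajectories(trajectories, k=k)
    return fit_arrays(arrays, init=init, bounds=bounds, method=method)


def random_model_aic(
    trajectories: Iterable[ParticipantTrajectory],
    choice_set_policy: str = "shrinking",
    k_random: int = 0,
    n_destinations: int | None = None,
) -> float:
    """AIC of the zero-parameter random model (all betas fixed at zero).

    Under the ``shrinking`` policy each decision's alternative count is the
    recorded choice-set size; under ``full`` every decision offers all
    ``n_destinations`` alternatives (inferred as the largest recorded choice
    set if not given).  ``k_random`` counts the random model's free
    parameters (zero by default).
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("cannot score an empty dataset")
    sizes = [len(ctx.alternatives) for t in trajectories for ctx in t.decisions]
    if choice_set_policy == "shrinking":
        ll = -sum(math.log(m) for m in sizes)
    elif choice_set_policy == "full":
        m = n_destinations if n_destinations is not None else max(sizes)
        ll = -len(sizes) * math.log(m)
    else:
        raise ValueError(f"unknown choice-set policy {choice_set_policy!r}")
    return 2.0 * k_random - 2.0 * ll
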