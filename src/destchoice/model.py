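"""Multinomial-logit destination-choice model.

Each decision a participant makes is modelled as a multinomial-logit choice
over the currently available destinations.  The utility of alternative ``i``
is linear in per-decision-normalised predictors,

    U_i = beta_occ * n_i + beta_dist * d_i  [+ beta_des * q_i]

where ``n_i`` is normalised occupancy (busyness), ``d_i`` normalised distance
and, for conditions where participants plan or are given a destination
schedule, ``q_i`` a normalised desirability derived from the schedule.
Each predictor is normalised per decision by dividing by the maximum value
over the alternatives at that decision, so every predictor lies in [0, 1]
and the betas measure relative effect strength.  The choice probability is
the softmax of the utilities, and the dataset log-likelihood sums the log
probability of the chosen alternative over all recorded decisions.

Desirability encodes schedule priority: the destination in (1-based) position
``p`` of the participant's remaining schedule has desirability exp(-p);
destinations already visited are removed from the schedule; destinations not
in the schedule have desirability zero.  A ``worked_example`` variant instead
appends off-schedule destinations to the schedule's tail before assigning
positions (so a 5-entry schedule over 6 destinations gives the 6th
destination exp(-6) rather than 0); both conventions appear in the
literature, and the zero rule is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "Schedule",
    "Alternative",
    "DecisionContext",
    "ParticipantTrajectory",
    "desirability_vector",
    "normalize_predictors",
    "utility",
    "alternative_probabilities",
    "choice_probabilities",
    "log_likelihood",
    "DecisionArrays",
]

CONDITIONS = ("base", "schedule_chosen", "schedule_given", "closed", "photo")
SCHEDULE_CONDITIONS = ("schedule_chosen", "schedule_given")


@dataclass(frozen=True)
class ModelParams:
    """Choice-model coefficients.

    ``beta_des`` is present only for schedule-condition (three-parameter)
    models and must be non-negative: it measures how strongly a participant
    follows their planned or given schedule, and a negative value would mean
    actively doing the opposite.
    """

    beta_occ: float
    beta_dist: float
    beta_des: float | None = None

    def __post_init__(self) -> None:
        if self.beta_des is not None and self.beta_des < 0:
            raise ValueError("beta_des must be non-negative")

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return 2 if self.beta_des is None else 3

    def as_array(self) -> np.ndarray:
        if self.beta_des is None:
            return np.array([self.beta_occ, self.beta_dist], dtype=float)
        return np.array([self.beta_occ, self.beta_dist, self.beta_des], dtype=float)

    @classmethod
    def from_array(cls, beta: Sequence[float]) -> "ModelParams":
        beta = list(map(float, beta))
        if len(beta) == 2:
            return cls(beta[0], beta[1])
        if len(beta) == 3:
            return cls(beta[0], beta[1], beta[2])
        raise ValueError(f"expected 2 or 3 coefficients, got {len(beta)}")


class Schedule(tuple):
    """Ordered, duplicate-free list of destinations a participant plans to visit."""

    def __new__(cls, labels: Iterable[str]):
        labels = tuple(labels)
        if len(set(labels)) != len(labels):
            raise ValueError(f"schedule contains duplicates: {labels}")
        return super().__new__(cls, labels)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Schedule({''.join(self)})"


@dataclass(frozen=True)
class Alternative:
    """One available destination at one decision, with its raw predictors."""

    label: str
    distance: float
    occupancy: float
    desirability: float = 0.0

    def __post_init__(self) -> None:
        if self.distance < 0 or self.occupancy < 0 or self.desirability < 0:
            raise ValueError("raw predictors must be non-negative")


@dataclass(frozen=True)
class DecisionContext:
    """One recorded decision: the alternatives faced and the one chosen."""

    decision_index: int
    position: str
    alternatives: tuple[Alternative, ...]
    chosen: str

    def __post_init__(self) -> None:
        labels = [a.label for a in self.alternatives]
        if len(set(labels)) != len(labels):
            raise ValueError("alternative labels must be distinct")
        if self.chosen not in labels:
            raise ValueError(
                f"chosen label {self.chosen!r} not among alternatives {labels}"
            )

    @property
    def chosen_index(self) -> int:
        for i, a in enumerate(self.alternatives):
            if a.label == self.chosen:
                return i
        raise AssertionError  # unreachable; checked in __post_init__

    @property
    def chosen_alternative(self) -> Alternative:
        return self.alternatives[self.chosen_index]


@dataclass(frozen=True)
class ParticipantTrajectory:
    """One participant's ordered decisions in one experimental condition."""

    participant_id: str
    condition: str
    decisions: tuple[DecisionContext, ...]
    schedule: Schedule | None = None
    completed: bool = True

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.decisions) > 5:
            raise ValueError("a trip has at most five decisions")
        chosen = [d.chosen for d in self.decisions]
        if len(set(chosen)) != len(chosen):
            raise ValueError(f"revisited destination in {chosen}")
        has_schedule = self.schedule is not None
        if has_schedule != (self.condition in SCHEDULE_CONDITIONS):
            raise ValueError(
                "schedule must be present iff the condition is a schedule condition"
            )

    @property
    def chosen_sequence(self) -> tuple[str, ...]:
        return tuple(d.chosen for d in self.decisions)


# ---------------------------------------------------------------------------
# Predictors
# ---------------------------------------------------------------------------

def desirability_vector(
    schedule: Schedule | Sequence[str],
    visited: Sequence[str],
    all_destinations: Sequence[str],
    variant: str = "rule",
) -> dict[str, float]:
    """Raw desirability q of every destination given the remaining schedule.

    The remaining schedule is the original schedule minus visited
    destinations, order preserved.  Under ``variant="rule"`` the destination
    at 1-based position p of the remaining schedule gets q = exp(-p) and
    destinations absent from the schedule get q = 0.  Under
    ``variant="worked_example"`` destinations absent from the schedule are
    first appended to its tail (in ``all_destinations`` order), so every
    destination receives a positive desirability.
    """
    unknown = set(visited) - set(all_destinations)
    if unknown:
        raise ValueError(f"visited contains non-destinations: {sorted(unknown)}")
    unknown = set(schedule) - set(all_destinations)
    if unknown:
        raise ValueError(f"schedule contains non-destinations: {sorted(unknown)}")
    if variant == "rule":
        extended = list(schedule)
    elif variant == "worked_example":
        extended = list(schedule) + [
            d for d in all_destinations if d not in schedule
        ]
    else:
        raise ValueError(f"unknown desirability variant {variant!r}")
    remaining = [d for d in extended if d not in set(visited)]
    q = {d: 0.0 for d in all_destinations}
    for p, dest in enumerate(remaining, start=1):
        q[dest] = math.exp(-p)
    return q


def normalize_predictors(values: Sequence[float]) -> np.ndarray:
    """Scale a predictor to [0, 1] by dividing by its maximum at this decision.

    An all-zero predictor (e.g. desirability when no schedule entry remains
    among the alternatives) stays all-zero: no signal, no contribution.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one alternative")
    if np.any(arr < 0):
        raise ValueError("predictors must be non-negative")
    m = arr.max()
    if m == 0:
        return np.zeros_like(arr)
    return arr / m


def utility(
    params: ModelParams,
    n_hat: float,
    d_hat: float,
    q_hat: float | None = None,
) -> float:
    """Linear utility of one alternative from its normalised predictors."""
    if (q_hat is None) != (params.beta_des is None):
        raise ValueError(
            "desirability predictor must be supplied iff beta_des is present"
        )
    u = params.beta_occ * n_hat + params.beta_dist * d_hat
    if params.beta_des is not None:
        u += params.beta_des * q_hat
    return u


def _context_design(context: DecisionContext, k: int) -> np.ndarray:
    """(n_alternatives, k) matrix of per-decision-normalised predictors."""
    n_hat = normalize_predictors([a.occupancy for a in context.alternatives])
    d_hat = normalize_predictors([a.distance for a in context.alternatives])
    cols = [n_hat, d_hat]
    if k == 3:
        cols.append(normalize_predictors([a.desirability for a in context.alternatives]))
    return np.column_stack(cols)


def alternative_probabilities(
    params: ModelParams, alternatives: Sequence[Alternative]
) -> dict[str, float]:
    """Softmax choice probabilities over a bare set of alternatives.

    Predictors are normalised per decision before entering the utilities;
    the softmax is computed with a max-utility shift for overflow safety.
    Used by :func:`choice_probabilities` and by the simulator, which needs
    probabilities before a choice exists.
    """
    n_hat = normalize_predictors([a.occupancy for a in alternatives])
    d_hat = normalize_predictors([a.distance for a in alternatives])
    cols = [n_hat, d_hat]
    if params.k == 3:
        cols.append(normalize_predictors([a.desirability for a in alternatives]))
    X = np.column_stack(cols)
    u = X @ params.as_array()
    u -= u.max()
    e = np.exp(u)
    p = e / e.sum()
    return {a.label: float(pi) for a, pi in zip(alternatives, p)}


def choice_probabilities(
    params: ModelParams, context: DecisionContext
) -> dict[str, float]:
    """Softmax choice probabilities over the context's alternatives."""
    return alternative_probabilities(params, context.alternatives)


def log_likelihood(
    params: ModelParams, trajectories: Iterable[ParticipantTrajectory]
) -> float:
    """Dataset log-likelihood; each recorded decision is one data point."""
    arrays = DecisionArrays.from_trajectories(trajectories, k=params.k)
    return arrays.log_likelihood(params.as_array())


# ---------------------------------------------------------------------------
# Vectorised likelihood backend
# ---------------------------------------------------------------------------

@dataclass
class DecisionArrays:
    """Padded array view of a dataset for fast repeated likelihood evaluation.

    Decisions are stacked into (n_decisions, max_alternatives, k) design
    tensors with a validity mask; resampling loops (bootstrap, permutation)
    and the optimiser evaluate the likelihood and its gradient without
    touching Python-level per-decision objects.
    """

    X: np.ndarray          # (D, A, k) normalised predictors, padded with 0
    mask: np.ndarray       # (D, A) True where the alternative exists
    chosen: np.ndarray     # (D,) index of the chosen alternative
    participant: np.ndarray  # (D,) integer participant codes
    participant_ids: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def from_trajectories(
        cls, trajectories: Iterable[ParticipantTrajectory], k: int
    ) -> "DecisionArrays":
        trajectories = list(trajectories)
        if k == 3:
            missing = [t.participant_id for t in trajectories if t.schedule is None]
            if missing:
                raise ValueError(
                    f"three-parameter model needs schedules; missing for {missing[:3]}"
                )
        designs, chosen, part = [], [], []
        ids: list[str] = []
        for t in trajectories:
            pi = len(ids)
            ids.append(t.participant_id)
            for ctx in t.decisions:
                designs.append(_context_design(ctx, k))
                chosen.append(ctx.chosen_index)
                part.append(pi)
        if not designs:
            raise ValueError("no decisions in dataset")
        A = max(d.shape[0] for d in designs)
        D = len(designs)
        X = np.zeros((D, A, k))
        mask = np.zeros((D, A), dtype=bool)
        for i, d in enumerate(designs):
            X[i, : d.shape[0]] = d
            mask[i, : d.shape[0]] = True
        return cls(
            X=X,
            mask=mask,
            chosen=np.asarray(chosen, dtype=np.intp),
            participant=np.asarray(part, dtype=np.intp),
            participant_ids=tuple(ids),
        )

    @property
    def n_decisions(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[2]

    def subset_participants(self, codes: np.ndarray) -> "DecisionArrays":
        """Dataset restricted to (or resampled over) the given participant codes.

        ``codes`` may repeat (bootstrap resampling with replacement); each
        occurrence contributes that participant's decisions once more.
        """
        rows = [np.flatnonzero(self.participant == c) for c in np.asarray(codes)]
        idx = np.concatenate(rows) if rows else np.empty(0, dtype=np.intp)
        if idx.size == 0:
            raise ValueError("subset contains no decisions")
        return DecisionArrays(
            X=self.X[idx],
            mask=self.mask[idx],
            chosen=self.chosen[idx],
            participant=self.participant[idx],
            participant_ids=self.participant_ids,
        )

    def _utilities(self, beta: np.ndarray) -> np.ndarray:
        u = self.X @ beta
        return np.where(self.mask, u, -np.inf)

    def log_likelihood(self, beta: np.ndarray) -> float:
        u = self._utilities(np.asarray(beta, dtype=float))
        m = u.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(u - m).sum(axis=1))
        u_chosen = u[np.arange(self.n_decisions), self.chosen]
        return float((u_chosen - lse).sum())

    def log_likelihood_grad(self, beta: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-likelihood and its gradient d LL / d beta.

        Standard MNL score: sum over decisions of (x_chosen - E_p[x]).
        """
        beta = np.asarray(beta, dtype=float)
        u = self._utilities(beta)
        m = u.max(axis=1, keepdims=True)
        e = np.exp(u - m)
        denom = e.sum(axis=1, keepdims=True)
        p = e / denom
        lse = m[:, 0] + np.log(denom[:, 0])
        rows = np.arange(self.n_decisions)
        ll = float((u[rows, self.chosen] - lse).sum())
        x_chosen = self.X[rows, self.chosen]
        expected = np.einsum("da,dak->dk", p, self.X)
        grad = (x_chosen - expected).sum(axis=0)
        return ll, grad
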