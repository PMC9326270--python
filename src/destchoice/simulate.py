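"""Synthetic-cohort generator: the virtual experiment in silico.

This module plays both roles the analysis needs: it is the simulator of the
virtual experiment (sequential destination choices under a shrinking choice
set and a hypothetical time budget) and the source of synthetic cohorts with
known ground truth for parameter-recovery, calibration and clustering
studies.

A simulated participant makes up to five consecutive choices.  At each
decision the available destinations (all not yet visited, under the default
no-revisit rule) are scored by the multinomial-logit model with the
participant's true coefficients; one is sampled from the resulting
probabilities; the elapsed hypothetical time w_d*d + w_o*o + eps of the
chosen transition is subtracted from the remaining budget.  A choice that
overruns the budget is still recorded before the trip ends (participants ran
out of time only after committing to a choice); a flag drops it instead.

Noise policy: by default noise is realised once per (decision, position,
destination) per environment and shared by all participants, mirroring the
experiment's pre-computed transition times — two participants making the same
choice sequence experience identical remaining times.  Fresh per-participant
draws are available for general simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .environment import EnvironmentSpec, NoiseTable, available_alternatives, elapsed_time
from .model import (
    SCHEDULE_CONDITIONS,
    Alternative,
    DecisionContext,
    ModelParams,
    ParticipantTrajectory,
    Schedule,
    alternative_probabilities,
    desirability_vector,
)

__all__ = ["CohortSpec", "simulate_participant", "simulate_cohort"]

DEFAULT_GIVEN_SCHEDULE = "DEBAC"


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort reproducibly.

    ``components`` is a mixture of true coefficient vectors with weights;
    each participant's component is drawn once.  ``schedule_policy`` is
    ``"none"``, ``"given"`` (everyone receives ``given_schedule``) or
    ``"chosen"`` (each participant draws a random ordered subset of
    ``chosen_k`` destinations, standing in for the planning step the
    experiment asks of participants).
    """

    n: int
    environment: EnvironmentSpec
    condition: str = "base"
    components: tuple[tuple[ModelParams, float], ...] = (
        (ModelParams(-4.0, -0.5), 1.0),
    )
    schedule_policy: str = "none"
    given_schedule: str = DEFAULT_GIVEN_SCHEDULE
    chosen_k: int = 5
    noise_policy: str = "shared_across_participants"
    choice_set_policy: str = "shrinking"
    desirability_variant: str = "rule"
    record_overrun: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        weights = np.array([w for _, w in self.components], dtype=float)
        if np.any(weights <= 0) or not np.isclose(weights.sum(), 1.0):
            raise ValueError("mixture weights must be positive and sum to 1")
        needs_schedule = self.condition in SCHEDULE_CONDITIONS
        if needs_schedule and self.schedule_policy == "none":
            raise ValueError(f"condition {self.condition!r} requires a schedule policy")
        if not needs_schedule and self.schedule_policy != "none":
            raise ValueError(f"condition {self.condition!r} must not carry schedules")
        if self.schedule_policy not in ("none", "given", "chosen"):
            raise ValueError(f"unknown schedule policy {self.schedule_policy!r}")
        if self.noise_policy not in ("shared_across_participants", "per_participant"):
            raise ValueError(f"unknown noise policy {self.noise_policy!r}")
        for params, _ in self.components:
            if needs_schedule != (params.beta_des is not None):
                raise ValueError(
                    "component arity must match schedule presence "
                    "(beta_des iff schedule condition)"
                )


def simulate_participant(
    env: EnvironmentSpec,
    params: ModelParams,
    schedule: Schedule | None,
    rng: np.random.Generator,
    participant_id: str = "p0",
    condition: str | None = None,
    choice_set_policy: str = "shrinking",
    desirability_variant: str = "rule",
    noise: NoiseTable | None = None,
    record_overrun: bool = True,
) -> ParticipantTrajectory:
    """Simulate one participant's trip through the environment.

    ``noise`` is a shared :class:`NoiseTable` (experiment-style precomputed
    realisations); when ``None`` a fresh draw is made per transition from
    ``rng``.  ``condition`` defaults to ``base`` / ``schedule_given``
    according to schedule presence.
    """
    if condition is None:
        condition = "schedule_given" if schedule is not None else "base"
    if (schedule is not None) != (params.beta_des is not None):
        raise ValueError("params arity must match schedule presence")
    position = env.origin
    visited: list[str] = []
    remaining = env.time_budget
    decisions: list[DecisionContext] = []
    completed = True
    for j in range(1, env.trip_length + 1):
        avail = available_alternatives(env, visited, policy=choice_set_policy)
        labels = [d for d in env.destinations if d in avail and d != position]
        if not labels:
            break
        if schedule is not None:
            q = desirability_vector(
                schedule, visited, env.destinations, variant=desirability_variant
            )
        else:
            q = {d: 0.0 for d in env.destinations}
        alts = tuple(
            Alternative(
                label=d,
                distance=env.distance(position, d),
                occupancy=env.occupancy(j, d),
                desirability=q[d],
            )
            for d in labels
        )
        probs = alternative_probabilities(params, alts)
        p = np.array([probs[d] for d in labels])
        chosen = labels[int(rng.choice(len(labels), p=p))]
        decisions.append(
            DecisionContext(decision_index=j, position=position,
                            alternatives=alts, chosen=chosen)
        )
        eps = (
            noise(j, position, chosen)
            if noise is not None
            else float(rng.normal(env.noise_mu, env.noise_sigma))
        )
        remaining -= elapsed_time(env, position, chosen, j, eps)
        visited.append(chosen)
        position = chosen
        if remaining <= 0:
            completed = False
            if not record_overrun:
                decisions.pop()
            break
    return ParticipantTrajectory(
        participant_id=participant_id,
        condition=condition,
        decisions=tuple(decisions),
        schedule=schedule,
        completed=completed,
    )


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[ParticipantTrajectory], dict[str, dict]]:
    """Generate a cohort plus a ground-truth sidecar.

    Returns the trajectories and, for recovery studies, a sidecar mapping
    participant id -> its true mixture component index, true coefficients and
    schedule.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    noise = (
        NoiseTable(spec.environment, seed=int(rng.integers(2**31)))
        if spec.noise_policy == "shared_across_participants"
        else None
    )
    weights = np.array([w for _, w in spec.components])
    trajectories: list[ParticipantTrajectory] = []
    sidecar: dict[str, dict] = {}
    width = max(1, len(str(max(spec.n - 1, 0))))
    for i in range(spec.n):
        pid = f"p{i:0{width}d}"
        comp = int(rng.choice(len(spec.components), p=weights))
        params = spec.components[comp][0]
        if spec.schedule_policy == "none":
            schedule = None
        elif spec.schedule_policy == "given":
            schedule = Schedule(spec.given_schedule)
        else:  # chosen: random ordered subset, the planning step stand-in
            picks = rng.choice(
                len(spec.environment.destinations), size=spec.chosen_k, replace=False
            )
            schedule = Schedule(spec.environment.destinations[k] for k in picks)
        traj = simulate_participant(
            spec.environment,
            params,
            schedule,
            rng,
            participant_id=pid,
            condition=spec.condition,
            choice_set_policy=spec.choice_set_policy,
            desirability_variant=spec.desirability_variant,
            noise=noise,
            record_overrun=spec.record_overrun,
        )
        trajectories.append(traj)
        sidecar[pid] = {
            "component": comp,
            "beta_occ": params.beta_occ,
            "beta_dist": params.beta_dist,
            "beta_des": params.beta_des,
            "schedule": "".join(schedule) if schedule else None,
            "completed": traj.completed,
        }
    return trajectories, sidecar
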