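import math

import pytest

from destchoice import (
    Alternative,
    CohortSpec,
    DecisionContext,
    EnvironmentSpec,
    ModelParams,
    ParticipantTrajectory,
    bundled_environment,
    simulate_cohort,
)


def make_env(
    name: str = "tiny",
    destinations: str = "ABCDEF",
    w_d: float = 1.0,
    w_o: float = 1.0,
    noise_sigma: float = 0.0,
    time_budget: float = 60.0,
    distance_overrides: dict | None = None,
) -> EnvironmentSpec:
    """Small deterministic environment for unit tests.

    Distances default to 1 + (index gap); occupancies cycle 1..6 shifted by
    decision index; everything integer and in range.
    """
    dests = tuple(destinations)
    positions = ("O",) + dests
    dist = {}
    for i, p in enumerate(positions):
        dist[p] = {}
        for j, q in enumerate(dests, start=1):
            if q == p:
                dist[p][q] = 0
            else:
                dist[p][q] = min(10, abs(j - i) + 1)
    if distance_overrides:
        for (p, q), v in distance_overrides.items():
            dist[p][q] = v
    occ = {
        j: {d: 1 + (i + j) % 6 for i, d in enumerate(dests)}
        for j in range(1, 6)
    }
    return EnvironmentSpec(
        name=name,
        destinations=dests,
        origin="O",
        distance_table=dist,
        occupancy_table=occ,
        w_d=w_d,
        w_o=w_o,
        noise_mu=0.0,
        noise_sigma=noise_sigma,
        time_budget=time_budget,
    )


def make_context(
    occupancies, distances, desirabilities=None, chosen_idx=0, decision_index=1
) -> DecisionContext:
    labels = "ABCDEF"[: len(occupancies)]
    if desirabilities is None:
        desirabilities = [0.0] * len(occupancies)
    alts = tuple(
        Alternative(label=l, distance=d, occupancy=o, desirability=q)
        for l, d, o, q in zip(labels, distances, occupancies, desirabilities)
    )
    return DecisionContext(
        decision_index=decision_index,
        position="O",
        alternatives=alts,
        chosen=labels[chosen_idx],
    )


def make_trajectory(contexts, pid="p0", condition="base", schedule=None,
                    completed=True) -> ParticipantTrajectory:
    return ParticipantTrajectory(
        participant_id=pid,
        condition=condition,
        decisions=tuple(contexts),
        schedule=schedule,
        completed=completed,
    )


@pytest.fixture(scope="session")
def open_env():
    return bundled_environment("open")


@pytest.fixture(scope="session")
def closed_env():
    return bundled_environment("closed")


@pytest.fixture(scope="session")
def photo_env():
    return bundled_environment("photo")


@pytest.fixture(scope="session")
def tiny_env():
    return make_env()


@pytest.fixture(scope="session")
def base_cohort(open_env):
    """200 participants simulated from the canonical base-condition betas."""
    spec = CohortSpec(
        n=200,
        environment=open_env,
        condition="base",
        components=((ModelParams(-4.0, -0.5), 1.0),),
        seed=12345,
    )
    trajectories, sidecar = simulate_cohort(spec)
    return trajectories, sidecar


@pytest.fixture(scope="session")
def schedule_cohort(open_env):
    """Schedule-given cohort with a strong desirability effect."""
    spec = CohortSpec(
        n=150,
        environment=open_env,
        condition="schedule_given",
        components=((ModelParams(-4.0, -0.5, 2.0), 1.0),),
        schedule_policy="given",
        seed=777,
    )
    trajectories, sidecar = simulate_cohort(spec)
    return trajectories, sidecar


SQRT2 = math.sqrt(2.0)
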