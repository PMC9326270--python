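"""Virtual environments for the destination-choice experiment.

An environment is a set of labelled destinations with an origin, a distance
matrix between positions, an occupancy (head-count) table indexed by decision
number, and the weights that convert distance and occupancy into hypothetical
elapsed minutes.  Choosing destination ``i`` at the ``j``-th decision consumes

    T_i(j) = w_d * d(position, i) + w_o * o(j, i) + eps

hypothetical minutes, where ``eps`` is Gaussian noise.  Participants may not
revisit destinations, so the choice set shrinks as a trip progresses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "EnvironmentSpec",
    "ConfigurationError",
    "InvalidTrajectoryError",
    "elapsed_time",
    "available_alternatives",
    "NoiseTable",
    "load_environment",
    "save_environment",
    "bundled_environment",
]

DISTANCE_RANGE = (0, 10)


class ConfigurationError(KeyError):
    """An environment table is missing an entry or violates an invariant."""


class InvalidTrajectoryError(ValueError):
    """A visit sequence breaks the experiment's rules (e.g. a revisit)."""


@dataclass(frozen=True)
class EnvironmentSpec:
    """Immutable definition of one virtual environment.

    Parameters
    ----------
    name:
        Environment label, e.g. ``"open"``.
    destinations:
        Ordered destination labels (the experiment uses six, A-F).
    origin:
        Label of the starting position; not itself a destination.
    distance_table:
        ``distance_table[position][destination]`` -> integer distance in
        arbitrary units, for every position in ``{origin} | destinations``.
        Stored as a full matrix; symmetry is not assumed.
    occupancy_table:
        ``occupancy_table[decision_index][destination]`` -> head-count at
        that destination when the ``decision_index``-th choice (1-based) is
        made.  Occupancies depend on the decision index only, never on the
        path taken, so identical choice sequences see identical occupancies.
    w_d, w_o:
        Hypothetical minutes per distance unit / per person.
    noise_mu, noise_sigma:
        Mean and standard deviation of the Gaussian noise added to each
        transition's elapsed time.
    time_budget:
        Total hypothetical minutes available for the trip.
    """

    name: str
    destinations: tuple[str, ...]
    origin: str
    distance_table: Mapping[str, Mapping[str, int]]
    occupancy_table: Mapping[int, Mapping[str, int]]
    w_d: float
    w_o: float
    noise_mu: float
    noise_sigma: float
    time_budget: float
    trip_length: int = 5

    def __post_init__(self) -> None:
        if len(set(self.destinations)) != len(self.destinations):
            raise ConfigurationError("duplicate destination labels")
        if self.origin in self.destinations:
            raise ConfigurationError("origin must not be a destination")
        if not (self.w_d > 0 and self.w_o > 0):
            raise ConfigurationError("w_d and w_o must be positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")
        if not self.time_budget > 0:
            raise ConfigurationError("time_budget must be positive")
        positions = {self.origin, *self.destinations}
        for pos in positions:
            row = self.distance_table.get(pos)
            if row is None:
                raise ConfigurationError(f"distance row missing for {pos!r}")
            for dest in self.destinations:
                if dest == pos:
                    continue
                d = row.get(dest)
                if d is None:
                    raise ConfigurationError(
                        f"distance missing for ({pos!r}, {dest!r})"
                    )
                if not (isinstance(d, (int, np.integer)) and
                        DISTANCE_RANGE[0] <= d <= DISTANCE_RANGE[1]):
                    raise ConfigurationError(
                        f"distance ({pos!r}, {dest!r}) = {d!r} not an "
                        f"integer in {list(DISTANCE_RANGE)}"
                    )
        for j in range(1, self.trip_length + 1):
            row = self.occupancy_table.get(j)
            if row is None:
                raise ConfigurationError(f"occupancy row missing for decision {j}")
            for dest in self.destinations:
                o = row.get(dest)
                if o is None:
                    raise ConfigurationError(
                        f"occupancy missing for (decision {j}, {dest!r})"
                    )
                if not (isinstance(o, (int, np.integer)) and o > 0):
                    raise ConfigurationError(
                        f"occupancy (decision {j}, {dest!r}) = {o!r} "
                        "not a positive integer"
                    )

    def distance(self, position: str, destination: str) -> int:
        try:
            return self.distance_table[position][destination]
        except KeyError as exc:
            raise ConfigurationError(
                f"no distance entry for ({position!r}, {destination!r})"
            ) from exc

    def occupancy(self, decision_index: int, destination: str) -> int:
        try:
            return self.occupancy_table[decision_index][destination]
        except KeyError as exc:
            raise ConfigurationError(
                f"no occupancy entry for (decision {decision_index}, "
                f"{destination!r})"
            ) from exc


def elapsed_time(
    env: EnvironmentSpec,
    position: str,
    destination: str,
    decision_index: int,
    noise_value: float,
) -> float:
    """Hypothetical minutes consumed by moving to ``destination``.

    ``noise_value`` is supplied by the caller so that the noise-realisation
    policy (shared across participants vs fresh per participant) lives with
    the simulator, not the formula; pass 0 for the deterministic part.
    """
    if destination == position:
        raise InvalidTrajectoryError("destination equals current position")
    d = env.distance(position, destination)
    o = env.occupancy(decision_index, destination)
    return env.w_d * d + env.w_o * o + noise_value


def available_alternatives(
    env: EnvironmentSpec,
    visited: Sequence[str],
    policy: str = "shrinking",
) -> set[str]:
    """Choice set at the next decision.

    ``shrinking`` removes already-visited destinations (the experiment's
    no-revisit rule); ``full`` always returns every destination.
    """
    if len(set(visited)) != len(visited):
        raise InvalidTrajectoryError(f"duplicate destination in visited: {visited}")
    unknown = set(visited) - set(env.destinations)
    if unknown:
        raise InvalidTrajectoryError(f"unknown destinations visited: {sorted(unknown)}")
    if policy == "shrinking":
        return set(env.destinations) - set(visited)
    if policy == "full":
        return set(env.destinations)
    raise ValueError(f"unknown choice-set policy {policy!r}")


@dataclass
class NoiseTable:
    """Noise realisations drawn once per (decision, position, destination).

    The experiment pre-computes the elapsed time of every possible transition
    once, so every participant facing the same transition experiences the same
    noise.  Draws are made lazily from a seeded generator and cached.
    """

    env: EnvironmentSpec
    seed: int
    _cache: dict[tuple[int, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    def __call__(self, decision_index: int, position: str, destination: str) -> float:
        key = (decision_index, position, destination)
        if key not in self._cache:
            self._cache[key] = float(
                self._rng.normal(self.env.noise_mu, self.env.noise_sigma)
            )
        return self._cache[key]


# ---------------------------------------------------------------------------
# File representation (YAML)
# ---------------------------------------------------------------------------

def _env_to_dict(env: EnvironmentSpec) -> dict:
    return {
        "name": env.name,
        "destinations": list(env.destinations),
        "origin": env.origin,
        "distance_table": {
            pos: {d: int(v) for d, v in sorted(row.items())}
            for pos, row in sorted(env.distance_table.items())
        },
        "occupancy_table": {
            int(j): {d: int(v) for d, v in sorted(row.items())}
            for j, row in sorted(env.occupancy_table.items())
        },
        "w_d": float(env.w_d),
        "w_o": float(env.w_o),
        "noise_mu": float(env.noise_mu),
        "noise_sigma": float(env.noise_sigma),
        "time_budget": float(env.time_budget),
        "trip_length": int(env.trip_length),
    }


def _env_from_dict(data: Mapping) -> EnvironmentSpec:
    return EnvironmentSpec(
        name=data["name"],
        destinations=tuple(data["destinations"]),
        origin=data["origin"],
        distance_table={
            pos: dict(row) for pos, row in data["distance_table"].items()
        },
        occupancy_table={
            int(j): dict(row) for j, row in data["occupancy_table"].items()
        },
        w_d=float(data["w_d"]),
        w_o=float(data["w_o"]),
        noise_mu=float(data["noise_mu"]),
        noise_sigma=float(data["noise_sigma"]),
        time_budget=float(data["time_budget"]),
        trip_length=int(data.get("trip_length", 5)),
    )


def save_environment(env: EnvironmentSpec, path: str | Path) -> None:
    """Write the environment definition as YAML (sorted keys, stable)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_env_to_dict(env), fh, sort_keys=True)


def load_environment(path: str | Path) -> EnvironmentSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return _env_from_dict(data)
    except KeyError as exc:
        raise ConfigurationError(f"environment file {path} missing key {exc}") from exc


def bundled_environment(name: str) -> EnvironmentSpec:
    """Load one of the packaged synthetic environments (open/closed/photo).

    The numeric tables are invented values obeying the experiment's structural
    constraints (integer distances in [0, 10], positive integer occupancies,
    budgets of 60 or 15 hypothetical minutes); they are NOT the study's own
    distance/occupancy tables.
    """
    path = Path(__file__).parent / "environments" / f"{name}.yaml"
    if not path.exists():
        raise ConfigurationError(f"no bundled environment named {name!r}")
    return load_environment(path)
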