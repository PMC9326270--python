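"""Schedule adherence: how closely realised trips follow planned schedules.

Adherence is measured by the Levenshtein distance between a participant's
planned schedule and the destination sequence they actually chose: the
minimum number of single-label substitutions, insertions and deletions (all
unit cost) converting one into the other.  Insertions/deletions matter
because a trip cut short by the hypothetical time budget is shorter than the
five-entry schedule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import ParticipantTrajectory

__all__ = ["AdherenceSummary", "levenshtein", "adherence_summary"]


def levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    """Unit-cost edit distance between two label sequences.

    Classic two-row dynamic programme; transpositions are not allowed.
    """
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(
                prev[j] + 1,                      # deletion
                cur[j - 1] + 1,                   # insertion
                prev[j - 1] + (ca != cb),         # substitution / match
            ))
        prev = cur
    return prev[-1]


@dataclass(frozen=True)
class AdherenceSummary:
    """Per-participant schedule-to-sequence distances and their summary."""

    distances: dict[str, int]
    mean: float
    histogram: dict[int, int]
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.distances and not np.isclose(
            self.mean, float(np.mean(list(self.distances.values())))
        ):
            raise ValueError("mean inconsistent with distances")


def adherence_summary(
    trajectories: Iterable[ParticipantTrajectory],
) -> AdherenceSummary:
    """Levenshtein distance schedule -> realised sequence, per participant.

    Participants without a schedule are excluded and listed on the result.
    The histogram counts participants at each integer distance (the figure
    the mean line annotates).
    """
    distances: dict[str, int] = {}
    excluded: list[str] = []
    for t in trajectories:
        if t.schedule is None:
            excluded.append(t.participant_id)
            continue
        distances[t.participant_id] = levenshtein(t.schedule, t.chosen_sequence)
    if distances:
        vals = list(distances.values())
        mean = float(np.mean(vals))
        histogram = {d: vals.count(d) for d in range(0, max(vals) + 1)}
    else:
        mean = float("nan")
        histogram = {}
    return AdherenceSummary(
        distances=distances, mean=mean, histogram=histogram, excluded=tuple(excluded)
    )
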