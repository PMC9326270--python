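"""Participant clustering by behaviour, two ways.

The first procedure is qualitative: per participant, the cumulative raw
distance (or occupancy) of chosen destinations is normalised by the number of
decisions made; if the cohort's distribution of this quantity is bimodal, the
midpoint between the two main modes splits participants into two clusters.

The second procedure calibrates the choice model separately for each
participant and clusters the coefficient estimates by agglomerative
hierarchical clustering (Euclidean distance, complete linkage), cutting the
dendrogram at a height chosen by the analyst.

Either clustering is evaluated by refitting the model within each cluster:
the clustered model's AIC is the sum of per-cluster AICs, compared with the
AIC of the aggregate fit on everyone.  A lower clustered AIC indicates
genuine behavioural heterogeneity rather than a parameter-count artefact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

from .calibration import DEFAULT_BOUND, FitResult, fit_mle
from .model import ModelParams, ParticipantTrajectory

__all__ = [
    "ClusterAssignment",
    "ClusterComparison",
    "normalized_cumulative",
    "estimate_bimodal_threshold",
    "threshold_clusters",
    "per_individual_fits",
    "hierarchical_clusters",
    "dendrogram_newick",
    "clustered_model_comparison",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Participant -> cluster label map plus how it was produced."""

    labels: dict[str, int]
    method: str  # "threshold" | "hierarchical"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("assignment must cover at least one participant")

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for pid, c in self.labels.items():
            out.setdefault(c, []).append(pid)
        return out

    def sizes(self) -> dict[int, int]:
        return {c: len(m) for c, m in self.clusters.items()}


@dataclass(frozen=True)
class ClusterComparison:
    """Clustered-vs-aggregate goodness-of-fit comparison."""

    cluster_fits: dict[int, FitResult]
    clustered_aic: float
    aggregate_fit: FitResult
    skipped_clusters: tuple[int, ...] = ()

    @property
    def aggregate_aic(self) -> float:
        return self.aggregate_fit.aic

    @property
    def improvement(self) -> float:
        """Aggregate AIC minus clustered AIC; positive favours clustering."""
        return self.aggregate_aic - self.clustered_aic


def normalized_cumulative(trajectory: ParticipantTrajectory, quantity: str) -> float:
    """Cumulative chosen raw distance or occupancy per decision made.

    The sum over decisions of the chosen alternative's raw value, divided by
    the participant's decision count (so trips cut short by the time budget
    are comparable with complete five-choice trips).
    """
    if not trajectory.decisions:
        raise ValueError("trajectory has no decisions")
    if quantity == "distance":
        vals = [d.chosen_alternative.distance for d in trajectory.decisions]
    elif quantity == "occupancy":
        vals = [d.chosen_alternative.occupancy for d in trajectory.decisions]
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return float(sum(vals)) / len(vals)


def estimate_bimodal_threshold(
    values: Sequence[float],
    bins: int = 20,
    valley_ratio: float = 0.5,
    min_mode_share: float = 0.05,
) -> float | None:
    """Midpoint between the two main modes of a histogram, if bimodal.

    The values are binned into ``bins`` equal-width bins over their range and
    local maxima of the counts are located.  The distribution is declared
    bimodal when the two highest modes are separated by a valley whose lowest
    bin falls below ``valley_ratio`` times the smaller mode's count, and each
    mode holds at least ``min_mode_share`` of the sample — sampling noise on
    a unimodal histogram routinely produces shallow secondary maxima, so a
    bare two-local-maxima rule would see modes everywhere.  If bimodal, the
    midpoint of the two modes' bin centres is returned; otherwise ``None``
    (no clustering is attempted for unimodal distributions).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values for mode detection")
    if np.ptp(values) == 0:
        return None
    counts, edges = np.histogram(values, bins=bins)
    centres = (edges[:-1] + edges[1:]) / 2.0

    maxima = []
    for i in range(len(counts)):
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < len(counts) - 1 else -1
        if counts[i] > 0 and counts[i] >= left and counts[i] >= right:
            # keep only the first bin of a flat-topped plateau
            if i > 0 and counts[i] == counts[i - 1] and maxima and maxima[-1] == i - 1:
                continue
            maxima.append(i)
    if len(maxima) < 2:
        return None
    min_count = max(1, int(np.ceil(min_mode_share * values.size)))
    candidates = [i for i in maxima if counts[i] >= min_count]
    if len(candidates) < 2:
        return None
    # the two highest modes, ties broken towards wider separation
    candidates.sort(key=lambda i: -counts[i])
    i, j = sorted(candidates[:2])
    between = counts[i + 1 : j]
    if between.size == 0:
        return None
    if between.min() <= valley_ratio * min(counts[i], counts[j]):
        return float((centres[i] + centres[j]) / 2.0)
    return None


def threshold_clusters(
    values: Mapping[str, float], threshold: float
) -> ClusterAssignment:
    """Two clusters: below the threshold (0) vs at-or-above it (1)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    labels = {pid: (0 if v < threshold else 1) for pid, v in values.items()}
    sizes = {c: sum(1 for l in labels.values() if l == c) for c in (0, 1)}
    empty = [c for c, n in sizes.items() if n == 0]
    return ClusterAssignment(
        labels=labels,
        method="threshold",
        metadata={"threshold": float(threshold), "empty_clusters": empty},
    )


def per_individual_fits(
    trajectories: Iterable[ParticipantTrajectory],
    model_spec: str = "two_param",
    bounds: float = DEFAULT_BOUND,
    method: str = "lbfgs",
) -> dict[str, ModelParams]:
    """One bounded MLE fit per participant.

    With at most five decisions per participant the likelihood often
    separates perfectly, so the box bound (default ±20) is what keeps the
    estimates finite; estimates pinned at a bound are legitimate output here.
    Participants whose fit fails to converge are absent from the returned
    mapping and so excluded from any downstream clustering.
    """
    fits: dict[str, ModelParams] = {}
    for t in trajectories:
        result = fit_mle([t], model_spec=model_spec, bounds=bounds, method=method)
        if result.converged:
            fits[t.participant_id] = result.params
    return fits


def hierarchical_clusters(
    estimates: Mapping[str, ModelParams],
    cut_height: float | None = None,
    n_clusters: int | None = None,
    linkage_method: str = "complete",
) -> ClusterAssignment:
    """Agglomerative clustering of per-participant coefficient estimates.

    Euclidean distance on the estimate vectors, complete linkage by default.
    Clusters are the dendrogram subtrees below ``cut_height``; alternatively
    ``n_clusters`` cuts the tree into exactly that many groups.  Labels are
    renumbered by decreasing cluster size, then by first participant id, so
    the assignment is independent of input order.
    """
    if (cut_height is None) == (n_clusters is None):
        raise ValueError("specify exactly one of cut_height or n_clusters")
    pids = sorted(estimates)
    if len(pids) < 2:
        raise ValueError("need at least two participants")
    X = np.vstack([estimates[p].as_array() for p in pids])
    Z = linkage(X, method=linkage_method, metric="euclidean")
    if cut_height is not None:
        raw = fcluster(Z, t=cut_height, criterion="distance")
    else:
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # canonical labels: 0, 1, ... by decreasing size then lexicographic member
    groups: dict[int, list[str]] = {}
    for pid, c in zip(pids, raw):
        groups.setdefault(int(c), []).append(pid)
    order = sorted(groups, key=lambda c: (-len(groups[c]), min(groups[c])))
    relabel = {c: i for i, c in enumerate(order)}
    labels = {pid: relabel[int(c)] for pid, c in zip(pids, raw)}
    meta: dict = {"linkage": linkage_method, "metric": "euclidean"}
    if cut_height is not None:
        meta["cut_height"] = float(cut_height)
    else:
        meta["n_clusters"] = int(n_clusters)
    return ClusterAssignment(labels=labels, method="hierarchical", metadata=meta)


def dendrogram_newick(
    estimates: Mapping[str, ModelParams], linkage_method: str = "complete"
) -> str:
    """Newick text of the estimate dendrogram, for external inspection.

    Branch lengths are merge-height differences, so cutting the tree at a
    given depth from the root corresponds to the ``cut_height`` criterion.
    """
    pids = sorted(estimates)
    if len(pids) < 2:
        raise ValueError("need at least two participants")
    X = np.vstack([estimates[p].as_array() for p in pids])
    root = to_tree(linkage(X, method=linkage_method, metric="euclidean"))

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{pids[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(root, root.dist) + ";"


def clustered_model_comparison(
    trajectories: Iterable[ParticipantTrajectory],
    assignment: ClusterAssignment,
    model_spec: str = "two_param",
    method: str = "nelder-mead",
    bounds: float = DEFAULT_BOUND,
) -> ClusterComparison:
    """Fit per cluster and on the aggregate; compare by summed AIC.

    The clustered model's AIC is the sum of the per-cluster AICs (every
    non-empty cluster counts, including singleton outliers).  Participants
    missing from the assignment raise; clusters with no trajectories are
    skipped with a record.
    """
    trajectories = list(trajectories)
    by_pid: dict[str, list[ParticipantTrajectory]] = {}
    for t in trajectories:
        by_pid.setdefault(t.participant_id, []).append(t)
    missing = set(by_pid) - set(assignment.labels)
    if missing:
        raise ValueError(f"participants not assigned to a cluster: {sorted(missing)[:5]}")

    cluster_fits: dict[int, FitResult] = {}
    skipped: list[int] = []
    for c, members in sorted(assignment.clusters.items()):
        data = [t for pid in members for t in by_pid.get(pid, [])]
        if not data:
            skipped.append(c)
            continue
        cluster_fits[c] = fit_mle(data, model_spec=model_spec, method=method, bounds=bounds)
    aggregate = fit_mle(trajectories, model_spec=model_spec, method=method, bounds=bounds)
    clustered_aic = float(sum(f.aic for f in cluster_fits.values()))
    return ClusterComparison(
        cluster_fits=cluster_fits,
        clustered_aic=clustered_aic,
        aggregate_fit=aggregate,
        skipped_clusters=tuple(skipped),
    )
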