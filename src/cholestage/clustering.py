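"""Complete-linkage clustering of factors into phase archetypes.

Each factor is represented by its row of the rescaled YS3 similarity matrix;
agglomerative complete-linkage clustering with Euclidean distances between
those rows groups factors with similar temporal behaviour.  The cluster
count is chosen as the largest cut of the tree in which every cluster keeps
more than one factor, which reproduces the six-phase structure of the study
design.  Cluster labels are assigned deterministically by the time at which
the cluster's mean profile peaks (earliest peak = cluster 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .dataset import NormalizedDataset
from .similarity import DEFAULT_WEIGHTS, SimilarityMatrix, ys3


@dataclass
class ClusterSet:
    """Factor-to-cluster assignment with per-cluster summaries.

    ``mean_courses[c]`` is the per-(time, replicate) mean of the normalized
    member values of cluster ``c`` (the regression tree's predictor samples);
    ``mean_profile[c]`` additionally averages over replicates for display;
    ``member_correlations`` holds each factor's rescaled YS3 similarity to
    its own cluster's mean course (member included in the mean).
    """

    assignment: dict[str, int]
    n_clusters: int
    mean_courses: dict[int, np.ndarray] = field(default_factory=dict)
    mean_profile: dict[int, np.ndarray] = field(default_factory=dict)
    member_correlations: dict[str, float] = field(default_factory=dict)

    def members(self, cluster: int) -> list[str]:
        return [f for f, c in self.assignment.items() if c == cluster]

    @property
    def cluster_labels(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    @property
    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.assignment.values():
            out[c] = out.get(c, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factor_id": f,
                "cluster": c,
                "member_correlation": self.member_correlations.get(f, np.nan),
            }
            for f, c in self.assignment.items()
        ]
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["cluster", "member_correlation"],
            ascending=[True, False],
        ).reset_index(drop=True)


def _linkage(sim: SimilarityMatrix) -> np.ndarray:
    """Complete-linkage tree on Euclidean distances between matrix rows."""
    return hierarchy.linkage(pdist(sim.values, metric="euclidean"), "complete")


def linkage_matrix(sim: SimilarityMatrix) -> np.ndarray:
    return _linkage(sim)


def _cut(Z: np.ndarray, k: int) -> np.ndarray:
    return hierarchy.cut_tree(Z, n_clusters=k).ravel()


def cluster_factors(
    sim: SimilarityMatrix,
    n_clusters: int,
    data: NormalizedDataset | None = None,
    weights=DEFAULT_WEIGHTS,
) -> ClusterSet:
    """Cut the complete-linkage tree into ``n_clusters`` groups.

    When ``data`` is given, per-cluster mean courses and member-to-mean
    correlations are computed and clusters are relabelled 1..k by ascending
    time of their mean-profile maximum; otherwise labels follow first
    occurrence in ``sim.factor_ids``.
    """
    k = len(sim.factor_ids)
    if not 1 <= n_clusters <= k:
        raise ValueError(f"n_clusters must be in [1, {k}], got {n_clusters}")
    raw = _cut(_linkage(sim), n_clusters)

    # provisional relabel by first occurrence for determinism
    seen: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in seen:
            seen[r] = len(seen) + 1
        labels.append(seen[r])
    assignment = dict(zip(sim.factor_ids, labels))
    clusters = ClusterSet(assignment, n_clusters)

    if data is not None:
        courses, profiles = cluster_mean_courses(clusters, data)
        # relabel by earliest time index of the mean-profile maximum
        # (ties resolved by minimum position, then provisional label)
        order = sorted(
            profiles,
            key=lambda c: (
                int(np.nanargmax(profiles[c])),
                int(np.nanargmin(profiles[c])),
                c,
            ),
        )
        relabel = {old: new + 1 for new, old in enumerate(order)}
        clusters = ClusterSet(
            {f: relabel[c] for f, c in assignment.items()}, n_clusters
        )
        courses, profiles = cluster_mean_courses(clusters, data)
        clusters.mean_courses = courses
        clusters.mean_profile = profiles
        clusters.member_correlations = member_correlations(
            clusters, data, weights
        )
    return clusters


def select_cluster_count(sim: SimilarityMatrix) -> int:
    """Largest cut with no singleton cluster (1 if no such cut >= 2 exists).

    The number of phase clusters is the maximum k such that cutting the
    complete-linkage tree at k leaves every cluster with more than one
    factor.
    """
    n = len(sim.factor_ids)
    if n < 4:
        raise ValueError("need at least 4 factors to select a cluster count")
    Z = _linkage(sim)
    for k in range(n, 1, -1):
        sizes = np.bincount(_cut(Z, k))
        if sizes[sizes > 0].min() >= 2:
            return k
    return 1


def cluster_mean_courses(
    clusters: ClusterSet, data: NormalizedDataset
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """(per-cell mean courses, per-time mean profiles) for each cluster.

    The per-cell course averages member factors at each (time, replicate)
    cell (missing cells excluded); the profile additionally averages over
    replicates.
    """
    import warnings

    courses: dict[int, np.ndarray] = {}
    profiles: dict[int, np.ndarray] = {}
    for c in clusters.cluster_labels:
        blocks = np.stack(
            [data.factor_values(f) for f in clusters.members(c)]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            course = np.nanmean(blocks, axis=0)
            profiles[c] = np.nanmean(course, axis=1)
        courses[c] = course
    return courses, profiles


def member_correlations(
    clusters: ClusterSet,
    data: NormalizedDataset,
    weights=DEFAULT_WEIGHTS,
) -> dict[str, float]:
    """Rescaled YS3 of each member against its own cluster mean course."""
    if not clusters.mean_courses:
        clusters.mean_courses, clusters.mean_profile = cluster_mean_courses(
            clusters, data
        )
    return {
        f: ys3(data.factor_values(f), clusters.mean_courses[c], weights).y_rescaled
        for f, c in clusters.assignment.items()
    }


def dendrogram_newick(sim: SimilarityMatrix) -> str:
    """Newick-style serialization ``(label:height)`` of the linkage tree."""
    Z = _linkage(sim)
    tree = hierarchy.to_tree(Z)
    labels = sim.factor_ids

    def _render(node, parent_height) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _render(node.left, node.dist)
        right = _render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _render(tree, tree.dist) + ";"


def write_mean_courses_csv(clusters: ClusterSet, times, path) -> None:
    rows = []
    for c, course in clusters.mean_courses.items():
        for i, t in enumerate(times):
            for r in range(course.shape[1]):
                rows.append(
                    {
                        "cluster": c,
                        "time_h": t,
                        "replicate": r + 1,
                        "value": course[i, r],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
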