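"""Structural priors: the trait correlation graph and feature/trait groups.

The graph-guided fused lasso consumes a graph over traits whose edges connect
highly correlated trait pairs; the sparse group lasso and the structured
input-output lasso consume a partition of the features (and, for the latter,
of the traits) obtained by hierarchical clustering of the column vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .data import FeatureMatrix, LabelledMatrix, TraitMatrix

__all__ = [
    "TraitGraph",
    "FeatureGroups",
    "TraitGroups",
    "build_trait_graph",
    "cluster_features",
    "cluster_traits",
]


@dataclass
class TraitGraph:
    """Undirected graph over traits with signed Pearson correlations per edge.

    Edge keys are sorted (m, l) trait-id pairs.  The fusion weight
    ``f(r) = |r|`` is the correlation magnitude; the sign is carried
    separately and flips the fused coefficient's sign in the penalty.
    """

    correlation: dict[tuple[str, str], float] = field(default_factory=dict)
    threshold: float = 0.7

    def __post_init__(self) -> None:
        for (m, l), r in self.correlation.items():
            if m == l:
                raise ValueError(f"self-loop on trait {m!r}")
            if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
                raise ValueError(f"correlation out of range for edge ({m}, {l}): {r}")

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.correlation)

    def weight(self, edge: tuple[str, str]) -> float:
        return abs(self.correlation[edge])

    def __len__(self) -> int:
        return len(self.correlation)


def _check_partition(assignment: dict[str, int], what: str) -> dict[int, int]:
    sizes: dict[int, int] = {}
    for g in assignment.values():
        sizes[g] = sizes.get(g, 0) + 1
    if not sizes:
        raise ValueError(f"empty {what} partition")
    return sizes


@dataclass
class FeatureGroups:
    """Partition of features into groups g in 1..m (every feature in one group)."""

    assignment: dict[str, int]

    def __post_init__(self) -> None:
        self.group_sizes = _check_partition(self.assignment, "feature")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for fid, g in self.assignment.items():
            out.setdefault(g, []).append(fid)
        return out


@dataclass
class TraitGroups(FeatureGroups):
    """Partition of traits into groups (the output-side analogue)."""


def build_trait_graph(Y: TraitMatrix, threshold: float = 0.7) -> TraitGraph:
    """Connect trait pairs whose absolute Pearson correlation >= threshold.

    The default threshold 0.7 keeps only very highly correlated trait pairs.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    if Y.n_columns < 2:
        raise ValueError("need at least 2 traits to build a trait graph")
    R = np.corrcoef(Y.values, rowvar=False)
    ids = Y.column_ids
    corr: dict[tuple[str, str], float] = {}
    K = len(ids)
    for a in range(K):
        for b in range(a + 1, K):
            if abs(R[a, b]) >= threshold:
                m, l = sorted((ids[a], ids[b]))
                corr[(m, l)] = float(R[a, b])
    return TraitGraph(corr, threshold=threshold)


def _cluster_columns(m: LabelledMatrix, n_groups: int) -> dict[str, int]:
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > m.n_columns:
        raise ValueError(f"n_groups={n_groups} exceeds number of columns {m.n_columns}")
    # Ward linkage on Euclidean distances between column vectors (Ward.D2).
    Z = linkage(m.values.T, method="ward", metric="euclidean")
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    return {cid: int(g) for cid, g in zip(m.column_ids, labels)}


def cluster_features(X: FeatureMatrix, n_groups: int = 20) -> FeatureGroups:
    """Group features by Ward-linkage hierarchical clustering of their columns."""
    return FeatureGroups(_cluster_columns(X, n_groups))


def cluster_traits(Y: TraitMatrix, n_groups: int = 20) -> TraitGroups:
    """Group traits the same way, for the output side of the structured lasso."""
    return TraitGroups(_cluster_columns(Y, n_groups))
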