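"""Coefficient-similarity networks.

A fitted coefficient matrix B (features x traits) induces two similarity
networks: between features (rows of B as profile vectors) and between traits
(columns of B).  Similarity is a scaled exponential kernel on Euclidean
distances with a locally adaptive bandwidth, the construction used by
similarity network fusion:

    W(i, j) = exp(-d^2(i, j) / (alpha * eps_ij)),
    eps_ij  = (mean_K(i) + mean_K(j) + d(i, j)) / 3,

where mean_K(i) is the mean distance from node i to its K nearest neighbors.
``normalize_kernel`` derives the row-stochastic full kernel P = D^-1 W and
the KNN-sparsified local affinity S used by the fusion iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .solvers import CoefficientMatrix

__all__ = ["AffinityNetwork", "NormalizedKernel", "coefficient_affinity", "normalize_kernel"]


@dataclass
class AffinityNetwork:
    """Symmetric nonnegative similarity matrix over features or traits."""

    W: np.ndarray
    node_ids: list[str]
    side: str = "feature"
    K: int | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        N = self.W.shape[0]
        if self.W.shape != (N, N) or N != len(self.node_ids):
            raise ValueError("W must be square and match node_ids")
        if np.abs(self.W - self.W.T).max() > 1e-12:
            raise ValueError("W must be symmetric")
        if self.W.min() < 0:
            raise ValueError("W must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass
class NormalizedKernel:
    """Row-stochastic full kernel P and KNN-sparse local affinity S."""

    P: np.ndarray
    S: np.ndarray
    K: int
    node_ids: list[str]


def _standardize_dims(V: np.ndarray) -> np.ndarray:
    """Standardize each dimension (column) of the node-by-dimension matrix."""
    mu = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (V - mu) / sd


def coefficient_affinity(
    B: CoefficientMatrix,
    side: str = "feature",
    K: int = 20,
    alpha: float = 0.5,
    standardize: bool = True,
) -> AffinityNetwork:
    """Build the similarity network of features (rows of B) or traits (columns).

    Profile vectors are standardized dimension-wise before the kernel, so the
    two sides are exact transposes of each other: the feature-side affinity of
    B equals the trait-side affinity of B transposed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if side == "feature":
        V = B.beta
        ids = list(B.feature_ids)
    elif side == "trait":
        V = B.beta.T
        ids = list(B.trait_ids)
    else:
        raise ValueError(f"side must be 'feature' or 'trait', got {side!r}")
    N = V.shape[0]
    zero_rows = int(np.sum(np.all(V == 0, axis=1)))
    if zero_rows > N / 2:
        raise ValueError(
            "degenerate coefficient matrix: more than half the nodes have "
            "all-zero coefficient vectors"
        )
    if standardize:
        V = _standardize_dims(V)
    D = squareform(pdist(V, metric="euclidean"))
    k_eff = min(K, N - 1)
    # mean distance of each node to its K nearest neighbors (excluding self)
    Dsorted = np.sort(D, axis=1)[:, 1 : k_eff + 1]
    mean_knn = Dsorted.mean(axis=1)
    eps = (mean_knn[:, None] + mean_knn[None, :] + D) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.exp(-(D**2) / (alpha * eps))
    W[~np.isfinite(W)] = 1.0  # zero distance with zero bandwidth
    np.fill_diagonal(W, 1.0)
    W = (W + W.T) / 2.0
    return AffinityNetwork(W, ids, side=side, K=K, alpha=alpha)


def normalize_kernel(
    W: AffinityNetwork, K: int, self_weight_half: bool = True
) -> NormalizedKernel:
    """Derive P = D^-1 W and the K-nearest-neighbor local affinity S.

    S keeps each row's K largest off-diagonal affinities.  By default the
    diagonal is excluded from the neighbor selection and re-inserted so that
    each row of S carries weight 1/2 on itself and 1/2 spread over its
    neighbors (the fusion method's convention); with
    ``self_weight_half=False`` the kept neighbors are simply renormalized.
    """
    A = W.W
    N = A.shape[0]
    row_sums = A.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("zero row sum in affinity matrix")
    P = A / row_sums[:, None]

    k_eff = min(K, N - 1)
    S = np.zeros_like(A)
    off = A.copy()
    np.fill_diagonal(off, -np.inf)
    for i in range(N):
        # ties broken by node order: stable sort on (-weight, index)
        order = np.lexsort((np.arange(N), -off[i]))
        nn = order[:k_eff]
        s = A[i, nn].sum()
        if s <= 0:
            raise ValueError(f"node {W.node_ids[i]!r} has no positive neighbors")
        if self_weight_half:
            S[i, nn] = A[i, nn] / (2.0 * s)
            S[i, i] = 0.5
        else:
            S[i, nn] = A[i, nn] / s
    return NormalizedKernel(P=P, S=S, K=K, node_ids=list(W.node_ids))
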