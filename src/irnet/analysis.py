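"""Topological diagnostics of thresholded networks and coefficient overlaps.

Covers the descriptive statistics used to compare the individual, fused and
correlation-baseline networks: node/edge counts, density, diameter of the
largest component, clustering coefficient, component structure, and the R^2
of a log-log straight-line fit to the degree distribution (a scale-freeness
score).  Graph quantities are computed directly (adjacency sets, BFS,
union-find) so they can be cross-checked against a graph library.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .data import LabelledMatrix
from .filtering import EdgeSet, _UnionFind
from .solvers import CoefficientMatrix

__all__ = [
    "NetworkReport",
    "OverlapReport",
    "network_properties",
    "degree_distribution_r2",
    "correlation_network",
    "top_k_overlap",
]


@dataclass
class NetworkReport:
    """Summary statistics of one thresholded network."""

    n_nodes: int
    n_edges: int
    density: float
    diameter: int
    clustering_coefficient: float
    global_transitivity: float
    average_neighbors: float
    n_components: int
    degree_r2: float | None


def _adjacency(edges: EdgeSet) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {v: set() for v in edges.node_ids}
    for a, b in edges.edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _components(adj: dict[str, set[str]]) -> list[set[str]]:
    seen: set[str] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if w not in comp:
                    comp.add(w)
                    queue.append(w)
        seen |= comp
        comps.append(comp)
    return comps


def _bfs_ecc(adj: dict[str, set[str]], start: str, comp: set[str]) -> int:
    dist = {start: 0}
    queue = deque([start])
    far = 0
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                far = max(far, dist[w])
                queue.append(w)
    if len(dist) != len(comp):  # pragma: no cover - defensive
        raise RuntimeError("BFS did not cover the component")
    return far


def network_properties(edges: EdgeSet) -> NetworkReport:
    """Compute the standard property table of a thresholded network.

    Density is 2E/(N(N-1)); the clustering coefficient is the mean local
    transitivity over nodes of degree >= 2 (the global triangle-ratio variant
    is reported alongside); the diameter is taken within the largest
    connected component.
    """
    if len(edges) == 0:
        raise ValueError("empty edge set")
    adj = _adjacency(edges)
    N = len(adj)
    E = len(edges.edges)
    density = 2 * E / (N * (N - 1)) if N > 1 else 0.0

    locals_ = []
    triangles = 0
    wedges = 0
    for v, nb in adj.items():
        d = len(nb)
        if d >= 2:
            links = sum(1 for x, y in combinations(sorted(nb), 2) if y in adj[x])
            locals_.append(2 * links / (d * (d - 1)))
            triangles += links
            wedges += d * (d - 1) // 2
    clustering = float(np.mean(locals_)) if locals_ else 0.0
    transitivity = triangles / wedges if wedges else 0.0

    comps = _components(adj)
    largest = max(comps, key=len)
    diameter = max(_bfs_ecc(adj, v, largest) for v in largest)

    try:
        r2 = degree_distribution_r2(edges)
    except ValueError:
        r2 = None
    return NetworkReport(
        n_nodes=N,
        n_edges=E,
        density=density,
        diameter=diameter,
        clustering_coefficient=clustering,
        global_transitivity=transitivity,
        average_neighbors=2 * E / N,
        n_components=len(comps),
        degree_r2=r2,
    )


def degree_distribution_r2(edges: EdgeSet) -> float:
    """R^2 of the log10(frequency) vs log10(degree) least-squares line.

    Computed on the unbinned table of distinct degrees with nonzero
    frequency; requires at least 3 distinct positive degrees.
    """
    adj = _adjacency(edges)
    degrees = np.array([len(nb) for nb in adj.values()])
    degrees = degrees[degrees > 0]
    uniq, freq = np.unique(degrees, return_counts=True)
    if len(uniq) < 3:
        raise ValueError("R^2 undefined: fewer than 3 distinct positive degrees")
    x = np.log10(uniq.astype(float))
    y = np.log10(freq.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0
    return 1.0 - ss_res / ss_tot


def correlation_network(M: LabelledMatrix, p_base: float = 0.01) -> EdgeSet:
    """Bonferroni-corrected all-pairs Pearson correlation network.

    Edge (i, j) is kept when the two-sided correlation-test p-value (t
    distribution on n-2 df) is below ``p_base`` divided by the number of
    tested pairs; edge weights are |r|.  Constant columns are excluded with a
    warning.
    """
    n = M.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples for correlation tests")
    sd = M.values.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [M.column_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"constant columns excluded from correlation network: {dropped[:5]}")
    V = M.values[:, keep]
    ids = [c for c, k in zip(M.column_ids, keep) if k]
    N = len(ids)
    R = np.corrcoef(V, rowvar=False)
    iu = np.triu_indices(N, k=1)
    r = np.clip(R[iu], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    n_pairs = N * (N - 1) // 2
    sig = p < p_base / n_pairs
    edges = []
    weights = []
    uf = _UnionFind(N)
    used = np.zeros(N, dtype=bool)
    for i, j, rv in zip(iu[0][sig], iu[1][sig], r[sig]):
        edges.append((ids[i], ids[j]))
        weights.append(float(abs(rv)))
        used[[i, j]] = True
        uf.union(int(i), int(j))
    comps: dict[str, int] = {}
    roots: dict[int, int] = {}
    for i in range(N):
        if used[i]:
            comps[ids[i]] = roots.setdefault(uf.find(i), len(roots))
    return EdgeSet(
        edges, weights, [ids[i] for i in range(N) if used[i]], 0.0,
        n_isolated=int(N - used.sum()), components=comps,
    )


@dataclass
class OverlapReport:
    """Top-k coefficient overlap across methods (the Venn-diagram counts)."""

    k: int
    top_pairs: dict[str, list[tuple[str, str]]]
    feature_sets: dict[str, set[str]] = field(default_factory=dict)
    intersections: dict[tuple[str, ...], int] = field(default_factory=dict)
    features_in_at_least_3: int = 0


def top_k_overlap(B_list: list[CoefficientMatrix], k: int = 200) -> OverlapReport:
    """Collect each method's k largest-|beta| (feature, trait) pairs and
    intersect the implicated feature sets across methods.

    Ties at the boundary are broken by (feature_id, trait_id) order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    names = []
    top_pairs: dict[str, list[tuple[str, str]]] = {}
    feature_sets: dict[str, set[str]] = {}
    ref = B_list[0]
    for idx, B in enumerate(B_list):
        if list(B.feature_ids) != list(ref.feature_ids) or list(B.trait_ids) != list(
            ref.trait_ids
        ):
            raise ValueError("coefficient matrices must share feature/trait ids")
        if k > B.beta.size:
            raise ValueError(f"k={k} exceeds number of coefficients {B.beta.size}")
        name = B.method or f"method{idx}"
        if name in top_pairs:
            name = f"{name}_{idx}"
        names.append(name)
        flat = [
            (-abs(B.beta[j, t]), B.feature_ids[j], B.trait_ids[t])
            for j in range(B.beta.shape[0])
            for t in range(B.beta.shape[1])
        ]
        flat.sort()
        pairs = [(f, t) for _, f, t in flat[:k]]
        top_pairs[name] = pairs
        feature_sets[name] = {f for f, _ in pairs}
    inter: dict[tuple[str, ...], int] = {}
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            common = set.intersection(*(feature_sets[c] for c in combo))
            inter[combo] = len(common)
    counts: dict[str, int] = {}
    for s in feature_sets.values():
        for f in s:
            counts[f] = counts.get(f, 0) + 1
    at_least_3 = sum(1 for c in counts.values() if c >= 3)
    return OverlapReport(
        k=k,
        top_pairs=top_pairs,
        feature_sets=feature_sets,
        intersections=inter,
        features_in_at_least_3=at_least_3,
    )
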