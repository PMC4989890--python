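"""Similarity network fusion and the consensus score for (K, alpha) selection.

The cross-diffusion update propagates similarity through each network's
K-nearest-neighbor backbone:

    P(v)  <-  S(v) . mean_{u != v} P(u) . S(v)^T

followed by symmetrization and row renormalization, for t iterations
(default 20); the fused network is the average of the diffused matrices.
Edges supported by several networks are reinforced while weak, unsupported
similarities decay.

The consensus score of a fused network against its m inputs is

    f(W, w_f) = mean_i SIM(w_f, w_i) + mean_{i<j} (1 - SIM(w_i, w_j)),

with SIM the Pearson correlation of the off-diagonal upper-triangle entries.
The (K, alpha) pair maximizing the score over a grid is selected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import AffinityNetwork, coefficient_affinity, normalize_kernel
from .solvers import CoefficientMatrix

__all__ = [
    "FusionState",
    "ConsensusScore",
    "snf_fuse",
    "snf_state",
    "consensus_score",
    "select_k_alpha",
]


@dataclass
class FusionState:
    """Intermediate matrices of one fusion run, for auditing the iteration."""

    P_list: list[np.ndarray]
    S_list: list[np.ndarray]
    t: int
    P_c: np.ndarray
    node_ids: list[str]
    row_sum_dev: list[float] = field(default_factory=list)


def _check_same_nodes(networks: list[AffinityNetwork]) -> list[str]:
    ids = networks[0].node_ids
    for net in networks[1:]:
        if list(net.node_ids) != list(ids):
            extra = sorted(set(net.node_ids) ^ set(ids))
            raise ValueError(f"networks differ in node sets: {extra[:10]}")
    return list(ids)


def snf_state(
    networks: list[AffinityNetwork],
    K: int,
    t: int = 20,
    self_weight_half: bool = True,
) -> FusionState:
    """Run the fusion iteration and return all intermediate state."""
    if len(networks) < 2:
        raise ValueError("need at least 2 networks to fuse")
    if t < 1:
        raise ValueError("t must be >= 1")
    ids = _check_same_nodes(networks)
    kernels = [normalize_kernel(w, K, self_weight_half=self_weight_half) for w in networks]
    P_list = [k.P.copy() for k in kernels]
    S_list = [k.S for k in kernels]
    m = len(P_list)
    dev = []
    for _ in range(t):
        new = []
        for v in range(m):
            others = sum(P_list[u] for u in range(m) if u != v) / (m - 1)
            P = S_list[v] @ others @ S_list[v].T
            P = (P + P.T) / 2.0
            P = P / P.sum(axis=1, keepdims=True)
            new.append(P)
        P_list = new
        dev.append(max(np.abs(P.sum(axis=1) - 1.0).max() for P in P_list))
    P_c = sum(P_list) / m
    P_c = (P_c + P_c.T) / 2.0
    return FusionState(P_list, S_list, t, P_c, ids, dev)


def snf_fuse(
    networks: list[AffinityNetwork],
    K: int,
    t: int = 20,
    self_weight_half: bool = True,
) -> AffinityNetwork:
    """Fuse m >= 2 affinity networks into their diffused consensus."""
    state = snf_state(networks, K, t=t, self_weight_half=self_weight_half)
    side = networks[0].side
    return AffinityNetwork(state.P_c, state.node_ids, side=side, K=K)


@dataclass
class ConsensusScore:
    """Value and components of the fused-vs-inputs consensus criterion."""

    value: float
    sim_to_fused: list[float]
    pairwise_sim: dict[tuple[int, int], float]
    K: int | None = None
    alpha: float | None = None


def _offdiag_upper(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def _sim(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        raise ValueError("SIM undefined: constant off-diagonal entries")
    return float(np.corrcoef(a, b)[0, 1])


def consensus_score(
    fused: AffinityNetwork | np.ndarray,
    networks: list[AffinityNetwork],
    K: int | None = None,
    alpha: float | None = None,
) -> ConsensusScore:
    """Score a fused network against its inputs (higher is better)."""
    Wf = fused.W if isinstance(fused, AffinityNetwork) else np.asarray(fused)
    vf = _offdiag_upper(Wf)
    vis = [_offdiag_upper(net.W) for net in networks]
    N = len(networks)
    sims = [_sim(vf, vi) for vi in vis]
    pair = {
        (i, j): _sim(vis[i], vis[j])
        for i, j in itertools.combinations(range(N), 2)
    }
    first = sum(sims) / N
    n_pairs = N * (N - 1) // 2
    second = sum(1.0 - s for s in pair.values()) / n_pairs if n_pairs else 0.0
    return ConsensusScore(first + second, sims, pair, K=K, alpha=alpha)


def select_k_alpha(
    B_list: list[CoefficientMatrix],
    side: str,
    K_range=range(2, 21),
    alpha_range=(0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    t: int = 20,
) -> tuple[int, float, pd.DataFrame]:
    """Grid-search (K, alpha): rebuild affinities and the fusion per cell.

    Returns the score-maximizing pair (ties broken toward smaller K, then
    smaller alpha) together with the full grid table.  A failing cell is
    recorded as NaN; only an entirely failed grid raises.
    """
    K_range = list(K_range)
    alpha_range = list(alpha_range)
    if not K_range or not alpha_range:
        raise ValueError("empty (K, alpha) grid")
    rows = []
    best: tuple[int, float] | None = None
    best_score = -np.inf
    for K in sorted(K_range):
        for alpha in sorted(alpha_range):
            try:
                nets = [
                    coefficient_affinity(B, side=side, K=K, alpha=alpha)
                    for B in B_list
                ]
                fused = snf_fuse(nets, K=K, t=t)
                score = consensus_score(fused, nets, K=K, alpha=alpha).value
            except Exception:
                rows.append({"K": K, "alpha": alpha, "score": np.nan})
                continue
            rows.append({"K": K, "alpha": alpha, "score": score})
            if score > best_score:
                best_score = score
                best = (K, alpha)
    table = pd.DataFrame(rows)
    if best is None:
        raise ValueError("all (K, alpha) grid cells failed")
    return best[0], best[1], table
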