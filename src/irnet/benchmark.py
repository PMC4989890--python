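"""End-to-end synthetic benchmark: fits, prediction error, and networks.

Reproduces the study design on generated data: a 2/3-1/3 train/test split,
per-method penalty selection by cross-validation on the training split, test
MSE per method, and the full network stage (affinity -> fusion -> permutation
cutoff) on the coefficient matrices.

Every method is tuned over a full geometric penalty path (lambda_min_fraction
0.01) here: restricting the sparse-group-lasso path to [0.8*lambda_max,
lambda_max] — the restriction used on the reference cancer datasets — leaves
near-null fits on strong-signal synthetic data whose all-zero coefficient
rows make the downstream affinity step degenerate, so the benchmark gives
each method the same full search range.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import filtering, fusion, network, priors, solvers
from .data import FeatureMatrix, TraitMatrix
from .simulate import SimulatedData, default_scenario, generate

__all__ = ["split_train_test", "tune_and_fit", "benchmark_fits", "network_stage"]

CV_FIT_KWARGS = {"tol": 1e-4, "max_iter": 400}
FIT_KWARGS = {"tol": 1e-5, "max_iter": 2000}
METHODS = ("lasso", "gflasso", "sgl", "siol")


def _take(m, idx):
    return replace(
        m, values=m.values[idx], sample_ids=[m.sample_ids[i] for i in idx]
    )


def split_train_test(X: FeatureMatrix, Y: TraitMatrix, seed: int, train_frac=2 / 3):
    rng = np.random.default_rng(seed)
    n = X.n_samples
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    tr, te = perm[:n_train], perm[n_train:]
    return _take(X, tr), _take(Y, tr), _take(X, te), _take(Y, te)


def tune_and_fit(
    X: FeatureMatrix,
    Y: TraitMatrix,
    seed: int,
    n_groups: int = 20,
    corr_threshold: float = 0.7,
    folds: int = 3,
    n_lambda: int = 6,
) -> dict[str, solvers.CoefficientMatrix]:
    """CV-tune and fit all four methods on (X, Y)."""
    graph = priors.build_trait_graph(Y, threshold=corr_threshold)
    fgroups = priors.cluster_features(X, min(n_groups, X.n_columns))
    tgroups = priors.cluster_traits(Y, min(n_groups, Y.n_columns))
    fits: dict[str, solvers.CoefficientMatrix] = {}

    pc = solvers.select_lambda_cv(
        "lasso", X, Y, folds=folds, seed=seed, n_lambda=n_lambda,
        fit_kwargs=CV_FIT_KWARGS,
    )
    fits["lasso"] = solvers.fit_lasso(X, Y, pc.lam, **FIT_KWARGS)

    pc = solvers.select_lambda_cv(
        "gflasso", X, Y, folds=folds, seed=seed, n_lambda=n_lambda,
        graph=graph, fit_kwargs=CV_FIT_KWARGS,
    )
    fits["gflasso"] = solvers.fit_gflasso(X, Y, graph, pc.lam, pc.gamma, **FIT_KWARGS)

    pc = solvers.select_lambda_cv(
        "sgl", X, Y, folds=folds, seed=seed, n_lambda=n_lambda,
        groups=fgroups, lambda_min_fraction=0.01, fit_kwargs=CV_FIT_KWARGS,
    )
    fits["sgl"] = solvers.fit_sgl(X, Y, fgroups, pc.lam, pc.alpha, **FIT_KWARGS)

    pc = solvers.select_lambda_cv(
        "siol", X, Y, folds=folds, seed=seed, n_lambda=n_lambda,
        groups=fgroups, trait_groups=tgroups, fit_kwargs=CV_FIT_KWARGS,
    )
    fits["siol"] = solvers.fit_siol(
        X, Y, fgroups, tgroups, pc.lam, pc.lam2, pc.lam3, **FIT_KWARGS
    )
    return fits


def benchmark_fits(seed: int, scenario=None) -> dict:
    """Generate one dataset, fit all methods on 2/3 of it, score on 1/3."""
    sim = generate(scenario or default_scenario(), seed=seed)
    Xtr, Ytr, Xte, Yte = split_train_test(sim.X, sim.Y, seed=seed)
    fits = tune_and_fit(Xtr, Ytr, seed=seed)
    mse = {}
    for name, B in fits.items():
        _, mse[name] = solvers.evaluate_mse(B, Xte, Yte)
    return {"sim": sim, "fits": fits, "test_mse": mse}


def support_share(edges: filtering.EdgeSet, sim: SimulatedData) -> float:
    """Fraction of edges joining features active in a common trait block."""
    if len(edges) == 0:
        return float("nan")
    members = sim.trait_groups.members()
    tidx = {t: i for i, t in enumerate(sim.Y.trait_ids)}
    fidx = {f: i for i, f in enumerate(sim.X.feature_ids)}
    blocks = [np.array([tidx[t] for t in b]) for b in members.values()]
    share = 0
    for a, b in edges.edges:
        sa = {i for i, blk in enumerate(blocks) if sim.support[fidx[a], blk].any()}
        sb = {i for i, blk in enumerate(blocks) if sim.support[fidx[b], blk].any()}
        if sa & sb:
            share += 1
    return share / len(edges)


def network_stage(
    fits: dict[str, solvers.CoefficientMatrix],
    side: str = "feature",
    K: int = 20,
    alpha: float = 0.5,
    t: int = 20,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Affinities, fusion, and the permutation cutoff for every network."""
    nets = {
        m: network.coefficient_affinity(B, side=side, K=K, alpha=alpha)
        for m, B in fits.items()
    }
    fused = fusion.snf_fuse(list(nets.values()), K=K, t=t)
    out = {"networks": nets, "fused": fused, "edges": {}, "cutoffs": {}}
    for name, W in list(nets.items()) + [("fused", fused)]:
        search = filtering.find_cutoff(W, n_perm=n_perm, seed=seed)
        out["cutoffs"][name] = search.cutoff
        out["edges"][name] = filtering.filter_edges(W, search.cutoff)
    return out
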