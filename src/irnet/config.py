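"""Run configuration and the end-to-end pipeline.

``run_pipeline`` chains every stage: input loading (or simulation) ->
structural priors -> the four regression fits -> feature- and trait-side
affinity networks -> fusion -> permutation cutoff -> filtered edge sets and
property reports.  All intermediates are persisted as delimited text in the
output directory, together with a resolved copy of the configuration, so a
run is reproducible from its artifacts alone.

Sub-seeds are derived from the master seed per stage through
``numpy.random.SeedSequence([master_seed, stage_index])``, so any stage can
be re-run independently with the same stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analysis, filtering, fusion, io, network, priors, simulate, solvers
from .data import FeatureMatrix, TraitMatrix, standardize

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger("irnet")

_STAGES = ["simulate", "fit", "network", "fuse", "cutoff", "analyze"]


def stage_seed(master_seed: int, stage: str) -> int:
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([master_seed, idx])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the reference analysis."""

    seed: int = 0
    outdir: str = "irnet_run"
    # inputs: either paths to feature/trait TSVs, or a simulation scenario
    features_path: str | None = None
    traits_path: str | None = None
    scenario: str | dict | None = "default"
    standardize_inputs: bool = True
    # priors
    correlation_threshold: float = 0.7
    n_feature_groups: int = 20
    n_trait_groups: int = 20
    # penalty selection
    cv_folds: int = 3
    cv: bool = True
    sgl_alpha: float = 0.1
    fixed_penalties: dict = field(default_factory=dict)
    # affinity / fusion
    knn: int = 20
    kernel_alpha: float = 0.5
    fusion_iterations: int = 20
    grid_search: bool = False
    # cutoff
    permutations: int = 100
    grid_step: float = 0.005
    # analysis
    top_k: int = 200

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(cfg: RunConfig) -> tuple[FeatureMatrix, TraitMatrix, object | None]:
    if cfg.features_path and cfg.traits_path:
        X = io.read_matrix(cfg.features_path, kind="feature")
        Y = io.read_matrix(cfg.traits_path, kind="trait")
        if X.sample_ids != Y.sample_ids:
            raise ValueError("feature and trait matrices differ in samples")
        if cfg.standardize_inputs:
            X, Y = standardize(X), standardize(Y)
        return X, Y, None
    if cfg.scenario is None:
        raise ValueError("either input paths or a simulation scenario is required")
    sc = (
        simulate.default_scenario()
        if cfg.scenario == "default"
        else simulate.SimulationScenario(**cfg.scenario)
    )
    sim = simulate.generate(sc, seed=stage_seed(cfg.seed, "simulate"))
    return sim.X, sim.Y, sim


def fit_all_methods(
    X: FeatureMatrix,
    Y: TraitMatrix,
    graph: priors.TraitGraph,
    fgroups: priors.FeatureGroups,
    tgroups: priors.TraitGroups,
    cfg: RunConfig,
) -> dict[str, solvers.CoefficientMatrix]:
    """Fit lasso, GFLasso, SGL and SIOL with CV-selected (or fixed) penalties."""
    seed = stage_seed(cfg.seed, "fit")
    fits: dict[str, solvers.CoefficientMatrix] = {}
    fixed = cfg.fixed_penalties
    fit_kwargs = {"tol": 1e-5, "max_iter": 2000}

    if cfg.cv and "lasso" not in fixed:
        pc = solvers.select_lambda_cv(
            "lasso", X, Y, folds=cfg.cv_folds, seed=seed, fit_kwargs=fit_kwargs
        )
        lam_lasso = pc.lam
    else:
        lam_lasso = fixed.get("lasso", {}).get("lam", 1.0)
    fits["lasso"] = solvers.fit_lasso(X, Y, lam_lasso)

    if cfg.cv and "gflasso" not in fixed:
        pc = solvers.select_lambda_cv(
            "gflasso", X, Y, folds=cfg.cv_folds, seed=seed, graph=graph,
            fit_kwargs=fit_kwargs,
        )
        lam_gf, gamma = pc.lam, pc.gamma
    else:
        d = fixed.get("gflasso", {})
        lam_gf, gamma = d.get("lam", 1.0), d.get("gamma", 1.0)
    fits["gflasso"] = solvers.fit_gflasso(X, Y, graph, lam_gf, gamma)

    if cfg.cv and "sgl" not in fixed:
        pc = solvers.select_lambda_cv(
            "sgl", X, Y, folds=cfg.cv_folds, seed=seed, groups=fgroups,
            alpha=cfg.sgl_alpha, fit_kwargs=fit_kwargs,
        )
        lam_sgl = pc.lam
    else:
        lam_sgl = fixed.get("sgl", {}).get("lam", 0.1)
    fits["sgl"] = solvers.fit_sgl(X, Y, fgroups, lam_sgl, alpha=cfg.sgl_alpha)

    if cfg.cv and "siol" not in fixed:
        pc = solvers.select_lambda_cv(
            "siol", X, Y, folds=cfg.cv_folds, seed=seed, groups=fgroups,
            trait_groups=tgroups, fit_kwargs=fit_kwargs,
        )
        l1, l2, l3 = pc.lam, pc.lam2, pc.lam3
    else:
        d = fixed.get("siol", {})
        l1, l2, l3 = d.get("lam1", 0.1), d.get("lam2", 0.3), d.get("lam3", 0.2)
    fits["siol"] = solvers.fit_siol(X, Y, fgroups, tgroups, l1, l2, l3)
    return fits


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages and return the artifact directory."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    logger.info("run starting: seed=%d outdir=%s", cfg.seed, out)
    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    stage = "inputs"
    try:
        X, Y, sim = _load_inputs(cfg)
        io.write_matrix(X, out / "features.tsv")
        io.write_matrix(Y, out / "traits.tsv")

        stage = "priors"
        graph = priors.build_trait_graph(Y, threshold=cfg.correlation_threshold)
        fgroups = priors.cluster_features(X, min(cfg.n_feature_groups, X.n_columns))
        tgroups = priors.cluster_traits(Y, min(cfg.n_trait_groups, Y.n_columns))
        io.write_edge_list(
            [(m, l, r) for (m, l), r in graph.correlation.items()],
            out / "trait_graph.tsv",
        )

        stage = "fit"
        fits = fit_all_methods(X, Y, graph, fgroups, tgroups, cfg)
        for name, B in fits.items():
            B.to_frame().to_csv(out / f"beta_{name}.tsv", sep="\t")
            with open(out / f"diagnostics_{name}.json", "w") as fh:
                json.dump(
                    {
                        "converged": B.diagnostics.converged,
                        "n_iter": B.diagnostics.n_iter,
                        "final_objective": B.diagnostics.objective[-1],
                        "sparsity": B.sparsity,
                        "penalties": B.penalties,
                    },
                    fh,
                    indent=2,
                )

        stage = "network"
        methods = list(fits)
        nets: dict[str, dict[str, network.AffinityNetwork]] = {}
        for side in ("feature", "trait"):
            nets[side] = {}
            for name in methods:
                aff = network.coefficient_affinity(
                    fits[name], side=side, K=cfg.knn, alpha=cfg.kernel_alpha
                )
                nets[side][name] = aff
                io.write_matrix(
                    network_to_matrix(aff), out / f"affinity_{side}_{name}.tsv"
                )

        stage = "fuse"
        fused: dict[str, network.AffinityNetwork] = {}
        for side in ("feature", "trait"):
            if cfg.grid_search:
                K_sel, a_sel, table = fusion.select_k_alpha(
                    [fits[m] for m in methods], side,
                    t=cfg.fusion_iterations,
                )
                table.to_csv(out / f"grid_{side}.csv", index=False)
                side_nets = [
                    network.coefficient_affinity(fits[m], side=side, K=K_sel, alpha=a_sel)
                    for m in methods
                ]
            else:
                K_sel = cfg.knn
                side_nets = [nets[side][m] for m in methods]
            fused[side] = fusion.snf_fuse(side_nets, K=K_sel, t=cfg.fusion_iterations)
            io.write_matrix(
                network_to_matrix(fused[side]), out / f"fused_{side}.tsv"
            )

        stage = "cutoff"
        cutoff_seed = stage_seed(cfg.seed, "cutoff")
        reports = {}
        for side in ("feature", "trait"):
            search = filtering.find_cutoff(
                fused[side], n_perm=cfg.permutations, seed=cutoff_seed,
                grid_step=cfg.grid_step,
            )
            search.table.to_csv(out / f"cutoff_table_{side}.csv", index=False)
            edges = filtering.filter_edges(fused[side], search.cutoff)
            io.write_edge_list(edges.to_edge_list(), out / f"edges_{side}.tsv")
            io.write_sif(edges.to_edge_list(), out / f"edges_{side}.sif")
            reports[side] = (search, edges)

        stage = "analyze"
        for side, (search, edges) in reports.items():
            if len(edges):
                rep = analysis.network_properties(edges)
                payload = dataclasses.asdict(rep)
            else:
                payload = {"n_edges": 0}
            payload["cutoff"] = search.cutoff
            payload["n_isolated"] = edges.n_isolated
            with open(out / f"report_{side}.json", "w") as fh:
                json.dump(payload, fh, indent=2)
        overlap = analysis.top_k_overlap(
            [fits[m] for m in methods], k=min(cfg.top_k, X.n_columns * Y.n_columns)
        )
        with open(out / "overlap.json", "w") as fh:
            json.dump(
                {
                    "k": overlap.k,
                    "intersections": {
                        "+".join(c): v for c, v in overlap.intersections.items()
                    },
                    "features_in_at_least_3": overlap.features_in_at_least_3,
                },
                fh,
                indent=2,
            )
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    logger.info("run finished in %.1f s", time.time() - t0)
    return out


def network_to_matrix(net: network.AffinityNetwork):
    from .data import LabelledMatrix

    return LabelledMatrix(net.W, list(net.node_ids), list(net.node_ids))
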