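"""Synthetic feature/trait matrices with planted structured coefficients.

The generator emulates the generative model behind the pipeline: standardized
feature columns with correlated blocks (recoverable by hierarchical
clustering), a sparse coefficient matrix whose support is aligned with the
feature groups and shared across traits of the same block, and Gaussian
noise correlated within trait blocks so that the trait correlation graph at
a high threshold is non-trivial.  Every stage of the pipeline can then be
exercised, and scored against the planted truth, without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FeatureMatrix, TraitMatrix, standardize
from .priors import FeatureGroups, TraitGraph, TraitGroups

__all__ = ["SimulationScenario", "SimulatedData", "default_scenario", "generate"]


@dataclass
class SimulationScenario:
    """Study design for one simulated dataset.

    ``block_correlation`` controls both the correlation of feature columns
    within a feature group and the noise correlation within a trait block.
    Effect sizes |beta| are drawn uniformly from [effect_low, effect_high]
    with random signs.
    """

    n_samples: int = 100
    n_features: int = 200
    n_traits: int = 50
    n_feature_groups: int = 10
    n_trait_blocks: int = 5
    support_fraction: float = 0.05
    effect_low: float = 0.5
    effect_high: float = 1.5
    block_correlation: float = 0.8
    noise_sd: float = 0.5
    active_groups_per_block: int = 2
    trait_jitter: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.support_fraction < 1.0:
            raise ValueError("support_fraction must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must lie in [0, 1)")
        for name in (
            "n_samples", "n_features", "n_traits",
            "n_feature_groups", "n_trait_blocks",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_feature_groups > self.n_features:
            raise ValueError("more feature groups than features")
        if self.n_trait_blocks > self.n_traits:
            raise ValueError("more trait blocks than traits")
        if self.support_fraction * self.n_features * self.n_traits < 1:
            raise ValueError("infeasible support: fraction * J * K < 1")


def default_scenario() -> SimulationScenario:
    """The reference study design: n=100, J=200, K=50, 10 feature groups,
    5 trait blocks, 5% support, |beta| in [0.5, 1.5], block correlation 0.8,
    noise SD 0.5."""
    return SimulationScenario()


@dataclass
class SimulatedData:
    """One generated dataset together with its planted truth."""

    X: FeatureMatrix
    Y: TraitMatrix
    beta: np.ndarray  # planted J x K coefficients (pre-standardization scale)
    feature_groups: FeatureGroups
    trait_groups: TraitGroups
    trait_graph: TraitGraph
    scenario: SimulationScenario
    seed: int

    @property
    def support(self) -> np.ndarray:
        return self.beta != 0.0


def _split(n_items: int, n_parts: int) -> list[np.ndarray]:
    return np.array_split(np.arange(n_items), n_parts)


def generate(scenario: SimulationScenario, seed: int) -> SimulatedData:
    """Draw one dataset from the scenario; fixed seed gives identical output."""
    sc = scenario
    rng = np.random.default_rng(seed)
    n, J, K = sc.n_samples, sc.n_features, sc.n_traits
    rho = sc.block_correlation

    feature_ids = [f"F{j:04d}" for j in range(J)]
    trait_ids = [f"T{k:03d}" for k in range(K)]
    sample_ids = [f"S{i:04d}" for i in range(n)]

    fgroups = _split(J, sc.n_feature_groups)
    tblocks = _split(K, sc.n_trait_blocks)

    # correlated Gaussian features: shared factor per group
    X = np.empty((n, J))
    for g in fgroups:
        z = rng.standard_normal(n)
        noise = rng.standard_normal((n, len(g)))
        X[:, g] = np.sqrt(rho) * z[:, None] + np.sqrt(1 - rho) * noise

    # planted coefficients: per trait block, a shared group-aligned support
    B = np.zeros((J, K))
    s_col = max(1, round(sc.support_fraction * J))
    for block in tblocks:
        n_active = min(sc.active_groups_per_block, len(fgroups))
        chosen = rng.choice(len(fgroups), size=n_active, replace=False)
        pool = np.concatenate([fgroups[g] for g in chosen])
        support = rng.choice(pool, size=min(s_col, len(pool)), replace=False)
        base = rng.uniform(sc.effect_low, sc.effect_high, size=len(support))
        base *= rng.choice([-1.0, 1.0], size=len(support))
        for k in block:
            jitter = 1.0 + sc.trait_jitter * rng.standard_normal(len(support))
            B[support, k] = base * jitter

    # noise correlated within trait blocks
    eps = np.empty((n, K))
    for block in tblocks:
        u = rng.standard_normal(n)
        e = rng.standard_normal((n, len(block)))
        eps[:, block] = sc.noise_sd * (
            np.sqrt(rho) * u[:, None] + np.sqrt(1 - rho) * e
        )
    Y = X @ B + eps

    Xm = standardize(FeatureMatrix(X, sample_ids, feature_ids))
    Ym = standardize(TraitMatrix(Y, sample_ids, trait_ids))

    feature_groups = FeatureGroups(
        {feature_ids[j]: gi + 1 for gi, g in enumerate(fgroups) for j in g}
    )
    trait_groups = TraitGroups(
        {trait_ids[k]: bi + 1 for bi, b in enumerate(tblocks) for k in b}
    )
    corr = {}
    Yv = Ym.values
    for block in tblocks:
        for a_i, a in enumerate(block):
            for b in block[a_i + 1:]:
                r = float(np.corrcoef(Yv[:, a], Yv[:, b])[0, 1])
                m, l = sorted((trait_ids[a], trait_ids[b]))
                corr[(m, l)] = r
    graph = TraitGraph(corr, threshold=0.0)
    return SimulatedData(
        Xm, Ym, B, feature_groups, trait_groups, graph, sc, seed
    )
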