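import numpy as np
import pytest

from irnet.data import FeatureMatrix, TraitMatrix, standardize
from irnet.network import AffinityNetwork


def make_feature_matrix(values, prefix="f"):
    values = np.asarray(values, dtype=float)
    n, J = values.shape
    return FeatureMatrix(
        values, [f"s{i}" for i in range(n)], [f"{prefix}{j}" for j in range(J)]
    )


def make_trait_matrix(values, prefix="t"):
    values = np.asarray(values, dtype=float)
    n, K = values.shape
    return TraitMatrix(
        values, [f"s{i}" for i in range(n)], [f"{prefix}{k}" for k in range(K)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_xy(rng):
    """Standardized 30x5 feature matrix and a 3-trait response with signal."""
    X = standardize(make_feature_matrix(rng.standard_normal((30, 5))))
    B = np.zeros((5, 3))
    B[0, 0] = 1.5
    B[2, 1] = -1.0
    B[4, 2] = 0.8
    Y = make_trait_matrix(X.values @ B + 0.1 * rng.standard_normal((30, 3)))
    return X, Y, B


def planted_block_network(seed, n_nodes=20, block=10, hi=(0.85, 0.95), lo=(0.05, 0.15)):
    """Two-community weighted network: strong within blocks, weak between."""
    rng = np.random.default_rng(seed)
    W = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            same = (i < block) == (j < block)
            w = rng.uniform(*hi) if same else rng.uniform(*lo)
            W[i, j] = W[j, i] = w
    np.fill_diagonal(W, 1.0)
    return AffinityNetwork(W, [f"n{i}" for i in range(n_nodes)])


def random_affinity(rng, n_nodes, ids=None):
    A = rng.uniform(0.05, 1.0, (n_nodes, n_nodes))
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return AffinityNetwork(A, ids or [f"n{i}" for i in range(n_nodes)])
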