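"""Solver correctness: closed forms, reduction identities, brute-force oracles.

The brute-force oracles re-state each objective directly from its formula
(independently of the solver module's own objective helpers) and minimize it
with a generic numeric optimizer from several starts.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from irnet.data import standardize
from irnet.priors import FeatureGroups, TraitGraph, TraitGroups
from irnet.solvers import (
    evaluate_mse,
    fit_gflasso,
    fit_lasso,
    fit_sgl,
    fit_siol,
    gflasso_lambda_heuristic,
    select_lambda_cv,
)

from conftest import make_feature_matrix, make_trait_matrix


def brute_minimum(obj, dim, rng, n_starts=12):
    best = np.inf
    for _ in range(n_starts):
        res = minimize(
            obj, rng.standard_normal(dim), method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-12, maxiter=30000, maxfev=30000),
        )
        best = min(best, res.fun)
    return best


def lasso_obj_oracle(Xv, Yc, lam):
    def obj(b):
        B = b.reshape(Xv.shape[1], Yc.shape[1])
        R = Yc - Xv @ B
        return np.sum(R * R) + lam * np.abs(B).sum()

    return obj


class TestLasso:
    def test_full_shrinkage_threshold(self, small_xy):
        X, Y, _ = small_xy
        Yc = Y.values - Y.values.mean(axis=0)
        lam_max = 2 * np.abs(X.values.T @ Yc).max()
        fit = fit_lasso(X, Y, lam_max * 1.001)
        assert np.all(fit.beta == 0.0)

    def test_unpenalized_limit_is_ols(self, small_xy):
        X, Y, _ = small_xy
        fit = fit_lasso(X, Y, 0.0, tol=1e-12)
        Yc = Y.values - Y.values.mean(axis=0)
        ols = np.linalg.lstsq(X.values, Yc, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)

    def test_orthonormal_design_soft_threshold(self, rng):
        # X^T X = n I: every coefficient is an entrywise soft-threshold of OLS
        n, J = 24, 6
        Q, _ = np.linalg.qr(rng.standard_normal((n, J)))
        Xv = Q * np.sqrt(n)
        X = make_feature_matrix(Xv)
        Yv = rng.standard_normal((n, 2))
        Y = make_trait_matrix(Yv)
        lam = 3.7
        fit = fit_lasso(X, Y, lam, tol=1e-12)
        Yc = Yv - Yv.mean(axis=0)
        ols = Xv.T @ Yc / n
        expected = np.sign(ols) * np.maximum(np.abs(ols) - lam / (2 * n), 0.0)
        np.testing.assert_allclose(fit.beta, expected, atol=1e-8)

    def test_negative_lambda_rejected(self, small_xy):
        X, Y, _ = small_xy
        with pytest.raises(ValueError):
            fit_lasso(X, Y, -0.1)

    def test_objective_monotone_and_beats_zero(self, small_xy):
        X, Y, _ = small_xy
        fit = fit_lasso(X, Y, 1.0)
        traj = np.array(fit.diagnostics.objective)
        assert np.all(np.diff(traj) <= 1e-9)
        assert traj[-1] <= traj[0]  # objective at B=0 is the start


class TestGFLasso:
    def _toy(self, rng):
        n, J = 10, 2
        X = standardize(make_feature_matrix(rng.standard_normal((n, J))))
        z = rng.standard_normal(n)
        Yv = np.column_stack(
            [z + 0.3 * rng.standard_normal(n), z + 0.3 * rng.standard_normal(n)]
        )
        Y = make_trait_matrix(Yv)
        r = float(np.corrcoef(Yv[:, 0], Yv[:, 1])[0, 1])
        return X, Y, TraitGraph({("t0", "t1"): r}, threshold=0.0)

    def test_objective_matches_bruteforce(self, rng):
        X, Y, graph = self._toy(rng)
        lam, gamma = 1.5, 2.0
        fit = fit_gflasso(X, Y, graph, lam, gamma)
        Yc = Y.values - Y.values.mean(axis=0)
        r = graph.correlation[("t0", "t1")]
        f_e, s_e = abs(r), np.sign(r)

        def obj(b):
            B = b.reshape(2, 2)
            R = Yc - X.values @ B
            fuse = np.abs(B[:, 0] - s_e * B[:, 1]).sum()
            return np.sum(R * R) + lam * np.abs(B).sum() + gamma * f_e * fuse

        best = brute_minimum(obj, 4, rng)
        assert obj(fit.beta.ravel()) <= best + 1e-4

    def test_zero_gamma_and_empty_graph_reduce_to_lasso(self, small_xy, rng):
        X, Y, _ = small_xy
        graph = TraitGraph({("t0", "t1"): 0.9}, threshold=0.0)
        lam = 2.0
        lasso = fit_lasso(X, Y, lam)
        Yc = Y.values - Y.values.mean(axis=0)
        oracle = lasso_obj_oracle(X.values, Yc, lam)
        ref = oracle(lasso.beta.ravel())
        for fit in (
            fit_gflasso(X, Y, graph, lam, 0.0),
            fit_gflasso(X, Y, TraitGraph({}), lam, 1.0),
        ):
            gap = oracle(fit.beta.ravel()) - ref
            assert abs(gap) <= 1e-5 * max(1.0, abs(ref))

    def test_self_loop_rejected(self, small_xy):
        X, Y, _ = small_xy
        with pytest.raises(ValueError):
            fit_gflasso(X, Y, TraitGraph({("t0", "t0"): 1.0}), 1.0, 1.0)

    def test_heuristic_lambda(self):
        B = np.zeros((3, 2))
        B[0, 0], B[1, 0], B[2, 1] = 0.1, 0.3, 0.5
        cm_kwargs = dict(
            intercepts=np.zeros(2), feature_ids=["a", "b", "c"], trait_ids=["x", "y"]
        )
        from irnet.solvers import CoefficientMatrix

        assert gflasso_lambda_heuristic(
            CoefficientMatrix(B, **cm_kwargs), 10
        ) == pytest.approx(3.0)
        B1 = np.zeros((3, 2))
        B1[1, 1] = 0.2
        assert gflasso_lambda_heuristic(
            CoefficientMatrix(B1, **cm_kwargs), 5
        ) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            gflasso_lambda_heuristic(
                CoefficientMatrix(np.zeros((3, 2)), **cm_kwargs), 5
            )

    def test_heuristic_matches_sort_oracle(self, rng):
        from irnet.solvers import CoefficientMatrix

        B = rng.standard_normal((6, 4))
        B[rng.random((6, 4)) < 0.4] = 0.0
        if not B.any():
            B[0, 0] = 1.0
        cm = CoefficientMatrix(
            B, np.zeros(4), [f"f{i}" for i in range(6)], [f"t{i}" for i in range(4)]
        )
        nz = sorted(abs(v) for v in B.ravel() if v != 0)
        k = len(nz)
        med = nz[k // 2] if k % 2 else 0.5 * (nz[k // 2 - 1] + nz[k // 2])
        assert gflasso_lambda_heuristic(cm, 7) == pytest.approx(med * 7)


class TestSGL:
    def test_objective_matches_bruteforce(self, rng):
        n, J = 12, 3
        X = standardize(make_feature_matrix(rng.standard_normal((n, J))))
        y = X.values[:, 0] * 1.2 - X.values[:, 2] * 0.7 + 0.3 * rng.standard_normal(n)
        Y = make_trait_matrix(y[:, None])
        groups = FeatureGroups({"f0": 1, "f1": 1, "f2": 2})
        lam, alpha = 0.3, 0.4
        fit = fit_sgl(X, Y, groups, lam, alpha)
        yc = y - y.mean()

        def obj(b):
            r = yc - X.values @ b
            grp = np.sqrt(2) * np.linalg.norm(b[:2]) + np.linalg.norm(b[2:])
            return (
                (r @ r) / (2 * n)
                + (1 - alpha) * lam * grp
                + alpha * lam * np.abs(b).sum()
            )

        best = brute_minimum(obj, J, rng)
        assert obj(fit.beta[:, 0]) <= best + 1e-4

    def test_alpha_one_is_lasso(self, small_xy):
        X, Y, _ = small_xy
        n = X.n_samples
        lam = 0.05
        groups = FeatureGroups({f: 1 + (i % 2) for i, f in enumerate(X.feature_ids)})
        sgl = fit_sgl(X, Y, groups, lam, alpha=1.0)
        lasso = fit_lasso(X, Y, 2 * n * lam)
        Yc = Y.values - Y.values.mean(axis=0)
        oracle = lasso_obj_oracle(X.values, Yc, 2 * n * lam)
        ref = oracle(lasso.beta.ravel())
        assert abs(oracle(sgl.beta.ravel()) - ref) <= 1e-5 * max(1.0, abs(ref))

    def test_alpha_zero_singleton_groups_is_lasso(self, small_xy):
        X, Y, _ = small_xy
        n = X.n_samples
        lam = 0.05
        singles = FeatureGroups({f: i + 1 for i, f in enumerate(X.feature_ids)})
        sgl = fit_sgl(X, Y, singles, lam, alpha=0.0)
        lasso = fit_lasso(X, Y, 2 * n * lam)
        Yc = Y.values - Y.values.mean(axis=0)
        oracle = lasso_obj_oracle(X.values, Yc, 2 * n * lam)
        ref = oracle(lasso.beta.ravel())
        assert abs(oracle(sgl.beta.ravel()) - ref) <= 1e-5 * max(1.0, abs(ref))

    def test_unknown_feature_in_groups_rejected(self, small_xy):
        X, Y, _ = small_xy
        bad = FeatureGroups({**{f: 1 for f in X.feature_ids}, "ghost": 2})
        with pytest.raises(ValueError, match="ghost"):
            fit_sgl(X, Y, bad, 0.1, 0.5)


class TestSIOL:
    def _toy(self, rng):
        n = 10
        X = standardize(make_feature_matrix(rng.standard_normal((n, 2))))
        Yv = np.column_stack(
            [
                X.values[:, 0] + 0.2 * rng.standard_normal(n),
                -0.5 * X.values[:, 1] + 0.2 * rng.standard_normal(n),
            ]
        )
        Y = make_trait_matrix(Yv)
        G = FeatureGroups({"f0": 1, "f1": 1})
        H = TraitGroups({"t0": 1, "t1": 1})
        return X, Y, G, H

    def test_objective_matches_bruteforce(self, rng):
        X, Y, G, H = self._toy(rng)
        l1, l2, l3 = 0.5, 0.8, 0.6
        fit = fit_siol(X, Y, G, H, l1, l2, l3)
        Yc = Y.values - Y.values.mean(axis=0)

        def obj(b):
            B = b.reshape(2, 2)
            R = Yc - X.values @ B
            col = sum(np.linalg.norm(B[:, k]) for k in range(2))
            row = sum(np.linalg.norm(B[j, :]) for j in range(2))
            return 0.5 * np.sum(R * R) + l1 * np.abs(B).sum() + l2 * col + l3 * row

        best = brute_minimum(obj, 4, rng)
        assert obj(fit.beta.ravel()) <= best + 1e-4

    def test_structured_penalties_vanish_to_lasso(self, rng):
        X, Y, G, H = self._toy(rng)
        l1 = 0.4
        siol = fit_siol(X, Y, G, H, l1, 0.0, 0.0)
        lasso = fit_lasso(X, Y, 2 * l1)
        Yc = Y.values - Y.values.mean(axis=0)
        oracle = lasso_obj_oracle(X.values, Yc, 2 * l1)
        ref = oracle(lasso.beta.ravel())
        assert abs(oracle(siol.beta.ravel()) - ref) <= 1e-5 * max(1.0, abs(ref))

    def test_singleton_groups_sum_penalties(self, rng):
        X, Y, _, _ = self._toy(rng)
        G = FeatureGroups({"f0": 1, "f1": 2})
        H = TraitGroups({"t0": 1, "t1": 2})
        l1, l2, l3 = 0.5, 0.8, 0.6
        siol = fit_siol(X, Y, G, H, l1, l2, l3)
        lasso = fit_lasso(X, Y, 2 * (l1 + l2 + l3))
        Yc = Y.values - Y.values.mean(axis=0)
        oracle = lasso_obj_oracle(X.values, Yc, 2 * (l1 + l2 + l3))
        ref = oracle(lasso.beta.ravel())
        assert abs(oracle(siol.beta.ravel()) - ref) <= 1e-5 * max(1.0, abs(ref))

    def test_objective_monotone(self, rng):
        X, Y, G, H = self._toy(rng)
        fit = fit_siol(X, Y, G, H, 0.2, 0.3, 0.1)
        traj = np.array(fit.diagnostics.objective)
        assert np.all(np.diff(traj) <= 1e-9)


class TestModelSelection:
    def test_pure_noise_selects_near_lambda_max(self, rng):
        X = standardize(make_feature_matrix(rng.standard_normal((30, 8))))
        Y = make_trait_matrix(rng.standard_normal((30, 2)))
        pc = select_lambda_cv("lasso", X, Y, folds=3, seed=0, n_lambda=8)
        grid = np.sort(pc.cv_table["lam"].to_numpy())
        # with no signal the heavy end of the grid is competitive
        assert pc.lam >= grid[len(grid) // 2]

    def test_strong_signal_keeps_the_feature(self, rng):
        # orthonormal design: the signal feature survives iff lam < 2n|ols|
        n, J = 24, 4
        Q, _ = np.linalg.qr(rng.standard_normal((n, J)))
        Xv = Q * np.sqrt(n)
        X = make_feature_matrix(Xv)
        y = 2.0 * Xv[:, 1] + 0.01 * rng.standard_normal(n)
        Y = make_trait_matrix(y[:, None])
        pc = select_lambda_cv("lasso", X, Y, folds=3, seed=0, n_lambda=10)
        fit = fit_lasso(X, Y, pc.lam)
        assert fit.beta[1, 0] != 0.0

    def test_cv_table_shape_and_finite(self, rng, small_xy):
        X, Y, _ = small_xy
        pc = select_lambda_cv("lasso", X, Y, folds=3, seed=1, n_lambda=7)
        assert len(pc.cv_table) == 7
        assert np.all(np.isfinite(pc.cv_table["mse"]))

    def test_fewer_samples_than_folds_rejected(self, rng):
        X = standardize(make_feature_matrix(rng.standard_normal((3, 2))))
        Y = make_trait_matrix(rng.standard_normal((3, 1)))
        with pytest.raises(ValueError):
            select_lambda_cv("lasso", X, Y, folds=4)


class TestEvaluateMSE:
    def test_perfect_and_null_fit(self, small_xy):
        X, Y, _ = small_xy
        fit = fit_lasso(X, Y, 0.0, tol=1e-12)
        _, mse = evaluate_mse(fit, X, Y)
        assert mse < 0.05  # near the noise floor on training data
        null = fit_lasso(X, Y, 1e9)
        Ys = make_trait_matrix(
            (Y.values - Y.values.mean(0)) / Y.values.std(0, ddof=1)
        )
        nullfit = fit_lasso(X, Ys, 1e9)
        per_trait, mse0 = evaluate_mse(nullfit, X, Ys)
        assert mse0 == pytest.approx(1.0, rel=0.05)

    def test_hand_computed_toy(self):
        from irnet.solvers import CoefficientMatrix

        X = make_feature_matrix([[1.0], [2.0], [3.0]])
        Y = make_trait_matrix([[1.0], [0.0], [2.0]])
        B = CoefficientMatrix(np.array([[0.5]]), np.array([0.0]), ["f0"], ["t0"])
        per_trait, mean = evaluate_mse(B, X, Y)
        # residuals: 1-0.5, 0-1.0, 2-1.5 -> (0.25+1+0.25)/3
        assert mean == pytest.approx(0.5)

    def test_dimension_mismatch_rejected(self, small_xy, rng):
        X, Y, _ = small_xy
        fit = fit_lasso(X, Y, 1.0)
        other = make_feature_matrix(rng.standard_normal((4, 2)), prefix="z")
        with pytest.raises(ValueError):
            evaluate_mse(fit, other, Y)
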