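"""Standardization, CCA and DCCA solvers, and their structural identities.

Brute-force oracles: for 2-D loadings the constrained objectives are
parametrized by a single angle per side, so an exhaustive 3600 x 3600 angle
grid (with constraint renormalization) bounds the true optimum to ~1e-6.
"""

import numpy as np
import pytest
from scipy import linalg

from emgstyle.canonical import (
    FeatureMatrix,
    ProjectionPair,
    build_class_matrices,
    canonical_variates,
    fit_cca,
    fit_dcca,
    project,
    standardize_columns,
)
from emgstyle.errors import (
    ConfigurationError,
    DegenerateColumnError,
    DegenerateDesignError,
    LabelMismatchError,
)
from conftest import random_standardized_pair


def grid_max_cca(X, Y, n_grid=3600):
    """Exhaustive angle-grid maximum of corr(Xa, Yb) for p = q = 2."""
    th = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    D = np.stack([np.cos(th), np.sin(th)])  # 2 x n directions
    U = X @ D
    V = Y @ D
    Uc = U - U.mean(axis=0)
    Vc = V - V.mean(axis=0)
    Un = Uc / np.linalg.norm(Uc, axis=0)
    Vn = Vc / np.linalg.norm(Vc, axis=0)
    return float(np.max(np.abs(Un.T @ Vn)))


def grid_max_dcca(Cw, S11, S22, n_grid=3600):
    """Exhaustive angle-grid maximum of a'Cw b under unit-scatter constraints."""
    th = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    D = np.stack([np.cos(th), np.sin(th)])
    A = D / np.sqrt(np.einsum("in,ij,jn->n", D, S11, D))
    B = D / np.sqrt(np.einsum("in,ij,jn->n", D, S22, D))
    return float(np.max(np.abs(A.T @ Cw @ B)))


class TestStandardize:
    def test_symmetric_three_point_column(self):
        fm = FeatureMatrix(np.array([[1.0], [2.0], [3.0]]), [1, 1, 2])
        out, _ = standardize_columns(fm)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])

    def test_fixed_point(self, rng):
        fm = FeatureMatrix(rng.standard_normal((30, 4)), np.ones(30, dtype=int))
        once, _ = standardize_columns(fm)
        twice, _ = standardize_columns(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_constant_column_raises_with_name(self, rng):
        vals = rng.standard_normal((10, 3))
        vals[:, 1] = 5.0
        fm = FeatureMatrix(vals, np.ones(10, dtype=int), column_names=["a", "b", "c"])
        with pytest.raises(DegenerateColumnError, match="b"):
            standardize_columns(fm)

    def test_total_cross_product_vanishes(self):
        # after column standardization (1'X)'(1'Y) is the zero matrix
        X, Y = random_standardized_pair(24, 6, 4, 3, seed=5)
        prod = np.outer(X.values.sum(axis=0), Y.values.sum(axis=0))
        assert np.max(np.abs(prod)) < 1e-8


class TestClassMatrices:
    def direct_cw(self, X, Y):
        # oracle: the literal double sum over same-class sample pairs
        p, q = X.n_features, Y.n_features
        Cw = np.zeros((p, q))
        for k in X.classes:
            xi = X.values[X.labels == k]
            yj = Y.values[Y.labels == k]
            for a in xi:
                for b in yj:
                    Cw += np.outer(a, b)
        return Cw

    def test_indicator_layout(self):
        # c = 3, n = 2: the class-2 indicator selects rows 3 and 4
        labels = np.repeat([1, 2, 3], 2)
        e2 = (labels == 2).astype(float)
        np.testing.assert_array_equal(e2, [0, 0, 1, 1, 0, 0])

    def test_cw_matches_direct_double_sum(self):
        X, Y = random_standardized_pair(24, 5, 3, 4, seed=11)
        mats = build_class_matrices(X, Y)
        np.testing.assert_allclose(mats.Cw, self.direct_cw(X, Y), atol=1e-10)

    def test_cb_plus_cw_vanishes_for_standardized_views(self):
        X, Y = random_standardized_pair(20, 6, 4, 4, seed=3)  # c=4, n=5
        mats = build_class_matrices(X, Y)
        assert np.max(np.abs(mats.Cw + mats.Cb)) < 1e-8

    def test_single_sample_per_class_gives_cross_scatter(self):
        X, Y = random_standardized_pair(8, 4, 3, 8, seed=2)  # one row per class
        mats = build_class_matrices(X, Y)
        np.testing.assert_allclose(mats.Cw, X.values.T @ Y.values, atol=1e-10)

    def test_label_mismatch_rejected(self, rng):
        X = FeatureMatrix(rng.standard_normal((6, 2)), [1, 1, 2, 2, 3, 3])
        Y = FeatureMatrix(rng.standard_normal((6, 2)), [1, 1, 2, 2, 4, 4])
        with pytest.raises(LabelMismatchError, match="3"):
            build_class_matrices(X, Y)


class TestCCA:
    def test_identical_views_fully_correlated(self):
        X, _ = random_standardized_pair(30, 4, 4, 3, seed=1)
        P = fit_cca(X, X, ridge=0.0)
        np.testing.assert_allclose(np.sqrt(P.eigenvalues), 1.0, atol=1e-8)

    def test_rotation_of_view_preserves_full_correlation(self, rng):
        X, _ = random_standardized_pair(30, 4, 4, 3, seed=4)
        Q = linalg.qr(rng.standard_normal((4, 4)))[0]
        Y, _ = standardize_columns(
            FeatureMatrix(X.values @ Q, X.labels)
        )
        P = fit_cca(X, Y, ridge=0.0)
        np.testing.assert_allclose(np.sqrt(P.eigenvalues), 1.0, atol=1e-8)

    def test_invariance_under_invertible_transform(self, rng):
        X, Y = random_standardized_pair(60, 4, 3, 3, seed=9)
        T = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        Y2 = FeatureMatrix(Y.values @ T, Y.labels)
        P1 = fit_cca(X, Y, ridge=0.0)
        P2 = fit_cca(X, Y2, ridge=0.0)
        np.testing.assert_allclose(P1.eigenvalues, P2.eigenvalues, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_first_correlation_matches_angle_grid(self, seed):
        rng = np.random.default_rng(seed)
        X = FeatureMatrix(rng.standard_normal((12, 2)), np.repeat([1, 2], 6))
        Y = FeatureMatrix(rng.standard_normal((12, 2)), np.repeat([1, 2], 6))
        Xs, _ = standardize_columns(X)
        Ys, _ = standardize_columns(Y)
        P = fit_cca(Xs, Ys, ridge=0.0)
        rho = float(np.sqrt(P.eigenvalues[0]))
        assert rho == pytest.approx(grid_max_cca(Xs.values, Ys.values), abs=1e-3)

    def test_agrees_with_iterative_reference_implementation(self):
        # independent oracle: scikit-learn's NIPALS-style CCA
        from sklearn.cross_decomposition import CCA as SkCCA

        X, Y = random_standardized_pair(60, 4, 3, 3, seed=13)
        P = fit_cca(X, Y, ridge=0.0)
        U, V = SkCCA(n_components=1).fit_transform(X.values, Y.values)
        rho_ref = abs(float(np.corrcoef(U[:, 0], V[:, 0])[0, 1]))
        assert float(np.sqrt(P.eigenvalues[0])) == pytest.approx(rho_ref, abs=1e-6)

    def test_singular_scatter_requires_ridge(self, rng):
        vals = rng.standard_normal((20, 3))
        vals = np.hstack([vals, vals[:, :1]])  # duplicated column
        X = FeatureMatrix(vals, np.repeat([1, 2], 10))
        Y = FeatureMatrix(rng.standard_normal((20, 3)), X.labels)
        Xs, _ = standardize_columns(X)
        Ys, _ = standardize_columns(Y)
        with pytest.raises(Exception, match="ridge"):
            fit_cca(Xs, Ys, ridge=0.0)
        fit_cca(Xs, Ys, ridge=1e-6)  # regularized fit succeeds

    def test_unequal_rows_rejected(self):
        X, _ = random_standardized_pair(30, 3, 3, 3, seed=1)
        Y, _ = random_standardized_pair(24, 3, 3, 3, seed=2)
        with pytest.raises(ConfigurationError):
            fit_cca(X, Y)


class TestDCCA:
    def test_symmetric_problem_gives_equal_loadings(self):
        X, _ = random_standardized_pair(24, 4, 4, 3, seed=6)
        P = fit_dcca(X, X)
        np.testing.assert_allclose(np.abs(P.A), np.abs(P.B), atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_first_objective_matches_angle_grid(self, seed):
        X, Y = random_standardized_pair(6, 2, 2, 2, seed=seed)  # c=2, n=3
        P = fit_dcca(X, Y, ridge=0.0)
        mats = build_class_matrices(X, Y)
        obj = abs(float(P.A[:, 0] @ mats.Cw @ P.B[:, 0]))
        assert obj == pytest.approx(
            grid_max_dcca(mats.Cw, P.S11, P.S22), abs=1e-3
        )

    def test_class_consistent_transform_aligns_class_means(self, rng):
        # Y is an invertible linear image of the same class structure
        labels = np.repeat(np.arange(1, 5), 8)
        means = rng.standard_normal((4, 6)) * 4
        X = FeatureMatrix(means[labels - 1] + rng.standard_normal((32, 6)), labels)
        T = rng.standard_normal((6, 6)) + 3 * np.eye(6)
        Y = FeatureMatrix(X.values @ T, labels)
        Xs, _ = standardize_columns(X)
        Ys, _ = standardize_columns(Y)
        P = fit_dcca(Xs, Ys)
        cv = canonical_variates(Xs, Ys, P, l=1)
        mu = np.array([cv.U[labels == k, 0].mean() for k in range(1, 5)])
        mv = np.array([cv.V[labels == k, 0].mean() for k in range(1, 5)])
        assert abs(np.corrcoef(mu, mv)[0, 1]) > 0.999

    def test_single_class_design_degenerates(self, rng):
        X = FeatureMatrix(rng.standard_normal((10, 3)), np.ones(10, dtype=int))
        Xs, _ = standardize_columns(X)
        with pytest.raises(DegenerateDesignError):
            fit_dcca(Xs, Xs)

    @pytest.mark.parametrize("seed", range(20))
    def test_whitened_solver_matches_unsymmetric_eigenproblem(self, seed):
        # the unsymmetric product C11^-1 Cw C22^-1 Cw' can leak complex parts;
        # the whitened solver must reproduce its spectrum exactly
        rng = np.random.default_rng(seed)
        p, q, c = rng.integers(2, 7), rng.integers(2, 7), rng.integers(2, 5)
        X, Y = random_standardized_pair(8 * c, p, q, c, seed=seed + 100)
        P = fit_dcca(X, Y, ridge=0.0)
        mats = build_class_matrices(X, Y)
        prod = (
            linalg.inv(mats.C11) @ mats.Cw @ linalg.inv(mats.C22) @ mats.Cw.T
        )
        w = linalg.eigvals(prod)
        assert np.max(np.abs(w.imag)) < 1e-10
        w = np.sort(w.real)[::-1]
        np.testing.assert_allclose(P.eigenvalues, w[: P.r], atol=1e-8)

    def test_eigen_equation_residuals(self):
        X, Y = random_standardized_pair(40, 5, 4, 4, seed=21)
        P = fit_dcca(X, Y)
        mats = build_class_matrices(X, Y)
        lhs = linalg.inv(P.S11) @ mats.Cw @ linalg.inv(P.S22) @ mats.Cw.T @ P.A
        rhs = P.A * P.eigenvalues
        assert np.max(np.abs(lhs - rhs)) < 1e-6

    def test_constraint_residuals_and_ordering(self):
        X, Y = random_standardized_pair(40, 5, 4, 4, seed=22)
        P = fit_dcca(X, Y)
        ra, rb = P.constraint_residuals()
        assert np.max(ra) < 1e-6 and np.max(rb) < 1e-6
        assert P.r < min(5, 4)
        assert np.all(np.diff(P.eigenvalues) <= 1e-12)
        assert np.all(P.eigenvalues >= 0)

    def test_unequal_row_counts_supported(self):
        X, _ = random_standardized_pair(40, 5, 5, 4, seed=23)
        Y, _ = random_standardized_pair(16, 4, 4, 4, seed=24)
        P = fit_dcca(X, Y)
        assert P.A.shape == (5, P.r) and P.B.shape == (4, P.r)

    def test_one_sample_per_class_reduces_to_cca_subspace(self):
        # with one row per class Cw = X'Y, so DCCA and CCA span the same space
        X, Y = random_standardized_pair(10, 4, 3, 10, seed=30)
        Pd = fit_dcca(X, Y, ridge=0.0)
        Pc = fit_cca(X, Y, ridge=0.0)
        angles = linalg.subspace_angles(Pd.A, Pc.A)
        assert np.max(angles) < 1e-6


class TestProjection:
    def fit_small(self):
        X, Y = random_standardized_pair(40, 5, 4, 4, seed=31)
        return X, Y, fit_dcca(X, Y)

    def test_full_prefix_shape(self):
        X, _, P = self.fit_small()
        U = project(X, P, "first", P.r)
        assert U.shape == (40, P.r)

    def test_single_column_is_first_loading(self):
        X, _, P = self.fit_small()
        U1 = project(X, P, "first", 1)
        np.testing.assert_allclose(U1[:, 0], X.values @ P.A[:, 0])

    def test_prefix_consistency(self):
        X, _, P = self.fit_small()
        np.testing.assert_array_equal(
            project(X, P, "first", 3), project(X, P, "first", P.r)[:, :3]
        )

    def test_out_of_range_prefix_rejected(self):
        X, _, P = self.fit_small()
        with pytest.raises(ConfigurationError):
            project(X, P, "first", P.r + 1)
        with pytest.raises(ConfigurationError):
            project(X, P, "first", 0)

    def test_second_side_uses_b_loadings(self):
        X, Y, P = self.fit_small()
        V = project(Y, P, "second", 2)
        np.testing.assert_allclose(V, Y.values @ P.B[:, :2])

    def test_projection_pair_npz_round_trip(self, tmp_path):
        _, _, P = self.fit_small()
        path = tmp_path / "pair.npz"
        P.save(path)
        back = ProjectionPair.load(path)
        np.testing.assert_array_equal(back.A, P.A)
        np.testing.assert_array_equal(back.B, P.B)
        np.testing.assert_array_equal(back.eigenvalues, P.eigenvalues)
        assert back.r == P.r and back.method == P.method
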