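"""Unit tests for the two-class LDR core: class statistics, scatter
matrices, the three separability criteria and their optimizers."""

import numpy as np
import pytest
import scipy.linalg

from hairpinldr.ldr import (
    CDAOptions,
    ClassGaussian,
    ScatterPair,
    criterion_value,
    estimate_class_gaussians,
    fit_cda,
    fit_fda,
    fit_hda,
    matrix_function,
    regularize_covariance,
    scatter_matrices,
)

from conftest import rand_spd, random_gaussian_pair


class TestEstimateClassGaussians:
    def test_two_point_means_and_priors(self):
        X = np.array([[0.0, 0], [2, 0], [10, 0], [12, 0]])
        y = np.array([1, 1, 0, 0])
        pos, neg = estimate_class_gaussians(X, y)
        assert np.allclose(pos.mean, [1, 0])
        assert np.allclose(neg.mean, [11, 0])
        assert pos.prior == neg.prior == 0.5

    def test_imbalanced_empirical_priors(self):
        # 691 positives vs 9,248 negatives: the benchmark's ~1:13 ratio
        rng = np.random.default_rng(0)
        y = np.concatenate([np.ones(691, int), np.zeros(9248, int)])
        X = rng.standard_normal((y.size, 2))
        pos, neg = estimate_class_gaussians(X, y)
        assert pos.prior == pytest.approx(691 / 9939, abs=1e-12)
        assert neg.prior == pytest.approx(9248 / 9939, abs=1e-12)
        assert pos.prior == pytest.approx(0.0695, abs=5e-4)

    def test_covariance_matches_double_loop_oracle(self, rng):
        X = rng.standard_normal((200, 4)) @ rand_spd(rng, 4)
        y = (rng.uniform(size=200) < 0.4).astype(int)
        pos, neg = estimate_class_gaussians(X, y)
        for gauss, lab in ((pos, 1), (neg, 0)):
            Xc = X[y == lab]
            m = Xc.mean(axis=0)
            S = np.zeros((4, 4))
            for row in Xc:  # brute-force sum of outer products / N
                S += np.outer(row - m, row - m)
            S /= Xc.shape[0]
            assert np.max(np.abs(gauss.covariance - S)) < 1e-10

    def test_equal_prior_mode(self, rng):
        X = rng.standard_normal((50, 2))
        y = np.array([1] * 10 + [0] * 40)
        pos, neg = estimate_class_gaussians(X, y, prior_mode="equal")
        assert pos.prior == neg.prior == 0.5

    def test_degenerate_class_rejected(self, rng):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ValueError, match="degenerate"):
            estimate_class_gaussians(X, np.array([1, 0, 0, 0, 0]))

    def test_non_finite_rejected(self):
        X = np.array([[0.0, np.nan], [1, 2], [3, 4], [5, 6]])
        with pytest.raises(ValueError, match="finite"):
            estimate_class_gaussians(X, np.array([1, 1, 0, 0]))


class TestScatterMatrices:
    def test_identity_average(self):
        c1 = ClassGaussian(np.zeros(2), np.eye(2), 0.5)
        c2 = ClassGaussian(np.ones(2), np.eye(2), 0.5)
        sc = scatter_matrices(c1, c2)
        assert np.allclose(sc.within, np.eye(2))

    def test_between_is_outer_product(self):
        c1 = ClassGaussian(np.array([0.0, 0]), np.eye(2), 0.5)
        c2 = ClassGaussian(np.array([2.0, 0]), np.eye(2), 0.5)
        sc = scatter_matrices(c1, c2)
        assert np.allclose(sc.between, [[4, 0], [0, 0]])

    def test_between_has_rank_one(self, rng):
        c1, c2 = random_gaussian_pair(rng, 5)
        w = np.sort(np.abs(np.linalg.eigvalsh(scatter_matrices(c1, c2).between)))
        assert w[-2] < 1e-10 * w[-1]

    def test_dimension_mismatch(self, rng):
        c1 = ClassGaussian(np.zeros(2), np.eye(2), 0.5)
        c2 = ClassGaussian(np.zeros(3), np.eye(3), 0.5)
        with pytest.raises(ValueError):
            scatter_matrices(c1, c2)


def _criterion_oracle(A, c1, c2, criterion):
    """Term-by-term re-implementation with scipy matrix functions,
    independent of the package's spectral helper."""
    A = np.atleast_2d(A)
    S1 = regularize_covariance(c1.covariance)
    S2 = regularize_covariance(c2.covariance)
    p1, p2 = c1.prior, c2.prior
    SW = p1 * S1 + p2 * S2
    d = c1.mean - c2.mean
    SE = np.outer(d, d)
    AWA = A @ SW @ A.T
    if criterion == "fda":
        return np.trace(np.linalg.inv(AWA) @ A @ SE @ A.T)
    if criterion == "hda":
        Wh = scipy.linalg.sqrtm(SW).real
        Wmh = np.linalg.inv(Wh)
        term = (
            p1 * scipy.linalg.logm(Wmh @ S1 @ Wmh)
            + p2 * scipy.linalg.logm(Wmh @ S2 @ Wmh)
        ).real / (p1 * p2)
        M = SE - Wh @ term @ Wh
        return np.trace(np.linalg.inv(AWA) @ A @ M @ A.T)
    # Chernoff
    val = p1 * p2 * np.trace(np.linalg.inv(AWA) @ A @ SE @ A.T)
    val += np.log(np.linalg.det(AWA))
    val -= p1 * np.log(np.linalg.det(A @ S1 @ A.T))
    val -= p2 * np.log(np.linalg.det(A @ S2 @ A.T))
    return val


class TestCriterionValue:
    def test_fda_scalar_example(self):
        c1 = ClassGaussian(np.array([2.0, 0]), np.eye(2), 0.5)
        c2 = ClassGaussian(np.array([0.0, 0]), np.eye(2), 0.5)
        # S_W = I, S_E = [[4,0],[0,0]], A = [1,0] -> J = 4
        J = criterion_value(np.array([[1.0, 0.0]]), c1, c2, "fda", reg=0.0)
        assert J == pytest.approx(4.0, abs=1e-10)

    def test_hda_collapses_to_fda_when_homoscedastic(self, rng):
        c1, c2 = random_gaussian_pair(rng, 4, homoscedastic=True)
        for _ in range(5):
            A = rng.standard_normal((2, 4))
            jf = criterion_value(A, c1, c2, "fda")
            jh = criterion_value(A, c1, c2, "hda")
            assert jh == pytest.approx(jf, abs=1e-8)

    @pytest.mark.parametrize("criterion", ["fda", "hda", "cda"])
    def test_matches_independent_oracle(self, rng, criterion):
        for _ in range(10):
            c1, c2 = random_gaussian_pair(rng, 3)
            A = rng.standard_normal((2, 3))
            got = criterion_value(A, c1, c2, criterion)
            want = _criterion_oracle(A, c1, c2, criterion)
            assert got == pytest.approx(want, abs=1e-8)

    def test_singular_projected_within_raises(self):
        c1 = ClassGaussian(np.zeros(2), np.eye(2), 0.5)
        c2 = ClassGaussian(np.ones(2), np.eye(2), 0.5)
        A = np.array([[1.0, 0.0], [1.0, 0.0]])  # rank-deficient projection
        with pytest.raises(np.linalg.LinAlgError, match="within"):
            criterion_value(A, c1, c2, "fda")

    def test_unknown_criterion(self):
        c1 = ClassGaussian(np.zeros(2), np.eye(2), 0.5)
        c2 = ClassGaussian(np.ones(2), np.eye(2), 0.5)
        with pytest.raises(ValueError):
            criterion_value(np.eye(2), c1, c2, "lda")


class TestFitFDA:
    def test_axis_aligned(self):
        sc = ScatterPair(within=np.eye(2), between=np.array([[4.0, 0], [0, 0]]))
        proj = fit_fda(sc, 1, reg=0.0)
        assert np.allclose(np.abs(proj.matrix), [[1, 0]], atol=1e-12)
        assert proj.objective_value == pytest.approx(4.0, abs=1e-10)

    def test_direction_proportional_to_whitened_mean_difference(self):
        # classic closed form: leading direction ~ S_W^{-1} (m1 - m2)
        SW = np.diag([1.0, 4.0])
        diff = np.array([0.0, 2.0])
        sc = ScatterPair(within=SW, between=np.outer(diff, diff))
        a = fit_fda(sc, 1, reg=0.0).matrix[0]
        want = np.linalg.inv(SW) @ diff
        cos = abs(a @ want) / np.linalg.norm(a) / np.linalg.norm(want)
        assert cos > 1 - 1e-10

    def test_row_transformation_invariance(self, rng):
        c1, c2 = random_gaussian_pair(rng, 5)
        sc = scatter_matrices(c1, c2)
        A = fit_fda(sc, 2).matrix
        J = criterion_value(A, c1, c2, "fda")
        for _ in range(5):
            T = rng.standard_normal((2, 2))
            if abs(np.linalg.det(T)) < 1e-3:
                continue
            assert criterion_value(T @ A, c1, c2, "fda") == pytest.approx(J, abs=1e-8)

    def test_d_out_of_range(self, rng):
        c1, c2 = random_gaussian_pair(rng, 3)
        with pytest.raises(ValueError):
            fit_fda(scatter_matrices(c1, c2), 4)


class TestFitHDA:
    def test_homoscedastic_equals_fda(self, rng):
        for _ in range(5):
            c1, c2 = random_gaussian_pair(rng, 4, homoscedastic=True)
            a_f = fit_fda(scatter_matrices(c1, c2), 1).matrix[0]
            a_h = fit_hda(c1, c2, 1).matrix[0]
            cos = abs(a_f @ a_h) / np.linalg.norm(a_f) / np.linalg.norm(a_h)
            assert cos > 1 - 1e-8

    def test_variance_only_signal(self):
        # equal means; all discriminative information is in axis-1 variance
        c1 = ClassGaussian(np.zeros(2), np.diag([1.0, 1.0]), 0.5)
        c2 = ClassGaussian(np.zeros(2), np.diag([9.0, 1.0]), 0.5)
        a = fit_hda(c1, c2, 1).matrix[0]
        a = a / np.linalg.norm(a)
        assert abs(abs(a[0]) - 1.0) < 1e-8

        # cross-check with a 1-D Bhattacharyya scan over directions
        thetas = np.linspace(0, np.pi, 3601)
        best = None
        for th in thetas:
            u = np.array([np.cos(th), np.sin(th)])
            v1 = u @ c1.covariance @ u
            v2 = u @ c2.covariance @ u
            bhatt = 0.5 * np.log((v1 + v2) / (2 * np.sqrt(v1 * v2)))
            if best is None or bhatt > best[0]:
                best = (bhatt, u)
        assert abs(abs(best[1][0]) - 1.0) < 1e-3

    def test_hda_at_least_fda_on_its_criterion(self, rng):
        for _ in range(10):
            c1, c2 = random_gaussian_pair(rng, 4, cov_scale2=3.0)
            a_h = fit_hda(c1, c2, 1)
            a_f = fit_fda(scatter_matrices(c1, c2), 1)
            j_h = criterion_value(a_h.matrix, c1, c2, "hda")
            j_f = criterion_value(a_f.matrix, c1, c2, "hda")
            assert j_h >= j_f - 1e-10


class TestFitCDA:
    def test_ascent_from_fda_init(self, rng):
        c1, c2 = random_gaussian_pair(rng, 3, homoscedastic=True)
        a_f = fit_fda(scatter_matrices(c1, c2), 1)
        proj = fit_cda(c1, c2, 1)
        assert proj.objective_value >= criterion_value(
            a_f.matrix, c1, c2, "cda"
        ) - 1e-10

    def test_objective_trace_non_decreasing(self, rng):
        c1, c2 = random_gaussian_pair(rng, 3, cov_scale2=4.0)
        proj = fit_cda(c1, c2, 1)
        assert np.all(np.diff(proj.objective_trace) >= 0)

    def test_homoscedastic_direction_matches_fda(self, rng):
        for _ in range(3):
            c1, c2 = random_gaussian_pair(rng, 2, homoscedastic=True)
            a_f = fit_fda(scatter_matrices(c1, c2), 1).matrix[0]
            a_c = fit_cda(c1, c2, 1).matrix[0]
            cos = abs(a_f @ a_c) / np.linalg.norm(a_f) / np.linalg.norm(a_c)
            assert cos > 0.999

    def test_beats_random_direction_search(self, rng):
        for _ in range(5):
            c1, c2 = random_gaussian_pair(rng, 3, mean_scale=2.0, cov_scale2=3.0)
            proj = fit_cda(c1, c2, 1)
            U = rng.standard_normal((10_000, 3))
            U /= np.linalg.norm(U, axis=1, keepdims=True)
            S1 = regularize_covariance(c1.covariance)
            S2 = regularize_covariance(c2.covariance)
            SW = c1.prior * S1 + c2.prior * S2
            diff = c1.mean - c2.mean
            se = (U @ diff) ** 2
            sw = np.einsum("ki,ij,kj->k", U, SW, U)
            s1 = np.einsum("ki,ij,kj->k", U, S1, U)
            s2 = np.einsum("ki,ij,kj->k", U, S2, U)
            J = (
                c1.prior * c2.prior * se / sw
                + np.log(sw)
                - c1.prior * np.log(s1)
                - c2.prior * np.log(s2)
            )
            assert proj.objective_value >= J.max() - 1e-6

    def test_options_validation(self):
        with pytest.raises(ValueError):
            CDAOptions(max_iterations=0)
        with pytest.raises(ValueError):
            CDAOptions(tolerance=0.0)


class TestMatrixFunction:
    def test_log_identity_is_zero(self):
        assert np.allclose(matrix_function(np.eye(3), "log"), 0.0)

    def test_sqrt_diagonal(self):
        out = matrix_function(np.diag([4.0, 9.0]), "sqrt")
        assert np.allclose(out, np.diag([2.0, 3.0]))

    def test_round_trips(self, rng):
        M = rand_spd(rng, 5)
        R = matrix_function(M, "sqrt")
        assert np.max(np.abs(R @ R - M)) < 1e-8
        L = matrix_function(M, "log")
        w, V = np.linalg.eigh(L)
        back = (V * np.exp(w)) @ V.T
        assert np.max(np.abs(back - M)) < 1e-8
        Ih = matrix_function(M, "inv_sqrt") @ matrix_function(M, "sqrt")
        assert np.max(np.abs(Ih - np.eye(5))) < 1e-8

    def test_asymmetric_rejected(self):
        M = np.array([[1.0, 2.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            matrix_function(M, "sqrt")

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            matrix_function(np.eye(2), "exp")
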