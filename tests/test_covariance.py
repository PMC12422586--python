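"""Covariance factor construction: spectrum, PCA match, spiked Wishart,
James-Stein shrinkage."""

import numpy as np
import pytest
from scipy import stats

from depsim import (
    SGDConfig,
    fit_corpcor,
    fit_independent,
    fit_pca,
    fit_spiked_wishart,
    reference_spectrum,
    sample_spiked_eigenvalues,
)
from depsim.covariance import shrinkage_intensities
from depsim.marginals import NormalizedMatrix

from conftest import random_centered_Z


def dense_shrunk_covariance(M, lam1, lam2):
    """Direct James-Stein shrinkage oracle on a centered p x n matrix."""
    n = M.shape[1]
    v = (M**2).sum(axis=1) / (n - 1)
    R = np.corrcoef(M)
    v_star = lam2 * np.median(v) + (1 - lam2) * v
    S = (1 - lam1) * R * np.sqrt(np.outer(v_star, v_star))
    np.fill_diagonal(S, v_star)
    return S


class TestReferenceSpectrum:
    def test_single_nonzero_row_norm(self):
        M = np.zeros((5, 4))
        M[2] = [1.0, -1.0, 2.0, -2.0]  # already centered
        spec = reference_spectrum(NormalizedMatrix(Z=M))
        assert abs(spec.singular_values[0] - np.sqrt(10.0)) < 1e-12
        assert np.all(spec.singular_values[1:] < 1e-12)

    def test_matches_dense_svd_oracle(self):
        Z = random_centered_Z(50, 6, seed=9)
        spec = reference_spectrum(Z)
        s_dense = np.linalg.svd(Z.Z, compute_uv=False)
        np.testing.assert_allclose(spec.singular_values, s_dense[:5], atol=1e-10)
        np.testing.assert_allclose(
            spec.eigenvalues, s_dense[:5] ** 2 / 5, atol=1e-10
        )

    def test_centering_forces_null_direction(self):
        Z = random_centered_Z(30, 8, seed=2)
        s = np.linalg.svd(Z.Z, compute_uv=False)
        assert s[-1] <= 1e-8 * s[0]

    def test_left_vectors_orthonormal_and_sign_fixed(self):
        Z = random_centered_Z(40, 7, seed=3)
        spec = reference_spectrum(Z)
        U = spec.left_singular_vectors
        np.testing.assert_allclose(U.T @ U, np.eye(6), atol=1e-10)
        for col in U.T:
            assert col[np.argmax(np.abs(col))] > 0


class TestIndependent:
    def test_d_equals_rowwise_sd_hand_case(self):
        M = np.array([[1.0, -1.0], [2.0, -2.0], [0.5, -0.5]])
        f = fit_independent(NormalizedMatrix(Z=M))
        # ddof=1 variances of (+-a) rows are 2 a^2
        np.testing.assert_allclose(f.D, np.sqrt([2.0, 8.0, 0.5]), atol=1e-12)
        assert f.k == 0
        np.testing.assert_allclose(f.diagonal(), f.D**2)

    def test_generated_latents_are_uncorrelated(self):
        from depsim import generate_normal_scores

        Z = random_centered_Z(6, 10, seed=1)
        f = fit_independent(Z)
        X = generate_normal_scores(f, 50_000, seed=0)
        C = np.corrcoef(X)
        off = C[np.triu_indices(6, k=1)]
        assert np.abs(off).max() < 4 / np.sqrt(50_000)


class TestPCA:
    @pytest.mark.parametrize("p,n,k,seed", [(6, 5, 2, 0), (80, 12, 2, 1),
                                            (40, 12, 5, 2)])
    def test_quadratic_form_and_diagonal_match(self, p, n, k, seed):
        Z = random_centered_Z(p, n, seed)
        f = fit_pca(Z, k)
        spec = reference_spectrum(Z)
        S = f.dense()
        for i in range(k):
            u = spec.left_singular_vectors[:, i]
            assert abs(u @ S @ u - spec.eigenvalues[i]) < 1e-8
        ref_diag = (Z.Z**2).sum(axis=1) / (n - 1)
        np.testing.assert_allclose(np.diag(S), ref_diag, atol=1e-8)

    def test_hand_solvable_orthogonal_rows(self):
        # two singular directions on disjoint coordinates: A is diagonal
        M = np.zeros((4, 4))
        M[0] = [3.0, -3.0, 3.0, -3.0]
        M[1] = [2.0, 2.0, -2.0, -2.0]
        Z = NormalizedMatrix(Z=M)
        f = fit_pca(Z, 2)
        # U columns are e0, e1; A = I - I = diag(0)?? no: A_ij = delta - U2'U2
        # U_l0^2 = [1,0,0,0], so A = [[0,0],[0,0]] is singular -> the solve
        # must still satisfy the quadratic form via the dense check
        spec = reference_spectrum(Z)
        S = f.dense()
        for i in range(2):
            u = spec.left_singular_vectors[:, i]
            assert abs(u @ S @ u - spec.eigenvalues[i]) < 1e-8

    def test_k_out_of_range_raises(self):
        Z = random_centered_Z(10, 5, seed=0)
        with pytest.raises(ValueError, match="k"):
            fit_pca(Z, 4)  # k must be <= n-2 = 3

    def test_printed_scaling_flag_changes_target(self):
        Z = random_centered_Z(30, 8, seed=4)
        f1 = fit_pca(Z, 2)
        with pytest.warns(UserWarning):
            f2 = fit_pca(Z, 2, target_scaling="printed")
        assert not np.allclose(f1.W, f2.W)


class TestSpikedSampler:
    def test_pure_wishart_when_k_zero(self):
        # k = 0: eigenvalues of c^2 * Wishart(p, I_m)/m
        p, m, reps, c = 60, 4, 4000, 1.5
        eigs = sample_spiked_eigenvalues(np.empty(0), c, p, m, reps, seed=0)
        # mean of the *sum* of eigenvalues = c^2 * p (trace/m identity)
        total = eigs.sum(axis=1)
        expect = c**2 * p
        se = total.std(ddof=1) / np.sqrt(reps)
        assert abs(total.mean() - expect) < 3 * se

    def test_matches_dense_brute_force(self):
        p, k, m, reps = 100, 2, 7, 4000
        w, c = np.array([5.0, 3.0]), 1.0
        fast = sample_spiked_eigenvalues(w, c, p, m, reps, seed=1)
        rng = np.random.default_rng(2)
        sd = np.full(p, c)
        sd[:k] = np.sqrt(w**2 + c**2)
        dense = np.empty((reps, m))
        for r in range(reps):
            A = sd[:, None] * rng.standard_normal((p, m))
            dense[r] = np.linalg.eigvalsh(A.T @ A / m)[::-1]
        rel = np.abs(fast.mean(axis=0) - dense.mean(axis=0)) / dense.mean(axis=0)
        assert rel.max() < 0.02
        assert stats.ks_2samp(fast.ravel(), dense.ravel()).pvalue > 0.01

    def test_small_c_limit_is_low_rank_gram(self):
        # c -> 0, k = m: eigenvalues converge to diag(w) G G^T diag(w)/m
        k = m = 3
        w = np.array([2.0, 1.0, 0.5])
        reps = 4000
        eigs = sample_spiked_eigenvalues(w, 1e-6, 200, m, reps, seed=3)
        rng = np.random.default_rng(4)
        G = rng.standard_normal((reps, k, m))
        lim = np.linalg.eigvalsh(
            np.swapaxes(G, 1, 2) @ (w[:, None] ** 2 * G) / m
        )[:, ::-1]
        for i in range(m):
            se = np.sqrt(eigs[:, i].var() / reps + lim[:, i].var() / reps)
            assert abs(eigs[:, i].mean() - lim[:, i].mean()) < 4 * se

    def test_p_not_larger_than_k_raises(self):
        with pytest.raises(ValueError, match="p > k"):
            sample_spiked_eigenvalues(np.ones(5), 1.0, 5, 3, 10, seed=0)

    def test_deterministic_given_seed(self):
        a = sample_spiked_eigenvalues(np.array([2.0]), 1.0, 50, 4, 10, seed=9)
        b = sample_spiked_eigenvalues(np.array([2.0]), 1.0, 50, 4, 10, seed=9)
        np.testing.assert_array_equal(a, b)


class TestSpikedFit:
    def test_loss_decreases_and_deterministic(self):
        Z = random_centered_Z(300, 8, seed=6)
        cfg = SGDConfig(iterations=60, mc_reps=10, final_reps=50)
        f1, fit1 = fit_spiked_wishart(Z, 3, seed=5, sgd_config=cfg)
        f2, fit2 = fit_spiked_wishart(Z, 3, seed=5, sgd_config=cfg)
        assert fit1.loss_trace[-1] <= fit1.init_loss
        np.testing.assert_array_equal(fit1.w, fit2.w)
        assert fit1.c == fit2.c
        assert f1.method == "wishart" and f1.c == fit1.c
        np.testing.assert_allclose(f1.D, np.full(300, fit1.c))

    def test_k_range_validated(self):
        Z = random_centered_Z(50, 6, seed=0)
        with pytest.raises(ValueError):
            fit_spiked_wishart(Z, 6, seed=0)  # k must be <= n-1 = 5

    def test_null_reference_recovers_unit_noise(self):
        """On an iid-noise reference there are no real spikes: c comes
        back near 1 and the low-rank part contributes little variance."""
        rng = np.random.default_rng(314)
        M = rng.standard_normal((800, 12))
        M -= M.mean(axis=1, keepdims=True)
        f, fit = fit_spiked_wishart(NormalizedMatrix(Z=M), 11, seed=1)
        assert abs(fit.c - 1.0) < 0.05
        # spikes may absorb bulk-edge fluctuations of the single target
        # draw, but their share of each gene's variance stays small
        assert ((f.U**2) @ (f.W**2)).mean() < 0.05 * fit.c**2


class TestCorpcor:
    def test_dense_oracle_equivalence_random_instances(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = rng.integers(4, 9)
            M = rng.standard_normal((p, 5))
            M -= M.mean(axis=1, keepdims=True)
            Z = NormalizedMatrix(Z=M)
            lam1, lam2 = shrinkage_intensities(Z)
            f = fit_corpcor(Z)
            oracle = dense_shrunk_covariance(M, lam1, lam2)
            np.testing.assert_allclose(f.dense(), oracle, atol=1e-10)

    def test_interpolation_endpoints(self):
        Z = random_centered_Z(8, 5, seed=1)
        # lam1 = 1: pure diagonal with shrunk variances
        f1 = fit_corpcor(Z, lambda1=1.0, lambda2=0.4)
        off = f1.dense()
        np.fill_diagonal(off, 0.0)
        assert np.abs(off).max() < 1e-12
        # lam1 = lam2 = 0: exactly the sample covariance
        f0 = fit_corpcor(Z, lambda1=0.0, lambda2=0.0)
        np.testing.assert_allclose(f0.dense(), Z.Z @ Z.Z.T / 4, atol=1e-12)

    def test_diagonal_preserved_under_variance_shrinkage_only(self):
        Z = random_centered_Z(10, 6, seed=2)
        f = fit_corpcor(Z)
        lam1, lam2 = shrinkage_intensities(Z)
        v = (Z.Z**2).sum(axis=1) / 5
        v_star = lam2 * np.median(v) + (1 - lam2) * v
        np.testing.assert_allclose(f.diagonal(), v_star, atol=1e-10)

    def test_equal_variances_make_lambda2_one(self):
        # rows scaled to identical variance: denominator is 0 -> lam2 := 1
        rng = np.random.default_rng(3)
        M = rng.standard_normal((6, 5))
        M -= M.mean(axis=1, keepdims=True)
        M /= M.std(axis=1, ddof=1)[:, None]
        _, lam2 = shrinkage_intensities(NormalizedMatrix(Z=M))
        assert lam2 == 1.0

    def test_needs_three_samples(self):
        with pytest.raises(ValueError, match="n >= 3"):
            shrinkage_intensities(random_centered_Z(5, 2, seed=0))


class TestFactorInvariants:
    @pytest.mark.parametrize("method", ["independent", "pca", "corpcor"])
    def test_psd_by_construction(self, method):
        Z = random_centered_Z(15, 7, seed=8)
        if method == "independent":
            f = fit_independent(Z)
        elif method == "pca":
            f = fit_pca(Z, 3)
        else:
            f = fit_corpcor(Z)
        eigs = np.linalg.eigvalsh(f.dense())
        assert eigs.min() >= -1e-10

    def test_negative_factors_rejected(self):
        from depsim.covariance import CovarianceFactors

        with pytest.raises(ValueError):
            CovarianceFactors(D=np.array([-1.0]), U=np.empty((1, 0)),
                              W=np.empty(0), k=0, method="independent")
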