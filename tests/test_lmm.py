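import numpy as np
import pytest
from scipy import stats

import medlmm
from medlmm.genotype import KinshipMatrix
from medlmm.lmm import (
    association_test,
    eigendecompose_kinship,
    fit_lmm,
    identity_basis,
    profile_loglik,
)
from conftest import rng_psd_kinship


def dense_gls(y, X, V):
    """Brute-force GLS with an explicitly inverted covariance matrix."""
    Vi = np.linalg.inv(V)
    cov = np.linalg.inv(X.T @ Vi @ X)
    beta = cov @ X.T @ Vi @ y
    return beta, cov


def dense_mvn_loglik(y, X, beta, sigma_e2, lam, K):
    V = sigma_e2 * (lam * K + np.eye(K.shape[0]))
    return stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=V)


class TestEigendecompose:
    def test_identity_spectrum(self):
        b = eigendecompose_kinship(np.eye(8))
        np.testing.assert_allclose(b.eigenvalues, 1.0)

    def test_all_ones_matrix_spectrum(self):
        n = 9
        b = eigendecompose_kinship(np.ones((n, n)))
        w = np.sort(b.eigenvalues)
        np.testing.assert_allclose(w[-1], n, atol=1e-10)
        np.testing.assert_allclose(w[:-1], 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction_on_random_psd(self, seed):
        k = rng_psd_kinship(30, seed)
        b = eigendecompose_kinship(k)
        rec = b.rotation @ np.diag(b.eigenvalues) @ b.rotation.T
        assert np.abs(rec - k).max() / np.abs(k).max() < 1e-6
        assert np.abs(b.rotation.T @ b.rotation - np.eye(30)).max() < 1e-8

    def test_asymmetric_rejected(self):
        k = np.eye(4)
        k[0, 1] = 0.5
        with pytest.raises(ValueError):
            eigendecompose_kinship(k)


class TestFitLMM:
    def test_identity_kinship_matches_ols(self):
        rng = np.random.default_rng(3)
        n = 80
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1.0, 0.5] + rng.standard_normal(n)
        with pytest.warns(RuntimeWarning, match="boundary"):
            fit = fit_lmm(y, X, identity_basis(n))
        beta_ols, _ = np.linalg.lstsq(X, y, rcond=None)[:2]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)
        # total variance matches the OLS residual variance (sigma split is free)
        resid = y - X @ beta_ols
        total = fit.sigma_g2 + fit.sigma_e2
        assert total == pytest.approx(resid @ resid / (n - 2), rel=1e-3)

    def test_lambda_recovery_median_within_factor_two(self, small_panel):
        g, k = small_panel
        basis = eigendecompose_kinship(k)
        n = g.n_lines
        L = np.linalg.cholesky(k.values + 1e-10 * np.eye(n))
        lams = []
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            u = L @ rng.standard_normal(n)  # var 1 * K
            y = 1.0 + u + rng.standard_normal(n)  # lambda = 1
            fit = fit_lmm(y, np.ones((n, 1)), basis)
            lams.append(fit.lambda_)
        assert 0.5 <= np.median(lams) <= 2.0

    def test_optimum_beats_brute_force_grid(self, small_panel):
        g, k = small_panel
        basis = eigendecompose_kinship(k)
        n = g.n_lines
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [0.3, 0.2] + np.linalg.cholesky(k.values + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
        fit = fit_lmm(y, X, basis)
        grid = np.logspace(-5, 5, 21)
        ll_grid, _, _ = profile_loglik(basis.rotate(y), basis.rotate(X), basis.eigenvalues, grid)
        assert fit.loglik >= ll_grid.max() - 1e-9

    def test_agrees_with_dense_gls_oracle(self):
        n = 50
        k = rng_psd_kinship(n, 11)
        basis = eigendecompose_kinship(k)
        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [0.2, 0.4] + rng.standard_normal(n)
        fit = fit_lmm(y, X, basis)
        V = fit.sigma_e2 * (fit.lambda_ * k + np.eye(n))
        beta_d, cov_d = dense_gls(y, X, V)
        np.testing.assert_allclose(fit.beta, beta_d, atol=1e-8)
        np.testing.assert_allclose(fit.se, np.sqrt(np.diag(cov_d)), atol=1e-8)

    def test_rotated_loglik_equals_dense_mvn_density(self):
        n = 60
        k = rng_psd_kinship(n, 21)
        basis = eigendecompose_kinship(k)
        rng = np.random.default_rng(21)
        X = np.ones((n, 1))
        y = rng.standard_normal(n) + 0.5
        lam = 0.7
        ll, beta, sig = profile_loglik(
            basis.rotate(y), basis.rotate(X), basis.eigenvalues, np.array([lam]), "ML"
        )
        dense = dense_mvn_loglik(y, X, beta[0], sig[0], lam, k)
        assert abs(ll[0] - dense) < 1e-8

    def test_shift_invariance_with_intercept(self, small_panel):
        g, k = small_panel
        basis = eigendecompose_kinship(k)
        n = g.n_lines
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [0.0, 0.4] + rng.standard_normal(n)
        f1 = fit_lmm(y, X, basis)
        f2 = fit_lmm(y + 100.0, X, basis)
        assert f1.beta[1] == pytest.approx(f2.beta[1], abs=1e-8)
        assert f1.lambda_ == pytest.approx(f2.lambda_, rel=1e-6)

    def test_rank_deficient_design_rejected(self, small_panel):
        g, k = small_panel
        basis = eigendecompose_kinship(k)
        n = g.n_lines
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            fit_lmm(np.arange(n, dtype=float), X, basis)


class TestAssociationTest:
    def test_null_pvalues_uniform(self, small_panel):
        g, k = small_panel
        basis = eigendecompose_kinship(k)
        n = g.n_lines
        rng = np.random.default_rng(17)
        L = np.linalg.cholesky(k.values + 1e-10 * np.eye(n))
        y = L @ rng.standard_normal(n) + rng.standard_normal(n)
        from medlmm.lmm import fit_lmm_rotated

        null = fit_lmm_rotated(basis.rotate(y), basis.rotate(np.ones((n, 1))), basis.eigenvalues)
        snps = rng.standard_normal((n, 2000))  # independent of y: null SNPs
        from medlmm.lmm import association_scan

        _, _, p = association_scan(y, snps, basis, null.lambda_)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_perfect_signal_identity_kinship(self):
        n = 40
        rng = np.random.default_rng(2)
        x = rng.standard_normal(n)
        beta, se, p = association_test(x.copy(), x, identity_basis(n), 0.0)
        assert beta == pytest.approx(1.0, abs=1e-10)
        assert p < 1e-30

    def test_matches_dense_gls_oracle(self):
        n = 50
        k = rng_psd_kinship(n, 31)
        basis = eigendecompose_kinship(k)
        rng = np.random.default_rng(31)
        x = rng.standard_normal(n)
        y = 0.3 * x + rng.standard_normal(n)
        lam = 1.3
        beta, se, p = association_test(y, x, basis, lam)
        V = lam * k + np.eye(n)
        X = np.column_stack([np.ones(n), x])
        beta_d, cov_raw = dense_gls(y, X, V)
        resid = y - X @ beta_d
        sigma2 = resid @ np.linalg.inv(V) @ resid / (n - 2)
        np.testing.assert_allclose(beta, beta_d[1], atol=1e-8)
        np.testing.assert_allclose(se, np.sqrt(sigma2 * cov_raw[1, 1]), atol=1e-8)

    def test_allele_flip_symmetry(self, small_panel):
        g, k = small_panel
        basis = eigendecompose_kinship(k)
        n = g.n_lines
        rng = np.random.default_rng(41)
        x = rng.standard_normal(n)
        y = 0.2 * x + rng.standard_normal(n)
        b1, _, p1 = association_test(y, x, basis, 0.5)
        b2, _, p2 = association_test(y, -x, basis, 0.5)
        assert b1 == pytest.approx(-b2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_constant_snp_rejected(self):
        with pytest.raises(ValueError):
            association_test(np.arange(10.0), np.ones(10), identity_basis(10), 0.0)
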