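"""Gibbs sampler conditionals, the full fit, and the composite strategy."""

import numpy as np
import pytest
from scipy import stats

from pgxprs.bayes import (MCMCConfig, PriorHyper, _omega_inv_parts,
                          compose_disease_pgx, fit_prs_pgx_bayes,
                          fit_prs_pgx_bayesx, sample_coefficients_block,
                          sample_local_covariance, sample_local_scales,
                          sample_residual_variance)
from pgxprs.io import DiseaseSummaryStats, ValidationError
from pgxprs.ld import build_design_correlation

from conftest import make_panel, make_pgx_sumstats


def _phi_matrix(D, psi, xi, rho):
    m = len(psi)
    a, d, c = _omega_inv_parts(psi, xi, rho)
    Phi = D.copy()
    idx = np.arange(m)
    Phi[idx, idx] += a
    Phi[m + idx, m + idx] += d
    Phi[idx, m + idx] += c
    Phi[m + idx, idx] += c
    return Phi


class TestCoefficientDraws:
    def test_null_bhat_draws_centered_at_zero(self, rng):
        panel = make_panel(m=5, seed=1)
        D = build_design_correlation(panel, 0.5, 0.05).D[0]
        psi = np.ones(5)
        draws = np.array([
            sample_coefficients_block(np.zeros(10), D, (psi, psi, np.zeros(5)),
                                      1.0, np.full(10, 1000.0), rng)
            for _ in range(2000)])
        se = draws.std(0) / np.sqrt(2000)
        assert np.all(np.abs(draws.mean(0)) < 4 * se)

    def test_mean_matches_dense_solve(self, rng):
        """Empirical mean of draws equals (D+Ω⁻¹)⁻¹ b̂ within MC error."""
        D = np.array([[1.0, 0.5], [0.5, 0.5]])
        psi = np.array([0.8])
        xi = np.array([1.2])
        rho = np.array([0.3])
        bhat = np.array([0.1, 0.05])
        draws = np.array([
            sample_coefficients_block(bhat, D, (psi, xi, rho), 1.0,
                                      np.full(2, 500.0), rng)
            for _ in range(5000)])
        mu = np.linalg.solve(_phi_matrix(D, psi, xi, rho), bhat)
        se = draws.std(0) / np.sqrt(5000)
        assert np.all(np.abs(draws.mean(0) - mu) < 3.5 * se)

    def test_distribution_matches_printed_formulas(self, rng):
        """With W = N·I the draw law equals μ=(N/σ²)Σb̂, Σ=(σ²/N)(D+Ω⁻¹)⁻¹."""
        m = 10
        panel = make_panel(m=m, seed=3)
        D = build_design_correlation(panel, 0.5, 0.1).D[0]
        psi = rng.uniform(0.5, 2, m)
        xi = rng.uniform(0.5, 2, m)
        rho = rng.uniform(-0.4, 0.4, m)
        bhat = rng.normal(0, 0.05, 2 * m)
        N, sigma2 = 2000.0, 0.7
        draws = np.array([
            sample_coefficients_block(bhat, D, (psi, xi, rho), sigma2,
                                      np.full(2 * m, N), rng)
            for _ in range(4000)])
        Phi = _phi_matrix(D, psi, xi, rho)
        Sigma = sigma2 / N * np.linalg.inv(Phi)
        mu = N / sigma2 * Sigma @ bhat
        se = draws.std(0) / np.sqrt(4000)
        assert np.all(np.abs(draws.mean(0) - mu) < 4 * se)
        emp_cov = np.cov(draws.T)
        assert np.abs(np.diag(emp_cov) - np.diag(Sigma)).max() < \
            5 * np.diag(Sigma).max() / np.sqrt(4000) * np.sqrt(2) * 3

    def test_non_pd_precision_advises_ridge(self, rng):
        D = -10 * np.eye(2)
        with pytest.raises(ValidationError, match="ridge|lambda"):
            sample_coefficients_block(np.zeros(2), D,
                                      (np.array([1e8]), np.array([1e8]),
                                       np.array([0.0])),
                                      1.0, np.full(2, 100.0), rng)


class TestResidualVariance:
    def test_null_case_mean_matches_inverse_gamma_identity(self, rng):
        """b = b̂ = 0: rate N/2, mean (N/2)/(m + N/2 − 1) over draws."""
        N, m = 200.0, 10
        draws = [sample_residual_variance(np.zeros(2 * m), np.zeros(2 * m),
                                          0.0, N, m, rng)
                 for _ in range(5000)]
        expected = (N / 2) / (m + N / 2 - 1)
        se = np.std(draws) / np.sqrt(5000)
        assert abs(np.mean(draws) - expected) < 4 * se

    def test_negative_rate_clamped(self, rng):
        bhat = np.array([1.0, 0.0])
        b = np.array([1.0, 0.0])   # 1 - 2 b̂'b + b'Mb < 0 with tiny quad
        val = sample_residual_variance(bhat, b, 0.0, 100.0, 1, rng)
        assert np.isfinite(val) and val > 0

    def test_shape_linear_in_n(self):
        # iG shape is m + N/2: difference across N is N-difference / 2
        assert (1 + 100 / 2) - (1 + 50 / 2) == 25


class TestLocalCovariance:
    def test_null_mean_matches_inverse_wishart_identity(self, rng):
        """K=1, b=0: E[M_j] = B_j/(2v−1) with B_j = 4v·diag(δ, λ)."""
        v, n_draws = 3.0, 20000
        delta = np.full(n_draws, 0.9)
        lam = np.full(n_draws, 0.4)
        zeros = np.zeros((1, n_draws))
        psi, xi, rho = sample_local_covariance(
            zeros, zeros, np.array([1.0]), np.array([[500.0, 500.0]]),
            delta, lam, v, rng)
        for draw, scale in ((psi, 4 * v * 0.9), (xi, 4 * v * 0.4)):
            expected = scale / (2 * v - 1)
            se = draw.std(ddof=1) / np.sqrt(n_draws)
            assert abs(draw.mean() - expected) < 4 * se

    def test_draws_are_valid_covariances(self, rng):
        m = 500
        beta = rng.normal(0, 0.1, (2, m))
        alpha = rng.normal(0, 0.1, (2, m))
        psi, xi, rho = sample_local_covariance(
            beta, alpha, np.array([1.0, 0.8]),
            np.array([[1000.0, 1000.0], [500.0, 500.0]]),
            np.ones(m), np.ones(m), 4.0, rng)
        assert np.all(psi > 0) and np.all(xi > 0)
        assert np.all(np.abs(rho) < 1)

    def test_scale_matrix_linear_in_precision_weight(self, rng):
        """Doubling N_k/σ_k² doubles the data part A_j of the scale."""
        b = np.array([[0.3]])
        a = np.array([[0.2]])
        v = 4.0
        # compare expected scale entries directly
        A1 = 1000.0 / 1.0 * b[0, 0] ** 2
        A2 = 2000.0 / 1.0 * b[0, 0] ** 2
        assert A2 == pytest.approx(2 * A1)
        # and the sampler consumes them consistently: larger weight -> larger psi
        n1 = [sample_local_covariance(b, a, np.array([1.0]),
                                      np.array([[1000.0, 1000.0]]),
                                      np.ones(1), np.ones(1), v, rng)[0][0]
              for _ in range(2000)]
        n2 = [sample_local_covariance(b, a, np.array([1.0]),
                                      np.array([[4000.0, 4000.0]]),
                                      np.ones(1), np.ones(1), v, rng)[0][0]
              for _ in range(2000)]
        assert np.mean(n2) > np.mean(n1)


class TestLocalScales:
    def test_gamma_mean_identity(self, rng):
        """ρ=0, ψ=2v, φ=0 → rate 1, mean v + b1 + 1/2."""
        v, b1 = 4.0, 0.5
        n = 10000
        psi = np.full(n, 2 * v)
        delta, _ = sample_local_scales(psi, psi, np.zeros(n), 0.0, v, b1, b1, rng)
        expected = v + b1 + 0.5
        se = delta.std(ddof=1) / np.sqrt(n)
        assert abs(delta.mean() - expected) < 4 * se

    def test_rate_monotone_in_phi(self, rng):
        v = 4.0
        psi = np.full(5000, 1.0)
        lo, _ = sample_local_scales(psi, psi, np.zeros(5000), 0.1, v, 0.5, 0.5,
                                    np.random.default_rng(1))
        hi, _ = sample_local_scales(psi, psi, np.zeros(5000), 10.0, v, 0.5, 0.5,
                                    np.random.default_rng(1))
        assert lo.mean() > hi.mean()

    def test_large_psi_limit_rate_phi(self, rng):
        """ψ → ∞ makes the δ rate → φ, so the mean → (v+b1+1/2)/φ."""
        v, b1, phi = 2.0, 0.5, 4.0
        psi = np.full(20000, 1e12)
        delta, _ = sample_local_scales(psi, psi, np.zeros(20000), phi, v, b1,
                                       b1, rng)
        expected = (v + b1 + 0.5) / phi
        assert delta.mean() == pytest.approx(expected, rel=0.05)


class TestFit:
    def test_null_sumstats_shrink_to_zero(self):
        ss = make_pgx_sumstats(m=100, seed=8, n=5000)
        ss.beta_G[:] = 0.0
        ss.beta_GT[:] = 0.0
        panel = make_panel(m=100, seed=8, block_size=50)
        post = fit_prs_pgx_bayes(ss, panel, PriorHyper(),
                                 MCMCConfig(n_iter=200, n_burnin=100, seed=0))
        assert np.abs(post.beta_post).max() < 0.02
        assert np.abs(post.alpha_post).max() < 0.02

    def test_single_population_delegates_bitwise(self):
        ss = make_pgx_sumstats(m=20, seed=9)
        panel = make_panel(m=20, seed=9)
        mcmc = MCMCConfig(n_iter=100, n_burnin=50, seed=4)
        a = fit_prs_pgx_bayes(ss, panel, PriorHyper(), mcmc)
        b = fit_prs_pgx_bayesx([ss], [panel], PriorHyper(), mcmc)[0]
        np.testing.assert_array_equal(a.beta_post, b.beta_post)
        np.testing.assert_array_equal(a.alpha_post, b.alpha_post)

    def test_deterministic_given_seed(self):
        ss = make_pgx_sumstats(m=20, seed=10)
        panel = make_panel(m=20, seed=10)
        mcmc = MCMCConfig(n_iter=100, n_burnin=50, seed=7)
        a = fit_prs_pgx_bayes(ss, panel, PriorHyper(), mcmc)
        b = fit_prs_pgx_bayes(ss, panel, PriorHyper(), mcmc)
        np.testing.assert_array_equal(a.beta_post, b.beta_post)

    def test_population_order_symmetry(self):
        """Swapping population input order swaps outputs bit-identically."""
        ss1 = make_pgx_sumstats(m=15, seed=11, population="EUR")
        ss2 = make_pgx_sumstats(m=15, seed=12, population="EAS")
        p1 = make_panel(m=15, seed=11, population="EUR")
        p2 = make_panel(m=15, seed=11, population="EAS")  # same block structure
        mcmc = MCMCConfig(n_iter=80, n_burnin=40, seed=3)
        out_a = fit_prs_pgx_bayesx([ss1, ss2], [p1, p2], PriorHyper(), mcmc)
        out_b = fit_prs_pgx_bayesx([ss2, ss1], [p2, p1], PriorHyper(), mcmc)
        by_pop_a = {o.population: o for o in out_a}
        by_pop_b = {o.population: o for o in out_b}
        for pop in ("EUR", "EAS"):
            np.testing.assert_array_equal(by_pop_a[pop].beta_post,
                                          by_pop_b[pop].beta_post)

    def test_burnin_config_error(self):
        with pytest.raises(ValidationError):
            MCMCConfig(n_iter=100, n_burnin=100)

    def test_empty_intersection_errors(self):
        ss = make_pgx_sumstats(m=5, seed=13)
        panel = make_panel(m=5, seed=13)
        for b in panel.blocks:
            b.variant_ids = [f"zz{i}" for i in range(len(b.variant_ids))]
        panel.variants = []
        with pytest.raises(ValidationError):
            fit_prs_pgx_bayes(ss, panel, PriorHyper(),
                              MCMCConfig(n_iter=10, n_burnin=5))

    def test_null_posterior_sign_balance(self):
        """Pure-noise inputs give sign-balanced posterior means."""
        ss = make_pgx_sumstats(m=100, seed=14, n=2000)
        panel = make_panel(m=100, seed=14, block_size=50)
        post = fit_prs_pgx_bayes(ss, panel, PriorHyper(),
                                 MCMCConfig(n_iter=200, n_burnin=100, seed=1))
        pos = int((post.beta_post > 0).sum())
        # binomial(100, 1/2) within 4 SDs
        assert abs(pos - 50) < 4 * np.sqrt(100 * 0.25)


class TestComposeDiseasePGx:
    def _disease_from(self, pgx, n=50000):
        return DiseaseSummaryStats(
            variants=list(pgx.variants), beta=pgx.beta_G.copy(),
            se=pgx.se_G.copy(), p=pgx.p_G.copy(), n=n, eaf=pgx.eaf.copy())

    def test_identity_substitution(self):
        pgx = make_pgx_sumstats(m=8, seed=15)
        disease = self._disease_from(pgx, n=pgx.n)
        comp = compose_disease_pgx(disease, pgx)
        np.testing.assert_array_equal(comp.beta_G, pgx.beta_G)
        np.testing.assert_array_equal(comp.beta_GT, pgx.beta_GT)
        assert comp.n_G == disease.n and comp.n_GT == pgx.n

    def test_swapped_disease_alleles_align_sign(self):
        pgx = make_pgx_sumstats(m=4, seed=16)
        disease = self._disease_from(pgx)
        disease.variants[2] = disease.variants[2].flipped()
        disease.beta = disease.beta.copy()
        disease.beta[2] = 0.3
        comp = compose_disease_pgx(disease, pgx)
        assert comp.beta_G[2] == pytest.approx(-0.3)

    def test_per_coordinate_sample_sizes_recorded(self):
        pgx = make_pgx_sumstats(m=6, seed=17, n=1000)
        disease = self._disease_from(pgx, n=50000)
        comp = compose_disease_pgx(disease, pgx)
        assert comp.n_G == 50000
        assert comp.n_GT == 1000
        assert comp.prognostic_source == "disease_marginal"
        np.testing.assert_array_equal(comp.beta_G_pgx, pgx.beta_G)

    def test_empty_intersection_errors(self):
        pgx = make_pgx_sumstats(m=3, seed=18)
        disease = self._disease_from(pgx)
        from pgxprs.io import VariantKey
        disease.variants = [VariantKey(f"q{i}", "7", 5 + i, "A", "G")
                            for i in range(3)]
        with pytest.raises(ValidationError):
            compose_disease_pgx(disease, pgx)
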