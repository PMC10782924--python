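"""The synthetic-trial generator: LD, effects, calibration, summary stats."""

import numpy as np
import pytest
from scipy import stats

from pgxprs.io import ValidationError
from pgxprs.simulate import (SimScenario, build_scenario,
                             compute_disease_sumstats, compute_pgx_sumstats,
                             draw_effect_sizes, simulate_disease_cohort,
                             simulate_ld_genotypes, simulate_pgx_cohort)


class TestGenotypes:
    def test_dosages_and_mafs_in_range(self, rng):
        scn = SimScenario(m=100, block_size=50, seed=1)
        G, mafs = simulate_ld_genotypes(2000, scn, rng)
        assert set(np.unique(G)) <= {0.0, 1.0, 2.0}
        assert mafs.min() >= scn.maf_range[0] and mafs.max() <= scn.maf_range[1]

    def test_zero_ar1_gives_independent_snps(self, rng):
        scn = SimScenario(m=100, block_size=50, ar1_rho=0.0, seed=2)
        G, _ = simulate_ld_genotypes(5000, scn, rng)
        R = np.corrcoef(G, rowvar=False)
        off = np.abs(R[np.triu_indices(100, 1)])
        assert off.mean() < 0.02

    def test_adjacent_ld_matches_tetrachoric_target(self, rng):
        """Empirical dosage correlation vs the latent-threshold induced value."""
        scn = SimScenario(m=50, block_size=50, ar1_rho=0.8,
                          maf_range=(0.2, 0.4), seed=3)
        G, mafs = simulate_ld_genotypes(20000, scn, rng)
        R = np.corrcoef(G, rowvar=False)
        t = stats.norm.ppf(mafs)
        mvn = stats.multivariate_normal(mean=[0, 0],
                                        cov=[[1, 0.8], [0.8, 1]])
        for j in range(0, 40, 8):
            p11 = mvn.cdf([t[j], t[j + 1]])
            target = (p11 - mafs[j] * mafs[j + 1]) / np.sqrt(
                mafs[j] * (1 - mafs[j]) * mafs[j + 1] * (1 - mafs[j + 1]))
            assert R[j, j + 1] == pytest.approx(target, abs=0.05)

    def test_hardy_weinberg_heterozygosity(self, rng):
        scn = SimScenario(m=50, block_size=50, maf_range=(0.3, 0.3001), seed=4)
        G, _ = simulate_ld_genotypes(20000, scn, rng)
        het = (G == 1).mean(axis=0)
        assert het.mean() == pytest.approx(2 * 0.3 * 0.7, abs=0.01)


class TestEffects:
    def test_zero_p_causal_all_zero(self, rng):
        scn = SimScenario(m=50, block_size=50, p_causal=0.0, seed=5)
        eff = draw_effect_sizes(scn, rng)
        assert not np.any(eff.base_prognostic["EUR"])
        assert not np.any(eff.target_predictive["EUR"])

    def test_expected_causal_count(self):
        """E[#causal] = m·p_causal (2263 for the reference m=22630, p=0.1)."""
        assert 22630 * 0.1 == pytest.approx(2263)
        scn = SimScenario(m=2000, block_size=50, p_causal=0.1, seed=6)
        counts = [draw_effect_sizes(scn, np.random.default_rng(s)).causal.sum()
                  for s in range(5)]
        se = np.sqrt(2000 * 0.1 * 0.9 / 5)
        assert abs(np.mean(counts) - 200) < 4 * se

    def test_effect_type_correlation_recovered(self, rng):
        scn = SimScenario(m=10000, block_size=50, p_causal=0.1, rho_E=0.6,
                          seed=7)
        eff = draw_effect_sizes(scn, rng)
        c = eff.causal
        r = np.corrcoef(eff.target_prognostic["EUR"][c],
                        eff.target_predictive["EUR"][c])[0, 1]
        assert r == pytest.approx(0.6, abs=3 / np.sqrt(c.sum()))

    def test_population_correlation_recovered(self, rng):
        scn = SimScenario(m=10000, block_size=50, p_causal=0.1, rho_P=0.5,
                          populations=("EUR", "EAS"), seed=8)
        eff = draw_effect_sizes(scn, rng)
        c = eff.causal
        r = np.corrcoef(eff.target_prognostic["EUR"][c],
                        eff.target_prognostic["EAS"][c])[0, 1]
        assert r == pytest.approx(0.5, abs=3 / np.sqrt(c.sum()))

    def test_cohort_correlation_recovered(self, rng):
        scn = SimScenario(m=10000, block_size=50, p_causal=0.1, rho_C=0.8,
                          seed=9)
        eff = draw_effect_sizes(scn, rng)
        c = eff.causal
        r = np.corrcoef(eff.base_prognostic["EUR"][c],
                        eff.target_prognostic["EUR"][c])[0, 1]
        assert r == pytest.approx(0.8, abs=3 / np.sqrt(c.sum()))

    def test_separated_mode_disjoint_causal_sets(self, rng):
        scn = SimScenario(m=5000, block_size=50, p_causal=0.2,
                          effect_mode="separated", seed=10)
        eff = draw_effect_sizes(scn, rng)
        assert not np.any(eff.causal_prognostic & eff.causal_predictive)
        prog = eff.base_prognostic["EUR"]
        pred = eff.base_predictive["EUR"]
        assert not np.any(pred[eff.causal_prognostic & ~eff.causal_predictive])
        assert not np.any(prog[eff.causal_predictive & ~eff.causal_prognostic])

    def test_dominance_ratio_rescales_variance(self, rng):
        scn = SimScenario(m=20000, block_size=50, p_causal=0.2,
                          scale_mode="prognostic_dominant", seed=11)
        eff = draw_effect_sizes(scn, rng)
        c = eff.causal
        ratio = np.var(eff.base_prognostic["EUR"][c]) / \
            np.var(eff.base_predictive["EUR"][c])
        assert ratio == pytest.approx(9.0, rel=0.25)


class TestPhenotypes:
    def test_treated_fraction_binomial(self, rng):
        scn = SimScenario(m=50, block_size=50, p_causal=0.2, seed=12,
                          treated_fraction=0.3)
        eff = draw_effect_sizes(scn, rng)
        G, _ = simulate_ld_genotypes(5000, scn, rng)
        cohort, _ = simulate_pgx_cohort(G, eff.target_prognostic["EUR"],
                                        eff.target_predictive["EUR"], scn, rng)
        se = np.sqrt(0.3 * 0.7 / 5000)
        assert abs(cohort.T.mean() - 0.3) < 3 * se

    def test_heritability_calibrated(self, rng):
        scn = SimScenario(m=100, block_size=50, p_causal=0.2, h2=0.3, seed=13)
        eff = draw_effect_sizes(scn, rng)
        beta = eff.target_prognostic["EUR"]
        alpha = eff.target_predictive["EUR"]
        G, _ = simulate_ld_genotypes(50000, scn, rng)
        cohort, c = simulate_pgx_cohort(G, beta, alpha, scn, rng)
        Gs = (cohort.G - cohort.G.mean(0)) / cohort.G.std(0)
        genetic = (Gs @ beta + cohort.T * (Gs @ alpha)) / c
        t = cohort.T == 1
        assert np.var(genetic[t]) / np.var(cohort.Y[t]) == pytest.approx(0.3, abs=0.01)

    def test_zero_effects_with_positive_h2_rejected(self, rng):
        scn = SimScenario(m=50, block_size=50, p_causal=0.0, h2=0.3, seed=14)
        G, _ = simulate_ld_genotypes(100, scn, rng)
        with pytest.raises(ValidationError):
            simulate_pgx_cohort(G, np.zeros(50), np.zeros(50), scn, rng)

    def test_disease_cohort_calibration(self, rng):
        scn = SimScenario(m=100, block_size=50, p_causal=0.2, seed=15)
        eff = draw_effect_sizes(scn, rng)
        mu = eff.base_prognostic["EUR"]
        G, _ = simulate_ld_genotypes(50000, scn, rng)
        Y, c = simulate_disease_cohort(G, mu, 0.3, rng)
        Gs = (G - G.mean(0)) / G.std(0)
        assert np.var(Gs @ mu / c) / np.var(Y) == pytest.approx(0.3, abs=0.01)


class TestSummaryStatistics:
    def test_null_z_scores_standard_normal(self, rng):
        """Null SNPs give z with variance ≈ 1 and mean ≈ 0."""
        scn = SimScenario(m=1000, block_size=50, ar1_rho=0.0, p_causal=0.0,
                          h2=0.0, seed=16)
        G, _ = simulate_ld_genotypes(600, scn, rng)
        cohort, _ = simulate_pgx_cohort(G, np.zeros(1000), np.zeros(1000),
                                        scn, rng)
        ss = compute_pgx_sumstats(cohort)
        z = ss.beta_G / ss.se_G
        assert abs(z.mean()) < 3 / np.sqrt(1000)
        assert z.var() == pytest.approx(1.0, abs=0.15)

    def test_single_causal_snp_recovered(self, rng):
        scn = SimScenario(m=50, block_size=50, ar1_rho=0.0, p_causal=0.0,
                          h2=0.5, seed=17)
        G, _ = simulate_ld_genotypes(4000, scn, rng)
        beta = np.zeros(50)
        beta[7] = 1.0
        cohort, c = simulate_pgx_cohort(G, beta, np.zeros(50), scn, rng)
        ss = compute_pgx_sumstats(cohort)
        sd7 = cohort.G[:, 7].std()
        # per-allele estimate times dosage SD = standardized effect
        assert ss.beta_G[7] * sd7 == pytest.approx(1.0 / c, abs=3 * ss.se_G[7] * sd7)
        assert ss.n == 4000

    def test_disease_sumstats_null_calibration(self, rng):
        scn = SimScenario(m=800, block_size=50, ar1_rho=0.0, seed=18)
        G, _ = simulate_ld_genotypes(500, scn, rng)
        Y = rng.standard_normal(500)
        ss = compute_disease_sumstats(Y, G)
        z = ss.beta / ss.se
        assert z.var() == pytest.approx(1.0, abs=0.15)
        assert ss.n == 500


class TestScenarioBundle:
    def test_deterministic_for_fixed_seed(self):
        scn = SimScenario(m=100, block_size=50, p_causal=0.1,
                          n_disease=500, n_pgx_base=300, n_target=200,
                          n_external_valid=100, n_reference=200, seed=19)
        a = build_scenario(scn)
        b = build_scenario(scn)
        pa, pb = a.populations["EUR"], b.populations["EUR"]
        np.testing.assert_array_equal(pa.target.Y, pb.target.Y)
        np.testing.assert_array_equal(pa.pgx_sumstats.beta_GT,
                                      pb.pgx_sumstats.beta_GT)
        np.testing.assert_array_equal(pa.ld_panel.blocks[0].R,
                                      pb.ld_panel.blocks[0].R)

    def test_two_population_structure(self):
        scn = SimScenario(m=100, block_size=50, p_causal=0.1,
                          populations=("EUR", "EAS"),
                          n_disease={"EUR": 500, "EAS": 200},
                          n_pgx_base={"EUR": 300, "EAS": 100},
                          n_target={"EUR": 200, "EAS": 100},
                          n_external_valid=100, n_reference=200, seed=20)
        b = build_scenario(scn)
        assert set(b.populations) == {"EUR", "EAS"}
        assert b.populations["EUR"].pgx_base.n == 300
        assert b.populations["EAS"].pgx_base.n == 100
        assert b.populations["EAS"].disease_sumstats.n == 200

    def test_cohorts_mutually_independent(self, small_bundle):
        """Base and target residual noise uncorrelated given the effects."""
        pd_ = small_bundle.populations["EUR"]
        n = min(pd_.pgx_base.n, pd_.target.n)
        r = np.corrcoef(pd_.pgx_base.Y[:n], pd_.target.Y[:n])[0, 1]
        assert abs(r) < 3 / np.sqrt(n)
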