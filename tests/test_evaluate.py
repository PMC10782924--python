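"""Score computation, the evaluation model, tuning, stratification."""

import numpy as np
import pandas as pd
import pytest

from pgxprs.evaluate import (PRSPair, compute_prs, cv_tune, evaluate_prediction,
                             external_tune, posterior_to_weights,
                             stratify_patients)
from pgxprs.io import PGxCohort, ValidationError

from conftest import make_variants


def _weights(variants, w_G, w_GT):
    return pd.DataFrame({
        "SNP": [v.id for v in variants], "CHR": [v.chrom for v in variants],
        "POS": [v.pos for v in variants], "A1": [v.a1 for v in variants],
        "BETA_G_POST": w_G, "BETA_GT_POST": w_GT, "POPULATION": "EUR"})


def _cohort(n=200, m=3, seed=0):
    rng = np.random.default_rng(seed)
    return PGxCohort("EUR", rng.normal(size=n),
                     (rng.uniform(size=n) < 0.5).astype(float),
                     rng.integers(0, 3, (n, m)).astype(float),
                     make_variants(m)), rng


class TestComputePRS:
    def test_zero_weights_zero_scores(self):
        cohort, _ = _cohort()
        prs = compute_prs(cohort, _weights(cohort.variants, np.zeros(3), np.zeros(3)))
        assert not np.any(prs.prs_G) and not np.any(prs.prs_GT)

    def test_single_snp_unstandardized_score_is_dosage(self):
        cohort, _ = _cohort()
        w = _weights(cohort.variants, np.array([1.0, 0, 0]), np.zeros(3))
        prs = compute_prs(cohort, w, standardize=False)
        np.testing.assert_array_equal(prs.prs_G, cohort.G[:, 0])

    def test_flip_invariance(self):
        cohort, rng = _cohort(m=5, seed=2)
        w_G = rng.normal(size=5)
        w_GT = rng.normal(size=5)
        w = _weights(cohort.variants, w_G, w_GT)
        flipped = w.copy()
        flipped.loc[2, "A1"] = cohort.variants[2].a2
        flipped.loc[2, "BETA_G_POST"] *= -1
        flipped.loc[2, "BETA_GT_POST"] *= -1
        s1 = compute_prs(cohort, w)
        s2 = compute_prs(cohort, flipped)
        assert np.abs(s1.prs_G - s2.prs_G).max() < 1e-12
        assert np.abs(s1.prs_GT - s2.prs_GT).max() < 1e-12

    def test_no_overlap_errors(self):
        cohort, _ = _cohort()
        w = _weights(make_variants(2, prefix="zz"), np.ones(2), np.ones(2))
        with pytest.raises(ValidationError):
            compute_prs(cohort, w)


class TestEvaluatePrediction:
    def test_perfect_score_r2_one(self):
        cohort, rng = _cohort(n=300, seed=3)
        prs = PRSPair(cohort.Y.copy(), rng.normal(size=300))
        res = evaluate_prediction(cohort, prs)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_wald_p_matches_statsmodels(self):
        """Interaction p agrees with an independent OLS implementation."""
        import statsmodels.api as sm
        cohort, rng = _cohort(n=50, seed=4)
        prs = PRSPair(rng.normal(size=50), rng.normal(size=50))
        res = evaluate_prediction(cohort, prs)
        X = sm.add_constant(np.column_stack([
            cohort.T, prs.prs_G, cohort.T * prs.prs_GT]))
        fit = sm.OLS(cohort.Y, X).fit()
        assert res.p_interaction == pytest.approx(fit.pvalues[3], rel=1e-10)
        assert res.beta3 == pytest.approx(fit.params[3], rel=1e-10)

    def test_affine_invariance_of_r2(self):
        cohort, rng = _cohort(n=400, seed=5)
        g = rng.normal(size=400)
        gt = rng.normal(size=400)
        r1 = evaluate_prediction(cohort, PRSPair(g, gt)).r2
        r2 = evaluate_prediction(cohort, PRSPair(3 * g + 1, -2 * gt + 5)).r2
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_constant_prs_rejected(self):
        cohort, rng = _cohort()
        with pytest.raises(ValidationError):
            evaluate_prediction(cohort, PRSPair(np.ones(cohort.n),
                                                rng.normal(size=cohort.n)))

    def test_permuted_scores_null_p_uniform(self):
        """Subject-shuffled PRS gives a calibrated interaction test."""
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            n = 150
            T = (rng.uniform(size=n) < 0.5).astype(float)
            g = rng.normal(size=n)
            Y = g + rng.normal(size=n)
            cohort = PGxCohort("EUR", Y, T, np.zeros((n, 1)), make_variants(1))
            perm = rng.permutation(n)
            res = evaluate_prediction(cohort, PRSPair(g[perm], g[perm]))
            rejections += res.p_interaction < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 3.5 * se


class TestTuning:
    def _setup(self, seed=7, n=600):
        rng = np.random.default_rng(seed)
        m = 4
        G = rng.integers(0, 3, (n, m)).astype(float)
        T = (rng.uniform(size=n) < 0.5).astype(float)
        Gs = (G - G.mean(0)) / G.std(0)
        signal = Gs @ np.array([0.5, 0.4, 0.0, 0.0])
        Y = signal + T * signal + rng.normal(size=n)
        cohort = PGxCohort("EUR", Y, T, G, make_variants(m))
        good = _weights(cohort.variants, np.array([0.5, 0.4, 0, 0]),
                        np.array([0.5, 0.4, 0, 0]))
        noise = _weights(cohort.variants, rng.normal(size=m) * 0.01 +
                         np.array([0, 0, 1.0, 1.0]),
                         np.array([0, 0, 1.0, 1.0]))
        return cohort, good, noise

    def test_single_candidate_trivial(self):
        cohort, good, _ = self._setup()
        best, folds, oof = cv_tune(cohort, {"only": good}, seed=1)
        assert best == "only"
        assert len(folds["only"]) == 5
        assert len(oof.prs_G) == cohort.n

    def test_oracle_candidate_selected(self):
        for seed in (1, 2, 3):
            cohort, good, noise = self._setup(seed=seed)
            best, _, _ = cv_tune(cohort, {"noise": noise, "good": good}, seed=seed)
            assert best == "good"

    def test_same_seed_same_folds_and_choice(self):
        cohort, good, noise = self._setup()
        a = cv_tune(cohort, {"a": good, "b": noise}, seed=9)
        b = cv_tune(cohort, {"a": good, "b": noise}, seed=9)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[2].prs_G, b[2].prs_G)

    def test_no_leakage_oof_below_train(self):
        oof_minus_train = []
        for seed in range(8):
            cohort, good, _ = self._setup(seed=100 + seed)
            _, folds, _ = cv_tune(cohort, {"w": good}, seed=seed)
            for res in folds["w"]:
                oof_minus_train.append(res.meta["oof_r2"] - res.meta["train_r2"])
        assert np.mean(oof_minus_train) < 0.02

    def test_external_tune_selects_better_candidate(self):
        cohort, good, noise = self._setup(seed=11)
        assert external_tune(cohort, {"n": noise, "g": good}) == "g"

    def test_tiny_cohort_fold_error(self):
        cohort, good, _ = self._setup(n=6)
        with pytest.raises(ValidationError):
            cv_tune(cohort, {"w": good}, k_folds=5, seed=0)


class TestStratification:
    def test_median_split(self):
        rng = np.random.default_rng(12)
        n = 10
        cohort = PGxCohort("EUR", rng.normal(size=n),
                           np.array([0, 1] * 5, dtype=float),
                           np.zeros((n, 1)), make_variants(1))
        prs = PRSPair(np.arange(n, dtype=float), np.arange(n, dtype=float))
        out = stratify_patients(prs, cohort, n_strata=2)
        assert list(out["n"]) == [5, 5]

    def test_score_means_nondecreasing(self):
        rng = np.random.default_rng(13)
        n = 400
        cohort = PGxCohort("EUR", rng.normal(size=n),
                           (rng.uniform(size=n) < 0.5).astype(float),
                           np.zeros((n, 1)), make_variants(1))
        prs = PRSPair(rng.normal(size=n), rng.normal(size=n))
        out = stratify_patients(prs, cohort, n_strata=4, component="G")
        assert np.all(np.diff(out["score_mean"]) >= 0)

    def test_strong_predictive_effect_separates_strata(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            n = 500
            T = (rng.uniform(size=n) < 0.5).astype(float)
            score = rng.normal(size=n)
            Y = T * score + 0.5 * rng.normal(size=n)
            cohort = PGxCohort("EUR", Y, T, np.zeros((n, 1)), make_variants(1))
            out = stratify_patients(PRSPair(score, score), cohort, n_strata=4)
            diff = out["treatment_effect"]
            hits += diff.iloc[-1] > diff.iloc[0]
        assert hits >= 38
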