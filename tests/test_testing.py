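"""Testing-stage models: logistic interaction and linear joint fits."""

import numpy as np
import pytest
from scipy import stats

from twostage.testing import (
    SeparationError,
    fit_linear_joint,
    fit_logistic_interaction,
)


def table_to_vectors(counts):
    """Expand a 2x2x2 (disease, g1, g2) count table into vectors."""
    d, g1, g2 = [], [], []
    for dd in (0, 1):
        for a in (0, 1):
            for b in (0, 1):
                n = counts[(dd, a, b)]
                d += [dd] * n
                g1 += [a] * n
                g2 += [b] * n
    return np.array(g1, float), np.array(g2, float), np.array(d, float)


def closed_form_beta3(counts):
    """Saturated-model interaction coefficient: the log odds-ratio ratio."""
    n = {k: counts[k] for k in counts}
    or1 = (n[(1, 1, 1)] * n[(0, 1, 0)]) / (n[(0, 1, 1)] * n[(1, 1, 0)])
    or0 = (n[(1, 0, 1)] * n[(0, 0, 0)]) / (n[(0, 0, 1)] * n[(1, 0, 0)])
    return np.log(or1 / or0)


class TestLogisticInteraction:
    def test_symmetric_table_zero_interaction(self):
        counts = {(d, a, b): 10 for d in (0, 1) for a in (0, 1) for b in (0, 1)}
        g1, g2, d = table_to_vectors(counts)
        rec = fit_logistic_interaction(g1, g2, d)
        assert rec.coefficients[3] == pytest.approx(0.0, abs=1e-8)
        assert rec.df == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_beta3_matches_log_odds_ratio_ratio(self, seed):
        rng = np.random.default_rng(seed)
        counts = {
            (d, a, b): int(rng.integers(5, 60))
            for d in (0, 1) for a in (0, 1) for b in (0, 1)
        }
        g1, g2, d = table_to_vectors(counts)
        rec = fit_logistic_interaction(g1, g2, d)
        assert rec.coefficients[3] == pytest.approx(
            closed_form_beta3(counts), abs=1e-6
        )

    @pytest.mark.parametrize(
        "test_kind,df", [
            ("interaction_1df", 1),
            ("main1_plus_interaction_2df", 2),
            ("joint_3df", 3),
        ],
    )
    def test_df_per_kind_and_chi2_tail(self, test_kind, df):
        rng = np.random.default_rng(3)
        g1 = rng.binomial(2, 0.3, 400).astype(float)
        g2 = rng.binomial(2, 0.3, 400).astype(float)
        d = rng.integers(0, 2, 400).astype(float)
        rec = fit_logistic_interaction(g1, g2, d, test_kind)
        assert rec.df == df
        assert rec.p_value == pytest.approx(
            stats.chi2.sf(rec.statistic, df), abs=1e-12
        )

    def test_two_df_variant_configurable_main(self):
        rng = np.random.default_rng(4)
        g1 = rng.binomial(2, 0.3, 500).astype(float)
        g2 = rng.binomial(2, 0.3, 500).astype(float)
        logit = -1.0 + 1.2 * g1
        d = (rng.random(500) < 1 / (1 + np.exp(-logit))).astype(float)
        with_m1 = fit_logistic_interaction(
            g1, g2, d, "main1_plus_interaction_2df", main_effect=1
        )
        with_m2 = fit_logistic_interaction(
            g1, g2, d, "main1_plus_interaction_2df", main_effect=2
        )
        # the null dropping the active main effect must fit far worse
        assert with_m1.statistic > with_m2.statistic

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        g1 = rng.binomial(2, 0.3, 300).astype(float)
        g2 = rng.binomial(2, 0.4, 300).astype(float)
        d = rng.integers(0, 2, 300).astype(float)
        a = fit_logistic_interaction(g1, g2, d, "joint_3df")
        b = fit_logistic_interaction(g2, g1, d, "joint_3df")
        assert a.coefficients[3] == pytest.approx(b.coefficients[3], abs=1e-8)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-8)

    def test_allele_relabel_invariance_joint(self):
        # recoding minor/major allele (g -> 2 - g) is an affine change of
        # basis; the joint LR statistic must not move
        rng = np.random.default_rng(6)
        g1 = rng.binomial(2, 0.3, 400).astype(float)
        g2 = rng.binomial(2, 0.4, 400).astype(float)
        logit = -1.0 + 0.5 * g1 - 0.3 * g2 + 0.4 * g1 * g2
        d = (rng.random(400) < 1 / (1 + np.exp(-logit))).astype(float)
        a = fit_logistic_interaction(g1, g2, d, "joint_3df")
        b = fit_logistic_interaction(2 - g1, g2, d, "joint_3df")
        assert a.statistic == pytest.approx(b.statistic, abs=1e-6)

    def test_wald_close_to_lr_at_large_n(self):
        rng = np.random.default_rng(7)
        g1 = rng.binomial(2, 0.3, 4000).astype(float)
        g2 = rng.binomial(2, 0.3, 4000).astype(float)
        logit = -1.5 + 0.3 * g1 * g2
        d = (rng.random(4000) < 1 / (1 + np.exp(-logit))).astype(float)
        lr = fit_logistic_interaction(g1, g2, d, statistic="lr")
        wald = fit_logistic_interaction(g1, g2, d, statistic="wald")
        assert lr.statistic == pytest.approx(wald.statistic, rel=0.1)

    def test_one_disease_class_rejected(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.3, 50).astype(float)
        with pytest.raises(ValueError, match="both disease classes"):
            fit_logistic_interaction(g, g[::-1], np.ones(50))

    def test_rank_deficiency_rejected(self):
        g1 = np.array([0.0, 1, 2, 0, 1, 2] * 10)
        d = np.tile([0.0, 1], 30)
        with pytest.raises(ValueError, match="rank"):
            fit_logistic_interaction(g1, 2 * g1, d)

    def test_separation_raises(self):
        g1 = np.r_[np.zeros(20), np.ones(20)]
        g2 = np.r_[np.zeros(10), np.ones(10), np.zeros(10), np.ones(10)]
        d = np.r_[np.zeros(20), np.ones(20)]  # d == g1 exactly
        with pytest.raises(SeparationError):
            fit_logistic_interaction(g1, g2, d)

    def test_null_lr_statistic_is_chi2_1(self):
        # calibration: mean of the 1-df LR statistic under the global null
        # should be 1 (chi-square(1) mean), to within 3 SEs; n per replicate
        # is large enough that the O(1/n) Bartlett-type mean inflation of
        # the LR statistic is inside the Monte-Carlo band
        rng = np.random.default_rng(9)
        reps, n = 5000, 500
        stats_ = np.empty(reps)
        for i in range(reps):
            g1 = rng.binomial(2, 0.3, n).astype(float)
            g2 = rng.binomial(2, 0.3, n).astype(float)
            d = rng.integers(0, 2, n).astype(float)
            stats_[i] = fit_logistic_interaction(g1, g2, d).statistic
        se = np.sqrt(2.0 / reps)  # var of chi2(1) is 2
        assert abs(stats_.mean() - 1.0) < 3 * se


class TestLinearJoint:
    def test_exact_interaction_recovery(self):
        rng = np.random.default_rng(10)
        g1 = rng.binomial(2, 0.4, 40).astype(float)
        g2 = rng.binomial(2, 0.4, 40).astype(float)
        trait = 1.0 + g1 * g2
        rec = fit_linear_joint(g1, g2, trait, "interaction_1df")
        assert rec.coefficients[3] == pytest.approx(1.0, abs=1e-10)
        assert rec.coefficients[1] == pytest.approx(0.0, abs=1e-10)
        assert rec.coefficients[2] == pytest.approx(0.0, abs=1e-10)
        assert rec.p_value == 0.0 and np.isinf(rec.statistic)

    def test_small_dataset_matches_normal_equations(self):
        g1 = np.array([0.0, 1, 2, 0, 1, 2, 0, 1])
        g2 = np.array([0.0, 0, 1, 1, 2, 2, 0, 1])
        trait = np.array([1.2, 0.7, 3.1, 1.9, 4.2, 6.8, 0.9, 2.0])
        X = np.column_stack([np.ones(8), g1, g2, g1 * g2])
        beta_ref = np.linalg.solve(X.T @ X, X.T @ trait)
        rec = fit_linear_joint(g1, g2, trait, "joint_3df")
        np.testing.assert_allclose(rec.coefficients, beta_ref, atol=1e-10)

    def test_null_3df_p_uniform(self):
        rng = np.random.default_rng(11)
        reps, n = 2000, 60
        pvals = np.empty(reps)
        for i in range(reps):
            g1 = rng.binomial(2, 0.3, n).astype(float)
            g2 = rng.binomial(2, 0.3, n).astype(float)
            trait = 2.0 + rng.standard_normal(n)
            pvals[i] = fit_linear_joint(g1, g2, trait, "joint_3df").p_value
        ks = stats.ks_1samp(pvals, stats.uniform.cdf)
        assert ks.statistic < 0.04

    def test_constant_trait_rejected(self):
        rng = np.random.default_rng(12)
        g = rng.binomial(2, 0.4, 30).astype(float)
        with pytest.raises(ValueError, match="constant trait"):
            fit_linear_joint(g, rng.binomial(2, 0.4, 30).astype(float),
                             np.full(30, 3.0))

    def test_residual_df_guard(self):
        g1 = np.array([0.0, 1, 2, 1])
        g2 = np.array([0.0, 2, 1, 1])
        with pytest.raises(ValueError, match="residual"):
            fit_linear_joint(g1, g2, np.array([1.0, 2, 3, 4]))
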