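"""Statistical suite: closed forms, identities, oracle agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from asthmacost.stats import (
    cochran_armitage_trend,
    games_howell,
    normality_diagnostics,
    pearson_chi2,
    welch_anova,
)


class TestPearsonChi2:
    def test_homogeneous_table(self):
        res = pearson_chi2([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_closed_form_2x2(self):
        # N(ad-bc)^2 / (row and column margins) = 60*(400-100)^2/30^4
        res = pearson_chi2([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(6.6667, abs=1e-4)
        assert res.df == 1

    def test_agrees_with_reference_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            shape = rng.choice([2, 3, 4], size=2)
            table = rng.integers(1, 60, size=shape)
            mine = pearson_chi2(table)
            ref_stat, ref_p, ref_df, _ = sps.chi2_contingency(table, correction=False)
            assert mine.statistic == pytest.approx(ref_stat, abs=1e-8)
            assert mine.pvalue == pytest.approx(ref_p, abs=1e-8)
            assert mine.df == ref_df

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [5, 5]])

    def test_agrees_with_permutation_oracle(self):
        """Asymptotic p within Monte-Carlo error of a 1e5-permutation null."""
        table = np.array([[30, 20], [20, 30]])
        mine = pearson_chi2(table)
        outcomes = np.repeat([1, 0, 1, 0], table.ravel())
        rng = np.random.default_rng(0)
        n1 = table[0].sum()
        perms = rng.permuted(np.tile(outcomes, (100_000, 1)), axis=1)
        x1 = perms[:, :n1].sum(axis=1).astype(float)
        # margin-fixed 2x2 (all margins 50): statistic is a closed form of
        # the (1,1) cell
        perm_stats = 100.0 * (x1**2 - (50.0 - x1) ** 2) ** 2 / 50.0**4
        # the chi-square tail approximates the permutation mid-p on a
        # discrete 2x2 null (half-weighting the observed atom)
        p_mid = (
            (perm_stats > mine.statistic + 1e-9).mean()
            + 0.5 * (np.abs(perm_stats - mine.statistic) <= 1e-9).mean()
        )
        assert mine.pvalue == pytest.approx(p_mid, abs=0.02)


class TestCochranArmitage:
    def test_no_trend(self):
        res = cochran_armitage_trend([10, 10, 10, 10], [100, 100, 100, 100])
        assert res.z == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_increasing_proportions_positive_significant(self):
        res = cochran_armitage_trend([10, 20, 30, 40], [100, 100, 100, 100])
        assert res.z > 0 and res.direction == 1
        assert res.pvalue < 0.05

    def test_reversing_order_flips_sign(self):
        a = cochran_armitage_trend([10, 20, 30, 40], [100] * 4)
        b = cochran_armitage_trend([40, 30, 20, 10], [100] * 4)
        assert b.z == pytest.approx(-a.z)
        assert b.pvalue == pytest.approx(a.pvalue)

    def test_all_zero_outcome_rejected(self):
        with pytest.raises(ValueError):
            cochran_armitage_trend([0, 0, 0], [10, 10, 10])

    def test_agrees_with_permutation_oracle(self):
        """Two-sided normal p within Monte-Carlo error of a 1e5-permutation
        null on a moderate 4-group table."""
        successes = [10, 13, 15, 18]
        totals = [50, 50, 50, 50]
        mine = cochran_armitage_trend(successes, totals)
        outcomes = np.concatenate(
            [np.r_[np.ones(s), np.zeros(t - s)] for s, t in zip(successes, totals)]
        )
        scores = np.repeat([1.0, 2.0, 3.0, 4.0], totals)
        rng = np.random.default_rng(1)
        perms = rng.permuted(np.tile(outcomes, (100_000, 1)), axis=1)
        # the permutation distribution of the numerator determines |Z|
        num = perms @ scores
        obs = outcomes @ scores
        center = outcomes.mean() * scores.sum()
        p_perm = (np.abs(num - center) >= abs(obs - center) - 1e-9).mean()
        assert mine.pvalue == pytest.approx(p_perm, abs=0.02)


class TestWelchAnova:
    def test_identical_means_give_zero_f(self):
        groups = [[4.0, 5.0, 6.0], [3.0, 5.0, 7.0], [1.0, 5.0, 9.0]]
        res = welch_anova(groups)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_two_groups_equal_welch_t_squared(self):
        rng = np.random.default_rng(2)
        g = [rng.gamma(2, 50, 30), rng.gamma(3, 40, 25)]
        res = welch_anova(g)
        t = sps.ttest_ind(g[0], g[1], equal_var=False)
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.pvalue == pytest.approx(t.pvalue, rel=1e-10)
        assert res.df2 == pytest.approx(t.df, rel=1e-10)

    def test_agrees_with_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        sizes = (40, 30, 25, 20)
        groups = [rng.gamma(2, 50, n) for n in sizes]
        mine = welch_anova(groups)
        df = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat(range(4), sizes)}
        )
        ref = pg.welch_anova(data=df, dv="y", between="g").iloc[0]
        assert mine.statistic == pytest.approx(ref["F"], rel=1e-9)
        assert mine.df2 == pytest.approx(ref["ddof2"], rel=1e-9)
        assert mine.pvalue == pytest.approx(ref["p-unc"] if "p-unc" in ref else ref["p_unc"], rel=1e-9)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])

    def test_separated_cost_strata_always_detected(self):
        """Severity strata calibrated to the reference cost table (10%
        scale) yield p < 0.001 in at least 99% of 200 replicates."""
        means = np.array([67.0, 482.0, 1061.0, 2235.0])
        sds = np.array([134.0, 1506.0, 1983.0, 3426.0])
        ns = (1419, 368, 141, 113)
        hits = 0
        for rep in range(200):
            rng = np.random.default_rng(400 + rep)
            gs = [
                rng.gamma((m / s) ** 2, s * s / m, n)
                for m, s, n in zip(means, sds, ns)
            ]
            hits += welch_anova(gs).pvalue < 0.001
        assert hits >= 198


class TestGamesHowell:
    def test_identical_pair_p_near_one(self):
        rng = np.random.default_rng(4)
        base = rng.gamma(2, 50, 60)
        groups = [base, base.copy(), rng.gamma(2, 120, 60)]
        res = games_howell(groups)
        pair = res[(res["group1"] == 1) & (res["group2"] == 2)].iloc[0]
        assert pair["pvalue"] > 0.999
        assert pair["mean_diff"] == pytest.approx(0.0)

    def test_two_groups_reduce_to_welch_t(self):
        rng = np.random.default_rng(5)
        g = [rng.gamma(2, 50, 30), rng.gamma(3, 40, 25)]
        res = games_howell(g).iloc[0]
        t = sps.ttest_ind(g[0], g[1], equal_var=False)
        assert res["q"] == pytest.approx(np.sqrt(2) * abs(t.statistic), rel=1e-10)
        assert res["pvalue"] == pytest.approx(t.pvalue, rel=1e-4)
        assert res["df"] == pytest.approx(t.df, rel=1e-10)

    def test_agrees_with_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        sizes = (40, 30, 25)
        groups = [rng.gamma(2, 50, n) for n in sizes]
        mine = games_howell(groups)
        df = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat(range(3), sizes)}
        )
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        np.testing.assert_allclose(mine["pvalue"], ref["pval"], atol=1e-8)
        np.testing.assert_allclose(mine["df"], ref["df"], rtol=1e-9)

    def test_ci_brackets_difference(self):
        rng = np.random.default_rng(7)
        groups = [rng.gamma(2, 50, 40), rng.gamma(2, 150, 40)]
        res = games_howell(groups).iloc[0]
        assert res["ci_low"] <= res["mean_diff"] <= res["ci_high"]

    def test_all_pairwise_contrasts_detected_at_cohort_scale(self):
        """At the reference cohort's stratum sizes, every pairwise severity
        contrast is significant in each of 20 replicates."""
        means = np.array([67.0, 482.0, 1061.0, 2235.0])
        sds = np.array([134.0, 1506.0, 1983.0, 3426.0])
        ns = (14191, 3680, 1408, 1131)
        for rep in range(20):
            rng = np.random.default_rng(700 + rep)
            gs = [
                rng.gamma((m / s) ** 2, s * s / m, n)
                for m, s, n in zip(means, sds, ns)
            ]
            res = games_howell(gs, method="tabulated")
            assert (res["pvalue"] < 0.05).all()


def test_normality_diagnostics_report_only():
    rng = np.random.default_rng(8)
    groups = [rng.gamma(1, 100, 50), rng.gamma(2, 200, 50)]
    diag = normality_diagnostics(groups)
    assert set(diag["test"]) == {"shapiro", "levene"}
    assert ((diag["pvalue"] >= 0) & (diag["pvalue"] <= 1)).all()
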