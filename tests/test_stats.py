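import numpy as np
import pandas as pd
import pytest

from oracles import hand_mixed_anova
from smx.exceptions import DegenerateInputError, ValidationError
from smx.io_model import GROUP_BVI, GROUP_SIGHTED, CohortTable
from smx.stats import (
    cohens_d_ci,
    collect_pvalues,
    emm_contrasts,
    hc_correct,
    levene_test,
    mixed_anova_2x2,
    mixed_anova_arrays,
    pairwise_tukey,
    pearson_ci,
    reproduce_analysis,
)
from smx.synthetic_data import SynthConfig, gen_cohort


def _table(rows):
    return CohortTable(pd.DataFrame(
        rows, columns=["participant_id", "group", "condition", "dv_name", "value"]))


def _cohort_2x2(groups, y1, y2, dv="pea", conds=("bipedal_ec", "semitandem_ec")):
    rows = []
    for i, (g, a, b) in enumerate(zip(groups, y1, y2)):
        rows.append((f"p{i}", g, conds[0], dv, a))
        rows.append((f"p{i}", g, conds[1], dv, b))
    return _table(rows)


class TestMixedAnova:
    def test_hand_built_four_participant_table(self):
        """F statistics must match an explicit sums-of-squares decomposition
        done by hand on the 8 numbers."""
        y = np.array([  # (group, subject, condition)
            [[4.0, 6.0], [5.0, 9.0]],
            [[2.0, 3.0], [3.0, 4.0]],
        ])
        oracle = hand_mixed_anova(y)
        groups = [GROUP_BVI, GROUP_BVI, GROUP_SIGHTED, GROUP_SIGHTED]
        res = mixed_anova_arrays(np.array(groups),
                                 y[:, :, 0].ravel(), y[:, :, 1].ravel())
        assert res.between.F == pytest.approx(oracle["F_group"], rel=1e-9)
        assert res.within.F == pytest.approx(oracle["F_cond"], rel=1e-9)
        assert res.interaction.F == pytest.approx(oracle["F_inter"], rel=1e-9)
        assert res.between.df_den == 2

    def test_sum_of_squares_decomposition_is_complete(self):
        rng = np.random.default_rng(0)
        y = rng.normal(10, 2, size=(2, 8, 2))
        ss = hand_mixed_anova(y)["ss"]
        parts = ss["group"] + ss["cond"] + ss["inter"] + ss["subj"] + ss["err"]
        assert parts == pytest.approx(ss["total"], rel=1e-9)

    def test_matches_pingouin_on_unbalanced_groups(self):
        import pingouin as pg

        rng = np.random.default_rng(1)
        n1, n2 = 10, 14
        groups = np.array([GROUP_BVI] * n1 + [GROUP_SIGHTED] * n2)
        y1 = rng.normal(10, 3, n1 + n2) + (groups == GROUP_BVI) * 1.5
        y2 = y1 + rng.normal(0.8, 1.2, n1 + n2)
        res = mixed_anova_arrays(groups, y1, y2)
        df = pd.DataFrame({
            "subj": np.tile(np.arange(n1 + n2), 2),
            "group": np.tile(groups, 2),
            "cond": ["c1"] * (n1 + n2) + ["c2"] * (n1 + n2),
            "y": np.r_[y1, y2],
        })
        ref = pg.mixed_anova(df, dv="y", within="cond", between="group",
                             subject="subj").set_index("Source")
        assert res.between.F == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert res.interaction.F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)
        # pingouin weights condition means by group size; the Type III
        # contrast here is unweighted, so only near-agreement is expected
        assert res.within.F == pytest.approx(ref.loc["cond", "F"], rel=0.01)
        # the unweighted contrast itself must match its defining formula
        d1 = (y2 - y1)[groups == GROUP_BVI]
        d2 = (y2 - y1)[groups == GROUP_SIGHTED]
        est = 0.5 * (d1.mean() + d2.mean())
        mse = (np.sum((d1 - d1.mean()) ** 2) + np.sum((d2 - d2.mean()) ** 2)) / (n1 + n2 - 2)
        F_hand = est**2 / (mse * (1 / n1 + 1 / n2) / 4)
        assert res.within.F == pytest.approx(F_hand, rel=1e-9)

    def test_identical_cell_means_give_null_group_effect(self):
        # both groups share cell means; group F reflects only noise-free zero
        groups = np.array([GROUP_BVI] * 3 + [GROUP_SIGHTED] * 3)
        y1 = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y2 = y1 + 1.0
        res = mixed_anova_arrays(groups, y1, y2)
        assert res.between.F == pytest.approx(0.0, abs=1e-9)

    def test_within_effect_power_grows_with_shift(self):
        rng = np.random.default_rng(2)
        groups = np.array([GROUP_BVI] * 14 + [GROUP_SIGHTED] * 14)
        base = rng.normal(0, 1, 28)
        Fs = []
        for delta in (0.0, 0.5, 1.5):
            y2 = base + delta + rng.normal(0, 0.3, 28)
            Fs.append(mixed_anova_arrays(groups, base, y2).within.F)
        assert Fs[0] < Fs[1] < Fs[2]

    def test_group_type_one_error_under_within_effect(self):
        """A pure within-subject shift must not inflate the between-group
        test (Monte-Carlo level check)."""
        rng = np.random.default_rng(3)
        groups = np.array([GROUP_BVI] * 14 + [GROUP_SIGHTED] * 14)
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            subj = rng.normal(0, 1, 28)
            y1 = subj + rng.normal(0, 1, 28)
            y2 = subj + 2.0 + rng.normal(0, 1, 28)
            if mixed_anova_arrays(groups, y1, y2).between.p < 0.05:
                hits += 1
        assert 0.01 <= hits / n_sims <= 0.10

    def test_missing_within_level_lists_participants(self):
        rows = [
            ("a", GROUP_BVI, "bipedal_ec", "pea", 1.0),
            ("a", GROUP_BVI, "semitandem_ec", "pea", 2.0),
            ("b", GROUP_SIGHTED, "bipedal_ec", "pea", 1.5),
        ]
        with pytest.raises(ValidationError, match="b"):
            mixed_anova_2x2(_table(rows), "pea",
                            ("bipedal_ec", "semitandem_ec"))


class TestLevene:
    def test_identical_samples_give_zero_statistic(self):
        W, df, p = levene_test([np.array([1.0, 2.0, 3.0]),
                                np.array([1.0, 2.0, 3.0])])
        assert W == pytest.approx(0.0, abs=1e-12)

    def test_globally_constant_data(self):
        W, df, p = levene_test([np.ones(5), np.ones(7)])
        assert W == 0.0 and p == 1.0

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(4)
        hits = sum(
            levene_test([rng.normal(0, 1, 200), rng.normal(5, 1, 200)])[2] < 0.05
            for _ in range(500)
        )
        assert 0.03 <= hits / 500 <= 0.08

    def test_power_against_fourfold_variance_ratio(self):
        rng = np.random.default_rng(5)
        hits = sum(
            levene_test([rng.normal(0, 1, 50), rng.normal(0, 2, 50)])[2] < 0.05
            for _ in range(200)
        )
        assert hits / 200 >= 0.80

    def test_matches_scipy(self):
        from scipy import stats as sps
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 2, 40)
        W, df, p = levene_test([a, b])
        W_ref, p_ref = sps.levene(a, b, center="mean")
        assert W == pytest.approx(W_ref) and p == pytest.approx(p_ref)


class TestHcCorrection:
    def test_agrees_with_uncorrected_under_homoscedasticity(self):
        rng = np.random.default_rng(7)
        n = 100
        groups = np.array([GROUP_BVI] * n + [GROUP_SIGHTED] * n)
        y1 = rng.normal(10, 2, 2 * n)
        y2 = y1 + rng.normal(1, 1, 2 * n)
        plain = mixed_anova_arrays(groups, y1, y2)
        robust = hc_correct(groups, y1, y2)
        assert robust.heteroscedasticity_corrected
        for eff in ("between", "within", "interaction"):
            F0 = getattr(plain, eff).F
            F1 = getattr(robust, eff).F
            assert F1 == pytest.approx(F0, rel=0.15)

    def test_type_one_error_under_group_heteroscedasticity(self):
        """With a 3:1 variance ratio the sandwich-corrected group test stays
        near the nominal level."""
        rng = np.random.default_rng(8)
        n1 = n2 = 14
        groups = np.array([GROUP_BVI] * n1 + [GROUP_SIGHTED] * n2)
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            sd = np.where(groups == GROUP_BVI, 3.0, 1.0)
            subj = rng.normal(0, sd)
            y1 = subj + rng.normal(0, 0.5, n1 + n2)
            y2 = subj + rng.normal(0, 0.5, n1 + n2)
            if hc_correct(groups, y1, y2).between.p < 0.05:
                hits += 1
        assert 0.02 <= hits / n_sims <= 0.09

    def test_two_per_cell_returns_finite_statistics(self):
        groups = np.array([GROUP_BVI] * 2 + [GROUP_SIGHTED] * 2)
        res = hc_correct(groups, np.array([1.0, 2.0, 3.0, 5.0]),
                         np.array([2.0, 2.5, 4.0, 5.5]))
        for eff in res.effects().values():
            assert np.isfinite(eff.F) and 0 <= eff.p <= 1


class TestTukeyContrasts:
    def test_two_levels_adjustment_is_identity(self):
        rng = np.random.default_rng(9)
        table = _cohort_2x2(
            np.array([GROUP_BVI] * 10 + [GROUP_SIGHTED] * 10),
            rng.normal(5, 1, 20), rng.normal(6, 1, 20))
        out = emm_contrasts(table, "pea", ("bipedal_ec", "semitandem_ec"))
        for factor in ("group", "condition"):
            df = out[factor]
            np.testing.assert_allclose(df["p_tukey"], df["p_raw"], atol=1e-9)

    def test_three_levels_matches_statsmodels_tukeyhsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(10)
        values = rng.normal(0, 1, 60)
        labels = np.repeat(["a", "b", "c"], 20)
        mine = pairwise_tukey(values, labels)
        ref = pairwise_tukeyhsd(values, labels)
        np.testing.assert_allclose(
            np.sort(mine["p_tukey"].to_numpy()),
            np.sort(np.asarray(ref.pvalues, dtype=float)), atol=1e-6)

    def test_three_levels_adjusted_p_exceeds_raw(self):
        rng = np.random.default_rng(11)
        values = rng.normal(0, 1, 45)
        labels = np.repeat(["a", "b", "c"], 15)
        df = pairwise_tukey(values, labels)
        assert (df["p_tukey"] >= df["p_raw"] - 1e-12).all()
        assert (df["p_tukey"] > df["p_raw"]).any()

    def test_contrast_estimate_is_cell_mean_difference(self):
        values = np.array([1.0, 2.0, 5.0, 7.0])
        labels = np.array(["a", "a", "b", "b"])
        df = pairwise_tukey(values, labels)
        assert df.loc[0, "estimate"] == pytest.approx(1.5 - 6.0)


class TestCohensD:
    def test_hand_example(self):
        d, ci = cohens_d_ci([0.0, 1.0], [1.0, 2.0])
        assert d == pytest.approx(-1.0 / np.sqrt(0.5), rel=1e-9)
        assert ci[0] < d < ci[1]

    def test_identical_samples_give_symmetric_ci_about_zero(self):
        d, ci = cohens_d_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert ci[0] == pytest.approx(-ci[1], rel=1e-6)

    def test_antisymmetry(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 25)
        d_ab, _ = cohens_d_ci(a, b)
        d_ba, _ = cohens_d_ci(b, a)
        assert d_ab == -d_ba

    def test_consistency_at_large_n(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.8, 1.0, 1000)
        b = rng.normal(0.0, 1.0, 1000)
        d, ci = cohens_d_ci(a, b)
        assert 0.7 <= d <= 0.9
        assert ci[0] <= 0.8 <= ci[1]

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(DegenerateInputError):
            cohens_d_ci([1.0, 1.0], [2.0, 2.0])


class TestPearson:
    def test_perfect_linearity(self):
        res = pearson_ci(np.arange(10.0), 2 * np.arange(10.0) + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_three_point_hand_example(self):
        res = pearson_ci([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert res.r == pytest.approx(3.0 / np.sqrt(2 * 14 / 3), rel=1e-9)
        assert res.df == 1

    def test_ci_coverage_calibration(self):
        rng = np.random.default_rng(14)
        rho, n, hits = 0.6, 50, 0
        n_sims = 500
        cov = np.array([[1, rho], [rho, 1]])
        for _ in range(n_sims):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            lo, hi = pearson_ci(xy[:, 0], xy[:, 1]).ci_95
            hits += lo <= rho <= hi
        assert 0.92 <= hits / n_sims <= 0.98

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
        base = pearson_ci(x, y)
        assert pearson_ci(3 * x + 2, 0.5 * y - 7).r == pytest.approx(base.r)
        assert pearson_ci(-x, y).r == pytest.approx(-base.r)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_ci(np.ones(10), np.arange(10.0))


class TestReproduceAnalysis:
    def test_empty_cohort_yields_warnings_only(self):
        report = reproduce_analysis(CohortTable(pd.DataFrame(
            columns=["participant_id", "group", "condition", "dv_name", "value"])))
        assert report["group_comparisons"] == {}
        assert report["warnings"]

    def test_selective_effect_recovery(self):
        """A cohort generated with a group effect on sway only should flag
        the sway comparison and not the gait comparisons."""
        cfg = SynthConfig.null(n_per_group=50, seed=20)
        cfg.dv_params["pea_bipedal_ec"].group_offset = 7.0
        cfg.dv_params["pea_semitandem_ec"].group_offset = 7.0
        cohort, _, _ = gen_cohort(cfg, level="dv")
        report = reproduce_analysis(cohort)
        assert report["group_comparisons"]["pea"].between.p < 0.01
        assert report["group_comparisons"]["stride_time_sd"].between.p > 0.01
        assert report["group_comparisons"]["lle"].between.p > 0.01

    def test_missing_dv_is_warned_not_fatal(self):
        cohort, _, _ = gen_cohort(SynthConfig(n_per_group=6, seed=21), level="dv")
        dropped = CohortTable(
            cohort.data[cohort.data["dv_name"] != "sls_time"].copy())
        report = reproduce_analysis(dropped)
        assert any("sls_time" in w for w in report["warnings"])
        assert "pea" in report["group_comparisons"]

    def test_collect_pvalues_counts_all_tests(self):
        cohort, _, _ = gen_cohort(SynthConfig(n_per_group=8, seed=22), level="dv")
        report = reproduce_analysis(cohort)
        ps = collect_pvalues(report)
        assert len(ps) > 20
        assert all(0 <= p <= 1 for p in ps)
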