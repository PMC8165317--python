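"""Cohort CNV statistics: summaries on the survey data, inference oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from ribocnv.datasets import load_qpcr_cohort, load_read_mapping_survey
from ribocnv.stats import (
    fold_variation,
    foreign_fraction_summary,
    lineage_summary,
    ols_regression,
    one_way_anova,
    pairwise_comparisons_mc,
    simulate_studentized_range,
    studentized_range_critical,
    two_way_anova,
)


@pytest.fixture(scope="module")
def cohort():
    return load_qpcr_cohort()


class TestDatasets:
    def test_cohort_shape_and_missingness(self, cohort):
        assert len(cohort) == 23
        # "n.d." parses to missing, never zero
        assert cohort["setaria_cn"].notna().sum() == 4
        assert (cohort["native_cn"] > 0).all()
        assert set(cohort["clade"]) == {"H", "I-American", "I-Eurasian", "Xa", "Xu"}

    def test_survey_table_loads(self):
        survey = load_read_mapping_survey()
        assert len(survey) == 10
        assert survey["m_mapped"].le(survey["n_reads"]).all()


class TestLineageSummary:
    def test_eurasian_mean_from_taxon_means(self, cohort):
        summary = lineage_summary(cohort).set_index("lineage")
        assert summary.loc["I-Eurasian", "mean_cn"] == 10229

    def test_american_fold_variation(self, cohort):
        summary = lineage_summary(cohort).set_index("lineage")
        assert summary.loc["I-American", "fold_variation"] == 13.2

    def test_h_lineage_subspecies_factor(self, cohort):
        summary = lineage_summary(cohort).set_index("lineage")
        assert summary.loc["H", "fold_variation"] == 1.1

    def test_single_member_group(self):
        df = pd.DataFrame({"clade": ["a", "b", "b"], "taxon": ["t1", "t2", "t3"],
                           "native_cn": [100.0, 200.0, 400.0]})
        out = lineage_summary(df).set_index("lineage")
        assert out.loc["a", "fold_variation"] == 1.0
        assert np.isnan(out.loc["a", "sd_cn"])
        assert out.loc["b", "fold_variation"] == 2.0

    def test_individual_level_vs_taxon_means(self):
        df = pd.DataFrame(
            {"clade": ["a"] * 3, "taxon": ["t1", "t1", "t2"], "native_cn": [100.0, 300.0, 200.0]}
        )
        taxa = lineage_summary(df, level="taxon-means")
        indiv = lineage_summary(df, level="individuals")
        assert taxa.loc[0, "mean_cn"] == 200 and indiv.loc[0, "mean_cn"] == 200
        assert taxa.loc[0, "fold_variation"] == 1.0  # taxon means: 200 vs 200
        assert indiv.loc[0, "fold_variation"] == 3.0

    def test_missing_values_excluded_not_zero_filled(self):
        df = pd.DataFrame({"clade": ["a", "a"], "taxon": ["t1", "t2"],
                           "native_cn": [100.0, np.nan]})
        out = lineage_summary(df)
        assert out.loc[0, "mean_cn"] == 100  # a zero-filled mean would be 50


class TestFoldVariation:
    def test_survey_extremes_almost_19_fold(self, cohort):
        fold = fold_variation(cohort["native_cn"])
        assert round(fold, 1) == 18.6
        assert fold <= 19

    def test_cultivar_fold_from_read_mapping(self):
        survey = load_read_mapping_survey()
        cultivars = survey[survey["sample"].str.contains("cv.")]["copy_number"]
        assert len(cultivars) == 4
        assert round(fold_variation(cultivars), 2) == 2.21

    def test_identical_values_give_unity(self):
        assert fold_variation([7.0, 7.0, 7.0]) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_variation([1.0, 0.0])


class TestForeignFractions:
    def test_survey_fraction_means(self, cohort):
        out = foreign_fraction_summary(cohort).set_index("ribotype")
        assert out.loc["setaria", "mean_fraction_pct"] == 0.1
        assert out.loc["euclasta", "mean_fraction_pct"] == 1.9
        assert out.loc["euclasta", "n_detected"] == 9

    def test_fraction_is_100_when_foreign_equals_native(self):
        df = pd.DataFrame({"native_cn": [500.0], "euclasta_cn": [500.0]})
        out = foreign_fraction_summary(df, ribotypes=["euclasta"])
        assert out.loc[0, "mean_fraction_pct"] == 100.0

    def test_missing_detections_excluded(self):
        df = pd.DataFrame({"native_cn": [100.0, 100.0], "setaria_cn": [10.0, np.nan]})
        out = foreign_fraction_summary(df, ribotypes=["setaria"])
        assert out.loc[0, "mean_fraction_pct"] == 10.0  # zero-filling would give 5.0
        assert out.loc[0, "n_detected"] == 1

    def test_never_detected_ribotype_omitted_with_note(self):
        df = pd.DataFrame({"native_cn": [100.0], "setaria_cn": [np.nan]})
        with pytest.warns(UserWarning, match="never detected"):
            out = foreign_fraction_summary(df, ribotypes=["setaria"])
        assert out.empty

    def test_total_denominator_option(self):
        df = pd.DataFrame({"native_cn": [90.0], "euclasta_cn": [10.0]})
        out = foreign_fraction_summary(df, ribotypes=["euclasta"], denominator="native_plus_foreign")
        assert out.loc[0, "mean_fraction_pct_raw"] == pytest.approx(10.0)


class TestRegression:
    def test_exact_linear_relation(self):
        x = np.arange(5.0)
        reg = ols_regression(x, 2 * x)
        assert reg.slope == pytest.approx(2.0)
        assert reg.r_squared == pytest.approx(1.0)
        assert reg.adjusted_r_squared == pytest.approx(1.0)

    def test_four_point_hand_computed_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 9.0])
        # closed forms: b1 = Sxy/Sxx, b0 = ybar - b1 xbar, r2 = 1 - SSE/SST
        sxx = ((x - x.mean()) ** 2).sum()
        b1 = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        b0 = y.mean() - b1 * x.mean()
        sse = ((y - b0 - b1 * x) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        r2 = 1 - sse / sst
        adj = 1 - (1 - r2) * 3 / 2
        t = b1 / np.sqrt(sse / 2 / sxx)
        p = 2 * scipy.stats.t.sf(abs(t), 2)
        reg = ols_regression(x, y)
        assert reg.slope == pytest.approx(b1)
        assert reg.intercept == pytest.approx(b0)
        assert reg.r_squared == pytest.approx(r2)
        assert reg.adjusted_r_squared == pytest.approx(adj)
        assert reg.p_value == pytest.approx(p)

    def test_null_data_has_small_adjusted_r2(self):
        rng = np.random.default_rng(0)
        reg = ols_regression(rng.normal(size=500), rng.normal(size=500))
        assert abs(reg.adjusted_r_squared) < 0.02
        assert reg.adjusted_r_squared <= reg.r_squared

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ols_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_methods_agreement_on_survey_overlap(self, cohort):
        # qPCR vs read-mapping estimates for the shared accessions correlate
        survey = load_read_mapping_survey()
        pairs = {
            "H. murinum subsp. glaucum BCC2017": "H. murinum subsp. glaucum",
            "H. marinum BCC2001": "H. marinum",
            "H. gussoneanum BCC2012": "H. gussoneanum",
            "H. bogdanii BCC2063": "H. bogdanii",
            "H. pubiflorum BCC2028": "H. pubiflorum",
            "H. vulgare subsp. spontaneum": "H. vulgare subsp. spontaneum",
        }
        sub = survey.set_index("sample").loc[list(pairs)]
        qpcr = cohort.set_index("taxon").loc[[pairs[s] for s in pairs], "native_cn"]
        reg = ols_regression(sub["copy_number"].to_numpy(float), qpcr.to_numpy(float))
        assert reg.slope > 0 and reg.r_squared > 0.3


class TestAnova:
    def test_identical_constant_groups_give_zero_f(self):
        f, p = one_way_anova([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert f == 0.0 and p == 1.0

    def test_two_equal_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=8)
        f, p_f = one_way_anova([a, b])
        t, p_t = scipy.stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_brute_force_sums_of_squares_oracle(self):
        groups = [[3.0, 5.0, 7.0], [6.0, 8.0], [10.0, 12.0, 14.0]]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        k, n = 3, allv.size
        f_hand = (ssb / (k - 1)) / (ssw / (n - k))
        p_hand = scipy.stats.f.sf(f_hand, k - 1, n - k)
        f, p = one_way_anova(groups)
        assert f == pytest.approx(f_hand)
        assert p == pytest.approx(p_hand)

    def test_f_invariant_under_constant_shift(self):
        groups = [[1.0, 2.0, 4.0], [3.0, 5.0], [2.0, 8.0, 9.0]]
        shifted = [[v + 1000.0 for v in g] for g in groups]
        assert one_way_anova(groups)[0] == pytest.approx(one_way_anova(shifted)[0])

    def test_empty_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            f, _ = one_way_anova([[1.0, 2.0], [], [3.0, 4.0]])
        assert np.isfinite(f)

    def test_two_way_anova_balanced_hand_oracle(self):
        # 2x2 balanced design, 2 replicates per cell: classical SS formulas
        df = pd.DataFrame(
            {
                "y": [3.0, 5.0, 7.0, 9.0, 6.0, 8.0, 4.0, 6.0],
                "a": ["a1"] * 4 + ["a2"] * 4,
                "b": ["b1", "b1", "b2", "b2"] * 2,
            }
        )
        out = two_way_anova(df, "y", "a", "b")
        grand = df["y"].mean()
        ss_a = sum(4 * (df[df["a"] == lv]["y"].mean() - grand) ** 2 for lv in ("a1", "a2"))
        ss_b = sum(4 * (df[df["b"] == lv]["y"].mean() - grand) ** 2 for lv in ("b1", "b2"))
        assert out.loc["C(a)", "sum_sq"] == pytest.approx(ss_a)
        assert out.loc["C(b)", "sum_sq"] == pytest.approx(ss_b)
        assert "C(a):C(b)" in out.index


class TestPairwiseComparisons:
    def test_identical_groups_adjusted_p_near_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=6)
        groups = [base + 0.0, base + 0.0, base + 0.0]
        p = pairwise_comparisons_mc(groups, seed=0)
        off_diag = p.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off_diag > 0.99).all()
        assert np.allclose(np.diag(p.to_numpy()), 1.0)
        assert np.allclose(p.to_numpy(), p.to_numpy().T)

    def test_large_shift_detected_others_not(self):
        rng = np.random.default_rng(2)
        g1, g2 = rng.normal(size=8), rng.normal(size=8)
        pooled_sd = np.sqrt((np.var(g1, ddof=1) + np.var(g2, ddof=1)) / 2)
        g3 = rng.normal(10 * pooled_sd, 1.0, size=8)
        p = pairwise_comparisons_mc([g1, g2, g3], seed=3, labels=["a", "b", "c"])
        assert p.loc["a", "c"] < 0.001 and p.loc["b", "c"] < 0.001
        assert p.loc["a", "b"] > 0.05

    def test_critical_value_matches_published_table(self):
        # studentized range upper 5% point q(0.05; k=3, df=12) = 3.773
        q = studentized_range_critical(3, 12, alpha=0.05, n_draws=400_000, seed=7)
        assert q == pytest.approx(3.773, rel=0.02)

    def test_null_draw_validation(self):
        with pytest.raises(ValueError):
            simulate_studentized_range(1, 10, 100)
        with pytest.raises(ValueError):
            pairwise_comparisons_mc([[1.0, 2.0], [2.0, 3.0]], n_draws=100)

    def test_survey_native_cn_by_clade_runs(self, cohort):
        groups = [g["native_cn"].to_numpy(float) for _, g in cohort.groupby("clade")]
        f, p_val = one_way_anova(groups)
        pmat = pairwise_comparisons_mc(groups, seed=11, n_draws=20_000)
        assert pmat.shape == (5, 5)
        assert np.isfinite(f)
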