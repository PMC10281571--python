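"""Fisher's exact test, pooled t-tests, outlier exclusion, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from garules import (
    exclude_outliers,
    fisher_exact_2x2,
    fisher_exact_2x2_exact,
    summarize_groups,
    two_sample_t,
    two_sample_t_summary,
    verification_compare,
)

from oracles import fisher_two_sided, permutation_t_pvalue


class TestFisherExact:
    def test_optic_nerve_table(self):
        # 26/66 favourable vs 2/27 unfavourable
        assert round(fisher_exact_2x2(26, 40, 2, 25), 3) == 0.002

    def test_bladder_bowel_table(self):
        # 1/88 favourable vs 5/41 unfavourable
        assert round(fisher_exact_2x2(1, 87, 5, 36), 2) == 0.01

    def test_identical_proportions(self):
        assert fisher_exact_2x2(0, 10, 0, 10) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_invariant_under_row_and_column_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact_2x2(a, b, c, d)
            assert fisher_exact_2x2(d, c, b, a) == pytest.approx(p, rel=1e-12)
            assert fisher_exact_2x2(b, a, d, c) == pytest.approx(p, rel=1e-12)

    def test_matches_rational_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 50, 4))
            if a + b + c + d == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d) == float(fisher_two_sided(a, b, c, d))
            assert fisher_exact_2x2_exact(a, b, c, d) == fisher_two_sided(a, b, c, d)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            if a + b + c + d == 0:
                continue
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(ref, rel=1e-7)

    def test_p_values_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact_2x2(a, b, c, d)
            assert 0 < p <= 1


class TestTwoSampleT:
    def test_age_comparison_from_summaries(self):
        res = two_sample_t_summary(41.9, 9.9, 67, 44.2, 9.8, 27)
        assert res.df == 92
        assert round(res.p_value, 2) == 0.31

    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_variance_conventions(self):
        assert two_sample_t_summary(5, 0, 3, 5, 0, 3).p_value == 1.0
        with pytest.raises(ValueError):
            two_sample_t_summary(5, 0, 3, 6, 0, 3)

    def test_summary_form_matches_raw_form(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.normal(0, 1, int(rng.integers(3, 30)))
            y = rng.normal(0.5, 1.5, int(rng.integers(3, 30)))
            raw = two_sample_t(x, y)
            summ = two_sample_t_summary(
                x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
            )
            assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
            assert raw.p_value == pytest.approx(summ.p_value, abs=1e-12)

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 15), rng.normal(0.8, 1, 12)
        res = two_sample_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0.0, 1.0, 25)
        y = rng.normal(0.5, 1.0, 25)
        p_t = two_sample_t(x, y).p_value
        p_perm = permutation_t_pvalue(x, y, n_perm=100_000, seed=0)
        assert p_t == pytest.approx(p_perm, abs=0.02)


class TestExcludeOutliers:
    def test_single_extreme_value(self):
        kept, report = exclude_outliers([1, 2, 3, 4, 100])
        assert kept == [1, 2, 3, 4]
        assert report.excluded_indices == (4,)
        assert report.n_excluded == 1

    def test_no_extremes_is_identity(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        kept, report = exclude_outliers(vals)
        assert kept == vals and report.n_excluded == 0

    def test_order_preserved(self):
        kept, _ = exclude_outliers([5, 100, 1, 3, 4, 2])
        assert kept == [5, 1, 3, 4, 2]

    def test_methods_agree_on_planted_extremes(self):
        # one planted 8-sigma outlier per n=20 Gaussian sample; a second
        # one in the same sample would inflate the sd enough to mask
        # both from the z-score rule, so the outliers sit in separate
        # samples (as they would in separate patient groups)
        rng = np.random.default_rng(7)
        for sign in (+1, -1):
            vals = list(rng.normal(0, 1, 19)) + [sign * 8.0]
            _, tukey = exclude_outliers(vals, "tukey_fence", 1.5)
            _, z = exclude_outliers(vals, "z_score", 3.0)
            assert set(tukey.excluded_indices) == set(z.excluded_indices) == {19}

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            exclude_outliers([1.0, 2.0, 3.0])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            exclude_outliers([1, 2, 3, 4, 5], "grubbs")


class TestSummarizeGroups:
    def _cohort(self):
        # 66 favourable / 27 unfavourable with 5 vs 7 flag carriers, plus
        # a continuous variable with a mild shift
        rng = np.random.default_rng(8)
        n_f, n_u = 66, 27
        course = ["favourable"] * n_f + ["unfavourable"] * n_u
        flag = [1] * 5 + [0] * (n_f - 5) + [1] * 7 + [0] * (n_u - 7)
        age = np.concatenate([rng.normal(42, 10, n_f), rng.normal(44, 10, n_u)])
        return pd.DataFrame(
            {"course": course, "cerebral_high_load": flag, "age": np.round(age, 1)},
            index=[f"P{i:03d}" for i in range(n_f + n_u)],
        )

    def test_flag_counts_and_percentages(self):
        summary = summarize_groups(self._cohort(), ["cerebral_high_load"])[0]
        assert summary.test == "fisher_exact"
        assert summary.group_stats["favourable"] == {"count": 5, "denominator": 66}
        assert summary.group_stats["unfavourable"] == {"count": 7, "denominator": 27}
        assert summary.percent("favourable") == 7.6
        assert summary.percent("unfavourable") == 25.9
        assert summary.p_value == pytest.approx(fisher_exact_2x2(5, 61, 7, 20))

    def test_continuous_variable_uses_pooled_t(self):
        cohort = self._cohort()
        summary = summarize_groups(cohort, ["age"])[0]
        x = cohort.loc[cohort.course == "favourable", "age"]
        y = cohort.loc[cohort.course == "unfavourable", "age"]
        assert summary.test == "t_test"
        assert summary.p_value == pytest.approx(two_sample_t(x, y).p_value)
        assert summary.group_stats["favourable"]["n"] == 66

    def test_denominators_follow_missingness(self):
        cohort = self._cohort()
        cohort.loc[cohort.index[:2], "cerebral_high_load"] = np.nan
        summary = summarize_groups(cohort, ["cerebral_high_load"])[0]
        assert summary.group_stats["favourable"]["denominator"] == 64

    def test_absent_variable_rejected(self):
        with pytest.raises(ValueError, match="edss"):
            summarize_groups(self._cohort(), ["edss"])

    def test_reconstructed_counts_match(self):
        for summary in summarize_groups(self._cohort(), ["cerebral_high_load"]):
            for g, gs in summary.group_stats.items():
                pct = summary.percent(g)
                assert round(pct * gs["denominator"] / 100) == gs["count"]


class TestVerificationCompare:
    def _table(self, shift=0.0, outliers=()):
        rng = np.random.default_rng(9)
        fav = rng.normal(10, 2, 20)
        unf = rng.normal(10 + shift, 2, 20)
        for i in outliers:
            fav[i] += 16.0  # 8 sd displacement
        return pd.DataFrame(
            {"group": ["favourable"] * 20 + ["unfavourable"] * 20,
             "HP": np.concatenate([fav, unf])},
            index=[f"V{i:03d}" for i in range(40)],
        )

    def test_masked_difference_revealed_by_exclusion(self):
        # a real shift hidden by two extreme favourable-group values
        table = self._table(shift=2.5, outliers=(0, 1))
        res = verification_compare(table, "HP", exclude=True)
        assert res.p_all > 0.05
        assert res.p_excluded < 0.05
        assert res.n_excluded == 2

    def test_no_outliers_identical_results(self):
        table = self._table(shift=1.0)
        res = verification_compare(table, "HP", exclude=True)
        assert res.n_excluded == 0
        assert res.p_excluded == pytest.approx(res.p_all)

    def test_unknown_protein_rejected(self):
        with pytest.raises(ValueError, match="A2M"):
            verification_compare(self._table(), "A2M")
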