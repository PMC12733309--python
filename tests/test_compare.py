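"""Normality routing, summaries, two-group tests and comparison tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from limbrisk import (
    ContingencyTable2x2,
    assess_normality,
    build_comparison_table,
    compare_categorical_2x2,
    compare_continuous,
    summarize_variable,
)
from limbrisk.compare import DegenerateSampleError, mann_whitney_u


class TestNormalityRouting:
    def test_normal_sample_is_gaussian(self):
        rng = np.random.default_rng(11)
        res = assess_normality(rng.standard_normal(500))
        assert res.is_gaussian
        assert res.p_value >= 0.05

    def test_lognormal_sample_is_not_gaussian(self):
        rng = np.random.default_rng(11)
        res = assess_normality(rng.lognormal(0.0, 1.0, 500))
        assert not res.is_gaussian

    def test_matches_reference_ks_implementation(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(2.0, 1.0, 120)
        res = assess_normality(x)
        ref_stat, ref_p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        assert res.statistic == pytest.approx(ref_stat)
        assert res.p_value == pytest.approx(ref_p)

    def test_lilliefors_variant_is_stricter_than_classical(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        classical = assess_normality(x, method="ks")
        lillie = assess_normality(x, method="lilliefors")
        assert lillie.p_value <= classical.p_value + 0.5  # both defined, same stat family
        assert lillie.statistic == pytest.approx(classical.statistic, rel=1e-6)

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            assess_normality([2.0] * 10)


class TestSummaries:
    def test_gaussian_summary_mean_sd(self):
        assert summarize_variable([1, 2, 3, 4, 5], True) == "3.00 ± 1.58"

    def test_nongaussian_summary_median_iqr_width(self):
        # linear-interpolation quartiles: Q1=2, Q3=4, IQR width 2
        assert summarize_variable([1, 2, 3, 4, 5], False) == "3.00 (2.00)"

    def test_weighted_average_quartile_convention(self):
        s = summarize_variable([1, 2, 3, 4, 5], False,
                               quartile_method="weighted_average")
        assert s == "3.00 (3.00)"  # (n+1)-based: Q1=1.5, Q3=4.5

    def test_single_observation_reports_zero_sd(self):
        assert summarize_variable([7], True) == "7.00 ± 0.00"

    def test_empty_sample_errors(self):
        with pytest.raises(DegenerateSampleError):
            summarize_variable([], True)


def _brute_force_mwu_p(a, b):
    """Two-sided exact Mann-Whitney p by direct pair counting over every
    reassignment of the pooled values to the two groups."""
    pooled = list(a) + list(b)
    n_a = len(a)
    idx = range(len(pooled))

    def u_stat(group_a_idx):
        ga = [pooled[i] for i in group_a_idx]
        gb = [pooled[i] for i in idx if i not in set(group_a_idx)]
        u = 0.0
        for x in ga:
            for y in gb:
                u += (x > y) + 0.5 * (x == y)
        return u

    mean_u = n_a * (len(pooled) - n_a) / 2.0
    obs = abs(u_stat(tuple(range(n_a))) - mean_u)
    combos = list(itertools.combinations(idx, n_a))
    hits = sum(1 for c in combos if abs(u_stat(c) - mean_u) >= obs - 1e-12)
    return hits / len(combos)


class TestCompareContinuous:
    def test_identical_samples_give_p_one(self):
        a = list(range(1, 11))
        res = compare_continuous(a, a)
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(50)
        res = compare_continuous(a, a + 5.0)
        assert res.p_value < 1e-6

    def test_small_sample_exact_enumeration_example(self):
        res = compare_continuous([1, 2, 3], [4, 5, 6])
        assert res.test_used == "mann_whitney_u"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 rank assignments

    @pytest.mark.parametrize("n_a, n_b", [(2, 2), (3, 3), (4, 5), (6, 6), (5, 7)])
    def test_exact_p_matches_brute_force_including_ties(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 100 + n_b)
        for _ in range(10):
            a = rng.integers(0, 6, n_a).astype(float)  # many ties
            b = rng.integers(0, 6, n_b).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(_brute_force_mwu_p(a, b))

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(9)
        a, b = rng.standard_normal(40), rng.standard_normal(40) + 0.5
        r1 = compare_continuous(a, b)
        r2 = compare_continuous(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        if r1.test_used == "student_t":
            assert r1.statistic == pytest.approx(-r2.statistic)

    def test_gaussian_pair_routes_to_t_and_matches_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 80)
        b = rng.normal(0.3, 1, 80)
        res = compare_continuous(a, b)
        assert res.test_used == "student_t"
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert "±" in res.summaries[0]

    def test_skewed_pair_routes_to_mwu_and_matches_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.lognormal(0, 1, 80)
        b = rng.lognormal(0.3, 1, 80)
        res = compare_continuous(a, b)
        assert res.test_used == "mann_whitney_u"
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue)
        assert "(" in res.summaries[0]

    def test_degenerate_group_named_in_error(self):
        with pytest.raises(DegenerateSampleError, match="group_b"):
            compare_continuous([1.0, 2.0, 3.0], [5.0])


class TestChiSquare:
    def test_gender_pad_table_reproduces_published_p(self):
        res = compare_categorical_2x2(
            ContingencyTable2x2(((18, 10), (42, 40))))
        assert res.p_value == pytest.approx(0.231, abs=1e-3)
        assert res.test_used == "chi_square"

    def test_gender_dpn_table_reproduces_published_p(self):
        res = compare_categorical_2x2(
            ContingencyTable2x2(((10, 8), (50, 42))))
        assert res.p_value == pytest.approx(0.925, abs=1e-3)

    def test_identical_proportions_give_statistic_zero(self):
        res = compare_categorical_2x2(
            ContingencyTable2x2(((10, 10), (20, 20))))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_formula_on_exhaustive_small_tables(self):
        """Pearson X^2 = sum (O-E)^2/E over every 2x2 table with cells 0..5."""
        checked = 0
        for a, b, c, d in itertools.product(range(6), repeat=4):
            counts = np.array([[a, b], [c, d]], dtype=float)
            if counts.sum() == 0:
                continue
            if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
                continue
            res = compare_categorical_2x2(
                ContingencyTable2x2(((a, b), (c, d))))
            expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
            x2 = ((counts - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(x2, abs=1e-12)
            assert res.p_value == pytest.approx(stats.chi2.sf(x2, 1))
            checked += 1
        assert checked > 1000

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            compare_categorical_2x2(ContingencyTable2x2(((0, 0), (5, 5))))


class TestComparisonTable:
    def test_demographic_table_shape_and_p_range(self, merged_frame):
        from limbrisk.pipeline import DEMOGRAPHIC_VARIABLES

        table = build_comparison_table(
            merged_frame, "pad_label", DEMOGRAPHIC_VARIABLES)
        assert len(table) == 12
        ok = table[table["test"] != "not computable"]
        assert len(ok) == 12
        assert ((ok["p_value"] >= 0) & (ok["p_value"] <= 1)).all()

    def test_all_missing_variable_flagged_not_computable(self, merged_frame):
        df = merged_frame.copy()
        df["ghost"] = np.nan
        table = build_comparison_table(df, "pad_label", ["ghost", "age"])
        assert table.loc[table.variable == "ghost", "test"].item() == "not computable"
        assert table.loc[table.variable == "age", "test"].item() != "not computable"

    def test_row_order_invariance(self, merged_frame):
        variables = ["age", "fpg", "tyg", "sii", "gender"]
        t1 = build_comparison_table(merged_frame, "dpn_label", variables)
        shuffled = merged_frame.sample(frac=1.0, random_state=3)
        t2 = build_comparison_table(shuffled, "dpn_label", variables)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_outcome_group_errors(self, merged_frame):
        df = merged_frame.copy()
        df["pad_label"] = "positive"
        with pytest.raises(DegenerateSampleError):
            build_comparison_table(df, "pad_label", ["age"])
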