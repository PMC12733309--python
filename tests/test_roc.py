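"""ROC construction, Mann-Whitney AUROC, Hanley-McNeil inference, Youden cut-offs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from limbrisk import (
    auroc_inference,
    auroc_mann_whitney,
    roc_analysis,
    roc_curve,
    youden_optimal_cutoff,
)
from limbrisk.roc import SingleClassError, trapezoidal_area


def _brute_force_auroc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += (p > q) + 0.5 * (p == q)
    return total / (len(pos) * len(neg))


def _brute_force_youden(scores, labels):
    curve = roc_curve(scores, labels)
    best = (-np.inf, None)
    for t, se, sp in zip(curve.thresholds, curve.sensitivity, curve.specificity):
        j = se + sp - 1.0
        if j > best[0] + 1e-15:
            best = (j, (t, se, sp))
    return best[1]


class TestAuroc:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([3, 4], [1, 2], 1.0),      # perfect separation
            ([1, 3], [2, 4], 0.25),     # one concordant pair of four
            ([1, 2], [1, 2], 0.5),      # two ties at half credit
        ],
    )
    def test_worked_examples(self, pos, neg, expected):
        scores = np.array(pos + neg, dtype=float)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        assert auroc_mann_whitney(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            auroc_mann_whitney([1.0, 2.0], [1, 1])

    def test_matches_pairwise_counting_on_random_instances(self):
        """Rank-based AUROC equals brute-force pair counting, 500 instances."""
        rng = np.random.default_rng(123)
        for _ in range(500):
            n = int(rng.integers(4, 51))
            scores = rng.integers(0, 10, n).astype(float)  # heavy ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            assert auroc_mann_whitney(scores, labels) == pytest.approx(
                _brute_force_auroc(scores, labels)
            )

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        scores = rng.normal(size=200)
        labels = (rng.uniform(size=200) < 0.4).astype(int)
        scores[labels == 1] += 0.7
        assert auroc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_score_negation_complements_area(self):
        rng = np.random.default_rng(21)
        scores = rng.normal(size=60)
        labels = (rng.uniform(size=60) < 0.5).astype(int)
        a = auroc_mann_whitney(scores, labels)
        assert auroc_mann_whitney(-scores, labels) == pytest.approx(1.0 - a)

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(22)
        scores = rng.uniform(0.1, 5.0, 80)
        labels = (rng.uniform(size=80) < 0.3).astype(int)
        a = auroc_mann_whitney(scores, labels)
        assert auroc_mann_whitney(np.log(scores), labels) == pytest.approx(a)
        assert auroc_mann_whitney(scores ** 3, labels) == pytest.approx(a)

    def test_equals_trapezoidal_area_under_own_curve(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.normal(size=n), 1)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            area = auroc_mann_whitney(scores, labels)
            assert trapezoidal_area(roc_curve(scores, labels)) == pytest.approx(area)

    def test_binormal_parameter_recovery(self):
        """Scores N(0,1) vs N(1,1) give AUROC near Phi(1/sqrt(2)) ~ 0.7602."""
        rng = np.random.default_rng(1701)
        n = 5000
        scores = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
        labels = np.concatenate([np.zeros(n, int), np.ones(n, int)])
        theory = stats.norm.cdf(1 / math.sqrt(2))
        assert auroc_mann_whitney(scores, labels) == pytest.approx(theory, abs=0.02)


class TestInference:
    def test_null_area_gives_p_one(self):
        inf = auroc_inference(0.5, 40, 40)
        assert inf.p_value == pytest.approx(1.0)

    def test_hanley_mcneil_formula_value(self):
        # closed form check at A=0.813, n+=82, n-=28
        a = 0.813
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        var = (a * (1 - a) + 81 * (q1 - a * a) + 27 * (q2 - a * a)) / (82 * 28)
        inf = auroc_inference(a, 82, 28)
        assert inf.se == pytest.approx(math.sqrt(var))
        assert inf.se == pytest.approx(0.0414, abs=5e-4)
        assert inf.ci95[0] == pytest.approx(a - 1.96 * inf.se)
        assert inf.ci95[1] <= 1.0

    def test_perfect_separation_is_degenerate(self):
        inf = auroc_inference(1.0, 3, 3)
        assert inf.se == 0.0
        assert inf.degenerate

    def test_ci_truncated_to_unit_interval(self):
        inf = auroc_inference(0.98, 5, 5)
        assert 0.0 <= inf.ci95[0] <= inf.ci95[1] <= 1.0


class TestCurveAndYouden:
    def test_midpoint_thresholds_with_sentinels(self):
        curve = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        np.testing.assert_allclose(curve.thresholds, [0.5, 1.5, 2.5, 3.5, 4.5])

    def test_integer_scores_give_half_integer_cutoffs(self):
        rng = np.random.default_rng(12)
        scores = rng.integers(0, 25, 110).astype(float)
        labels = (scores + rng.normal(0, 5, 110) > 12).astype(int)
        curve = roc_curve(scores, labels)
        interior = curve.thresholds[1:-1]
        assert np.allclose(interior % 1.0, 0.5)

    def test_constant_scores_give_diagonal_endpoints(self):
        curve = roc_curve([2.0, 2.0, 2.0], [1, 0, 1])
        assert curve.thresholds.size == 2
        np.testing.assert_allclose(curve.sensitivity, [1.0, 0.0])
        np.testing.assert_allclose(curve.specificity, [0.0, 1.0])

    def test_monotone_sensitivity_specificity(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=70)
        labels = (rng.uniform(size=70) < 0.4).astype(int)
        curve = roc_curve(scores, labels)
        assert np.all(np.diff(curve.sensitivity) <= 0)
        assert np.all(np.diff(curve.specificity) >= 0)
        assert curve.sensitivity[0] == 1.0 and curve.specificity[0] == 0.0
        assert curve.sensitivity[-1] == 0.0 and curve.specificity[-1] == 1.0

    def test_youden_worked_example_tie_broken_low(self):
        scores = np.array([2, 3, 4, 1, 1, 2], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0])
        cutoff, sens, spec = youden_optimal_cutoff(roc_curve(scores, labels))
        assert cutoff == pytest.approx(1.5)
        assert sens == pytest.approx(1.0)
        assert spec == pytest.approx(2 / 3)

    def test_perfect_separation_reaches_j_one(self):
        cutoff, sens, spec = youden_optimal_cutoff(
            roc_curve([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0]))
        assert sens + spec - 1 == pytest.approx(1.0)
        assert cutoff == pytest.approx(4.0)

    def test_youden_matches_exhaustive_scan(self):
        rng = np.random.default_rng(14)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.normal(size=n), 1)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            curve = roc_curve(scores, labels)
            assert youden_optimal_cutoff(curve) == _brute_force_youden(scores, labels)

    def test_direction_flag_for_protective_markers(self):
        scores = np.array([1, 2, 3, 7, 8, 9], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0])  # lower score = diseased
        res = roc_analysis(scores, labels, direction="lower-positive")
        assert res.auroc == pytest.approx(1.0)


@given(st.data())
def test_analysis_auroc_always_in_unit_interval(data):
    n = data.draw(st.integers(4, 30))
    scores = data.draw(
        st.lists(st.integers(0, 8), min_size=n, max_size=n).map(
            lambda v: np.array(v, dtype=float))
    )
    k = data.draw(st.integers(1, n - 1))
    labels = np.zeros(n, dtype=int)
    labels[:k] = 1
    res = roc_analysis(scores, labels)
    assert 0.0 <= res.auroc <= 1.0
    assert 0.0 <= res.p_value <= 1.0
    assert res.cutoff in roc_curve(scores, labels).thresholds
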