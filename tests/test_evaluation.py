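"""Reliability, screening metrics, diagnosis curve, descriptives."""

import numpy as np
import pytest

from catgrm import (
    ResponseMatrix,
    auc_mann_whitney,
    classify_by_criterion,
    diagnosis_curve,
    marginal_reliability,
    optimal_cutpoint,
    response_descriptives,
    roc_table,
    screening_metrics,
)


class TestMarginalReliability:
    def test_constant_se_closed_form(self):
        assert marginal_reliability([0.31] * 5) == pytest.approx(0.9039)
        assert marginal_reliability([0.19] * 5) == pytest.approx(0.9639)

    def test_equals_one_minus_mean_squared_se(self):
        rng = np.random.default_rng(1)
        se = rng.uniform(0.1, 0.6, 200)
        assert marginal_reliability(se) == pytest.approx(1 - np.mean(se**2), abs=1e-12)

    def test_nonpositive_se_rejected_and_negative_value_warns(self):
        with pytest.raises(ValueError):
            marginal_reliability([0.2, 0.0])
        with pytest.warns(RuntimeWarning, match="negative"):
            assert marginal_reliability([1.5]) < 0


class TestClassifyByCriterion:
    def test_cutoff_is_inclusive(self):
        assert classify_by_criterion([75.0], 75)[0] == 1
        assert classify_by_criterion([74.9], 75)[0] == 0

    def test_positive_count_on_synthetic_cohort(self):
        rng = np.random.default_rng(12)
        scores = np.sort(rng.normal(50, 12, 1014))
        cut = scores[-40]  # exactly 40 scores at or above this value
        labels = classify_by_criterion(scores, cut)
        assert labels.sum() == 40 and labels.size - labels.sum() == 974


class TestScreeningMetrics:
    def test_published_style_sensitivity_specificity_youden(self):
        # 10 positives with 9 detected; 40 negatives with 37 correctly negative
        scores = np.r_[np.full(9, 2.0), [0.0], np.full(37, 0.0), np.full(3, 2.0)]
        labels = np.r_[np.ones(10), np.zeros(40)].astype(int)
        m = screening_metrics(scores, labels, cutpoint=1.0)
        assert m.sensitivity == pytest.approx(0.900)
        assert m.specificity == pytest.approx(0.925)
        assert m.youden == pytest.approx(0.825)

    def test_youden_identity_holds_at_every_cutpoint(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=120)
        labels = (scores + rng.normal(scale=1.2, size=120) > 0).astype(int)
        tab = roc_table(scores, labels)
        np.testing.assert_allclose(tab["youden"],
                                   tab["sensitivity"] + tab["specificity"] - 1,
                                   atol=1e-12)

    def test_perfect_separation_gives_auc_one(self):
        m = screening_metrics([0, 1, 2, 10, 11], [0, 0, 0, 1, 1], cutpoint=5)
        assert m.auc == 1.0 and m.youden == 1.0

    def test_toy_pair_counting(self):
        assert auc_mann_whitney([0, 1, 2, 3], [0, 0, 1, 1]) == 1.0
        assert auc_mann_whitney([1, 2, 0, 3], [0, 0, 1, 1]) == 0.5

    def test_auc_matches_sklearn_on_random_sets(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 8, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            screening_metrics([1.0, 2.0], [1, 1], 1.5)


class TestOptimalCutpoint:
    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60)
        labels = (scores + rng.normal(scale=0.8, size=60) > 0.2).astype(int)
        cut, m = optimal_cutpoint(scores, labels)
        brute = max(
            (screening_metrics(scores, labels, c).youden, -c)
            for c in np.unique(scores)
        )
        assert m.youden == pytest.approx(brute[0])
        assert cut == pytest.approx(-brute[1])  # ties resolve to lowest cutpoint

    def test_perfectly_separated_toy_set(self):
        cut, m = optimal_cutpoint([0, 1, 5, 6], [0, 0, 1, 1])
        assert m.youden == 1.0

    def test_degenerate_identical_scores(self):
        cut, m = optimal_cutpoint([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        assert m.youden == pytest.approx(0.0)


class TestDiagnosisCurve:
    def test_generative_recovery_of_logistic_slope(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=5000)
        p = 1 / (1 + np.exp(-(2.0 * x - 3.0)))
        labels = (rng.random(5000) < p).astype(int)
        curve = diagnosis_curve(x, labels)
        assert curve.slope == pytest.approx(2.0, abs=0.2)
        assert curve.score_at_p50 == pytest.approx(-curve.intercept / curve.slope)

    def test_median_score_sits_at_the_50th_percentile(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=501)
        labels = (x + rng.normal(scale=1.0, size=501) > 1).astype(int)
        curve = diagnosis_curve(x, labels)
        assert curve.percentile(np.median(x)) == pytest.approx(50.0, abs=1.0)

    @pytest.mark.filterwarnings("ignore::UserWarning", "ignore:Maximum Likelihood")
    def test_separated_labels_put_p50_inside_the_gap(self):
        x = np.r_[np.linspace(-2, 0, 40), np.linspace(1, 3, 40)]
        labels = np.r_[np.zeros(40), np.ones(40)].astype(int)
        curve = diagnosis_curve(x, labels)
        assert 0.0 < curve.score_at_p50 < 1.0

    def test_cat_criterion_correlation_drops_as_stopping_loosens(self, bank68):
        from catgrm import CATConfig, generate_respondents, run_rule

        respondents = generate_respondents(400, bank68, seed=404)
        rng = np.random.default_rng(405)
        true_theta = np.array([r.true_theta for r in respondents])
        criterion = np.tanh(true_theta) + rng.normal(scale=0.5, size=400)
        corr = {}
        for t in (0.3, 0.5):
            res = run_rule(respondents, bank68, CATConfig(se_threshold=t, seed=1))
            corr[t] = np.corrcoef([r.theta_hat for r in res], criterion)[0, 1]
        assert corr[0.3] > corr[0.5]


class TestResponseDescriptives:
    def test_hand_computed_moments(self):
        rm = ResponseMatrix(np.array([[0.0], [0.0], [1.0], [1.0]]), ["x"])
        row = response_descriptives(rm).iloc[0]
        assert row["mean"] == pytest.approx(0.5)
        assert row["sd"] == pytest.approx(0.57735, abs=1e-5)  # n-1 denominator

    def test_symmetric_codes_have_zero_skewness(self):
        rm = ResponseMatrix(np.array([[0.0], [1.0], [1.0], [2.0]]), ["x"])
        assert response_descriptives(rm).iloc[0]["skewness"] == pytest.approx(0.0)

    def test_constant_column_yields_nan_shape_moments_with_warning(self):
        rm = ResponseMatrix(np.ones((5, 1)), ["x"])
        with pytest.warns(RuntimeWarning, match="constant"):
            row = response_descriptives(rm).iloc[0]
        assert row["sd"] == 0.0
        assert np.isnan(row["skewness"]) and np.isnan(row["kurtosis"])

    def test_excess_kurtosis_convention(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=4000).round(2)[:, None] + 3  # near-normal codes
        x = np.clip(np.round(x), 0, 6)
        rm = ResponseMatrix(x, ["x"])
        assert abs(response_descriptives(rm).iloc[0]["kurtosis"]) < 0.3
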