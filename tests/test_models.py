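"""Model-layer checks: probabilities, likelihoods, information, SE/reliability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catgrm import (
    ItemBank,
    ItemParameters,
    ThetaGrid,
    category_probabilities,
    item_information,
    reliability_from_information,
    response_loglik,
    standard_error_from_information,
)
from catgrm import test_information as total_information


def _random_item(rng, model=None):
    model = model or rng.choice(["GRM", "GPCM", "NRM"])
    m = int(rng.integers(2, 6))
    if model == "GRM":
        b = np.sort(rng.normal(0, 1.5, m - 1))
        b += 1e-3 * np.arange(m - 1)  # guard exact ties
        return ItemParameters("r", "GRM", m, rng.uniform(0.5, 2.5), b)
    if model == "GPCM":
        return ItemParameters("r", "GPCM", m, rng.uniform(0.5, 2.5),
                              rng.normal(0, 1.5, m - 1))
    a = np.concatenate([[0.0], rng.uniform(0.2, 2.0, m - 1)])
    c = np.concatenate([[0.0], rng.normal(0, 1.0, m - 1)])
    return ItemParameters("r", "NRM", m, a, c)


class TestCategoryProbabilities:
    def test_logistic_symmetry_two_categories(self):
        item = ItemParameters("i", "GRM", 2, 1.0, [0.0])
        assert category_probabilities(item, 0.0) == pytest.approx([0.5, 0.5])

    def test_three_category_grm_hand_values(self, grm_item):
        # direct evaluation of the two cumulative logistics and differencing
        p = category_probabilities(grm_item, 0.0)
        assert p == pytest.approx([0.2689, 0.6119, 0.1192], abs=5e-5)

    def test_probabilities_normalize_over_random_items(self):
        rng = np.random.default_rng(11)
        thetas = rng.uniform(-5, 5, 100)
        for _ in range(100):  # 100 items x 100 thetas = 1e4 (item, theta) draws
            item = _random_item(rng)
            P = category_probabilities(item, thetas)
            assert np.all(P >= 0) and np.all(P <= 1)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    @given(theta=st.floats(-6, 6), a=st.floats(0.3, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_grm_cumulative_monotone_in_theta_and_category(self, theta, a):
        from scipy.special import expit

        b = np.array([-1.0, 0.2, 1.5])
        cum_lo = expit(a * (theta - b))
        cum_hi = expit(a * (theta + 1e-3 - b))
        assert np.all(cum_hi > cum_lo)           # increasing in theta
        assert np.all(np.diff(cum_lo) < 0)       # decreasing in category

    def test_invalid_items_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ItemParameters("x", "RASCH", 2, 1.0, [0.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            ItemParameters("x", "GRM", 3, 1.0, [1.0, 0.5])
        with pytest.raises(ValueError, match="discrimination"):
            ItemParameters("x", "GRM", 2, -1.0, [0.0])


class TestResponseLoglik:
    def test_single_item_bottom_category(self):
        item = ItemParameters("i", "GRM", 2, 1.0, [0.0])
        assert response_loglik([0], [item], 0.0) == pytest.approx(np.log(0.5))

    def test_all_missing_contributes_zero(self, grm_item):
        assert response_loglik([np.nan, None], [grm_item, grm_item], 1.3) == 0.0

    def test_additivity_over_items(self, grm_item):
        other = ItemParameters("j", "GRM", 4, 1.2, [-1.0, 0.0, 1.0])
        joint = response_loglik([1, 2], [grm_item, other], 0.4)
        parts = response_loglik([1], [grm_item], 0.4) + response_loglik([2], [other], 0.4)
        assert joint == pytest.approx(parts, abs=1e-12)

    def test_out_of_range_code_names_item(self, grm_item):
        with pytest.raises(ValueError, match="demo"):
            response_loglik([3], [grm_item], 0.0)


class TestInformation:
    def test_tails_vanish(self):
        item = ItemParameters("i", "GRM", 2, 1.0, [0.0])
        assert item_information(item, 8.0) < 1e-3

    @pytest.mark.parametrize("model", ["GRM", "GPCM", "NRM"])
    def test_matches_numerical_derivative_oracle(self, model):
        rng = np.random.default_rng(5)
        h = 1e-5
        for _ in range(20):
            item = _random_item(rng, model)
            for theta in (-2.0, -0.3, 0.0, 1.1, 2.5):
                P = category_probabilities(item, theta)
                dP = (category_probabilities(item, theta + h)
                      - category_probabilities(item, theta - h)) / (2 * h)
                oracle = float((dP**2 / P).sum())
                assert item_information(item, theta) == pytest.approx(oracle, abs=1e-6)

    def test_fixture_bank_information_matches_oracle(self, bank68):
        h = 1e-5
        thetas = np.linspace(-3, 3, 7)
        for item in bank68:
            for theta in thetas:
                P = category_probabilities(item, theta)
                dP = (category_probabilities(item, theta + h)
                      - category_probabilities(item, theta - h)) / (2 * h)
                oracle = float((dP**2 / P).sum())
                assert item_information(item, theta) == pytest.approx(oracle, abs=1e-6)

    def test_higher_discrimination_never_lowers_peak_information(self):
        grid = np.linspace(-4, 4, 161)
        for a in (0.5, 1.0, 1.7):
            lo = ItemBank([ItemParameters("l", "GRM", 3, a, [-0.4, 0.8])])
            hi = ItemBank([ItemParameters("h", "GRM", 3, 2 * a, [-0.4, 0.8])])
            assert hi.information_matrix(grid).max() >= lo.information_matrix(grid).max()

    def test_test_information_is_additive_and_permutation_invariant(self, bank68):
        theta = 0.7
        per_item = sum(item_information(it, theta) for it in bank68)
        assert total_information(bank68, theta) == pytest.approx(per_item, abs=1e-10)
        shuffled = ItemBank(list(reversed(bank68.items)))
        assert total_information(shuffled, theta) == pytest.approx(per_item, abs=1e-10)

    def test_vectorized_bank_information_matches_per_item(self, bank68):
        thetas = np.array([-1.0, 0.0, 2.0])
        mat = bank68.information_matrix(thetas)
        for ti, theta in enumerate(thetas):
            for j, item in enumerate(bank68):
                assert mat[ti, j] == pytest.approx(item_information(item, theta), abs=1e-10)


class TestSEAndReliability:
    def test_se_closed_form(self):
        assert standard_error_from_information(4.0) == pytest.approx(0.5)
        assert standard_error_from_information(11.1111) == pytest.approx(0.3, abs=2e-6)
        with pytest.raises(ValueError, match="non-positive"):
            standard_error_from_information(0.0)

    def test_reliability_closed_form(self):
        assert reliability_from_information(10.0) == pytest.approx(0.9)
        assert reliability_from_information(1.0) == pytest.approx(0.0)
        with pytest.warns(RuntimeWarning):
            assert reliability_from_information(0.5) == pytest.approx(-1.0)

    @given(info=st.floats(0.2, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_reliability_equals_one_minus_se_squared(self, info):
        import warnings

        se = standard_error_from_information(info)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = reliability_from_information(info)
        assert r == pytest.approx(1.0 - se**2, abs=1e-12)


class TestThetaGrid:
    def test_normal_grid_is_valid_and_centered(self):
        grid = ThetaGrid.normal(81)
        assert grid.points.size == 81
        assert grid.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert grid.mean == pytest.approx(0.0, abs=1e-12)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ThetaGrid([0.0, 0.0, 1.0], [0.3, 0.3, 0.4])
        with pytest.raises(ValueError, match="sum to 1"):
            ThetaGrid([0.0, 1.0], [0.7, 0.2])
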