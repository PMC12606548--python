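"""Statistical primitives: beta tails, bimonotone isotonic fit, contour, KM."""

import numpy as np
import pytest
from scipy.optimize import minimize

from greatwall import (
    UtilityScores,
    beta_tail,
    isotonic_2d,
    km_survival,
    mean_utility_estimate,
    mtd_contour,
    true_mean_utility,
)
from greatwall.estimation import below_contour_mask, posterior_mean_toxicity


class TestBetaTail:
    def test_prior_only(self):
        assert beta_tail(0, 0, 0.25) == pytest.approx(0.75)

    def test_all_failures_closed_form(self):
        # Beta(1, l+1) tail beyond t is (1-t)^(l+1)
        assert beta_tail(0, 12, 0.25) == pytest.approx(0.75**13, rel=1e-10)

    @pytest.mark.parametrize("l,t", [(3, 0.25), (10, 0.5), (7, 0.9)])
    def test_all_successes_closed_form(self, l, t):
        assert beta_tail(l, l, t) == pytest.approx(1 - t ** (l + 1), rel=1e-10)

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            beta_tail(1, 2, 1.5)


def qp_isotonic_oracle(values, weights):
    """Projection onto the bimonotone cone by constrained optimization."""
    J, K = values.shape
    cons = []
    for j in range(J):
        for k in range(K):
            if k + 1 < K:
                cons.append((j * K + k, j * K + k + 1))
            if j + 1 < J:
                cons.append((j * K + k, (j + 1) * K + k))
    res = minimize(
        lambda z: np.sum(weights.ravel() * (z - values.ravel()) ** 2),
        values.ravel(),
        jac=lambda z: 2 * weights.ravel() * (z - values.ravel()),
        constraints=[
            {"type": "ineq", "fun": (lambda z, lo=lo, hi=hi: z[hi] - z[lo])}
            for lo, hi in cons
        ],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return res.x.reshape(J, K)


class TestIsotonic2d:
    def test_bimonotone_input_unchanged(self):
        m = np.array([[0.1, 0.2, 0.3], [0.2, 0.25, 0.5]])
        np.testing.assert_allclose(isotonic_2d(m), m, atol=1e-9)

    def test_single_row_matches_1d_pava(self):
        out = isotonic_2d(np.array([[0.3, 0.1]]))
        np.testing.assert_allclose(out, [[0.2, 0.2]], atol=1e-9)

    def test_single_row_matches_sklearn(self):
        from sklearn.isotonic import IsotonicRegression

        rng = np.random.default_rng(7)
        y = rng.uniform(size=(1, 8))
        w = rng.uniform(0.5, 2.0, size=(1, 8))
        ours = isotonic_2d(y, w)[0]
        theirs = IsotonicRegression().fit(
            np.arange(8), y[0], sample_weight=w[0]
        ).predict(np.arange(8))
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_qp_oracle_on_random_3x3(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(size=(3, 3))
        w = rng.uniform(0.5, 3.0, size=(3, 3))
        np.testing.assert_allclose(
            isotonic_2d(y, w), qp_isotonic_oracle(y, w), atol=1e-4
        )

    def test_output_bimonotone_and_within_input_range(self):
        rng = np.random.default_rng(11)
        y = rng.uniform(size=(4, 5))
        out = isotonic_2d(y)
        assert np.all(np.diff(out, axis=0) >= -1e-9)
        assert np.all(np.diff(out, axis=1) >= -1e-9)
        assert out.min() >= y.min() - 1e-9 and out.max() <= y.max() + 1e-9

    def test_preserves_weighted_mean(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(size=(3, 4))
        w = rng.uniform(0.5, 2.0, size=(3, 4))
        out = isotonic_2d(y, w)
        assert np.sum(w * out) == pytest.approx(np.sum(w * y), rel=1e-6)

    def test_masked_cells_stay_nan(self):
        y = np.array([[0.4, np.nan], [0.2, 0.6]])
        out = isotonic_2d(y)
        assert np.isnan(out[0, 1])
        assert out[0, 0] <= out[1, 0] + 1e-9

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError, match="masked"):
            isotonic_2d(np.full((2, 2), np.nan))

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(size=(3, 3))
        once = isotonic_2d(y)
        np.testing.assert_allclose(isotonic_2d(once), once, atol=1e-7)


class TestMtdContour:
    def test_nearest_to_target_in_row(self):
        iso = np.array([[0.10, 0.28, 0.45]])
        assert mtd_contour(iso, 0.3).tolist() == [1]

    def test_excluded_row_contributes_nothing(self):
        iso = np.array([[0.5, 0.6, 0.7]])
        excl = np.array([[True, True, True]])
        assert mtd_contour(iso, 0.3, excluded=excl).tolist() == [-1]

    def test_rho_threshold_limits_eligibility(self):
        iso = np.array([[0.10, 0.44, 0.45]])
        # with the hard threshold, 0.44 and 0.45 >= 0.42 are out
        assert mtd_contour(iso, 0.3, rho=1.4).tolist() == [0]

    def test_equidistant_below_and_above_prefers_lower(self):
        iso = np.array([[0.25, 0.35, 0.6]])
        assert mtd_contour(iso, 0.3).tolist() == [0]

    def test_tied_pooled_estimates_below_target_take_higher_dose(self):
        # isotonic pooling yields exact ties; below target there is room left
        iso = np.array([[0.2, 0.2, 0.2]])
        assert mtd_contour(iso, 0.3).tolist() == [2]

    def test_below_contour_mask_restricted_to_tried(self):
        tried = np.array([[True, True, False], [True, False, False]])
        mask = below_contour_mask(np.array([1, 0]), tried)
        assert mask.tolist() == [[True, True, False], [True, False, False]]


class TestPosteriorMeanToxicity:
    def test_shrinks_with_diffuse_prior_and_masks_untried(self):
        est = posterior_mean_toxicity(np.array([[1, 0]]), np.array([[3, 0]]))
        assert est[0, 0] == pytest.approx(1.05 / 3.1)
        assert np.isnan(est[0, 1])

    def test_raw_mode(self):
        est = posterior_mean_toxicity(np.array([[1]]), np.array([[3]]), prior=None)
        assert est[0, 0] == pytest.approx(1 / 3)


class TestMeanUtility:
    def test_extreme_outcomes(self):
        s = UtilityScores()
        assert mean_utility_estimate(5, 0, 0, 0, s) == 1.0
        assert mean_utility_estimate(0, 0, 0, 5, s) == 0.0

    def test_plug_in_arithmetic(self):
        # (5*100 + 1*60 + 3*40 + 1*0) / (10*100)
        assert mean_utility_estimate(5, 1, 3, 1, UtilityScores()) == pytest.approx(0.68)

    def test_no_data_rejected(self):
        with pytest.raises(ValueError, match="no data"):
            mean_utility_estimate(0, 0, 0, 0, UtilityScores())

    @pytest.mark.parametrize(
        "pe, pt, expected",
        [(0.55, 0.10, 0.69), (0.70, 0.12, 0.77), (0.60, 0.15, 0.70)],
    )
    def test_true_mean_utility_reproduces_printed_values(self, pe, pt, expected):
        assert round(true_mean_utility(pe, pt), 2) == expected

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            UtilityScores(u00=140.0)


class TestKmSurvival:
    def test_all_beyond_landmark(self):
        assert km_survival([8, 9, 10], [1, 1, 1], 6.0) == 1.0

    def test_hand_computed_product_limit(self):
        # events at 2 and 4 before the landmark, one event at 8, censor at 10
        t = [2, 4, 8, 10]
        e = [1, 1, 1, 0]
        assert km_survival(t, e, 6.0) == pytest.approx(0.5)

    def test_no_censoring_equals_empirical_fraction(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(8.0, size=40) + 1e-6
        e = np.ones(40)
        assert km_survival(t, e, 6.0) == pytest.approx(np.mean(t > 6.0))

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(9)
        t = rng.exponential(7.0, size=60) + 1e-6
        e = rng.random(60) < 0.8
        obs = np.minimum(t, 12.0)
        ev = e & (t <= 12.0)
        km = KaplanMeierFitter().fit(obs, ev)
        ours = km_survival(obs, ev, 6.0)
        theirs = float(km.predict(6.0))
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_survival([], [], 6.0)
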