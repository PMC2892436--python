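"""Goodness-of-fit statistics against hand-computed and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sigmofit import (PerfectFitError, aic, aicc, akaike_weights, bic,
                      chi_square, log_lik_gaussian, r_squared, r_squared_adj,
                      reduced_chi_square, residual_variance)


class TestRSquared:
    def test_perfect_fit_gives_one(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r_squared(y, y) == 1.0

    def test_mean_fit_gives_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_hand_example(self):
        # RSS = 0.02, TSS = 2
        assert r_squared([1, 2, 3], [1.1, 2.0, 2.9]) == pytest.approx(0.99)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=30),
           st.integers(0, 10**6))
    def test_agrees_with_brute_force_sums(self, ys, seed):
        y = np.asarray(ys)
        if np.ptp(y) == 0:
            return
        fitted = y + np.random.default_rng(seed).normal(0, 1, y.size)
        rss = sum((yi - fi) ** 2 for yi, fi in zip(y, fitted))
        tss = sum((yi - y.mean()) ** 2 for yi in y)
        assert r_squared(y, fitted) == pytest.approx(1 - rss / tss,
                                                     rel=1e-10, abs=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-5, 1), st.integers(5, 50), st.integers(1, 4))
    def test_adjusted_below_raw_and_matches_formula(self, r2, n, p):
        if n <= p:
            return
        adj = r_squared_adj(r2, n, p)
        assert adj == pytest.approx(1 - (1 - r2) * (n - 1) / (n - p))
        assert adj <= r2 + 1e-12

    def test_adjusted_hand_example(self):
        assert r_squared_adj(0.9, 26, 3) == pytest.approx(1 - 0.1 * 25 / 23)

    def test_single_parameter_leaves_r2_unchanged(self):
        assert r_squared_adj(0.7, 26, 1) == pytest.approx(0.7)

    def test_adjusted_requires_n_greater_p(self):
        with pytest.raises(ValueError):
            r_squared_adj(0.9, 3, 3)


class TestLogLik:
    def test_closed_form_example(self):
        # N = 26, RSS = 0.0026 -> -13*(ln 2pi + ln 1e-4 + 1)
        resid = np.full(26, math.sqrt(0.0026 / 26))
        assert log_lik_gaussian(resid) == pytest.approx(82.8420, abs=5e-4)

    def test_scaling_residuals_shifts_by_n_log_scale(self):
        resid = np.array([0.1, -0.2, 0.3, -0.1])
        low = log_lik_gaussian(resid)
        high = log_lik_gaussian(10 * resid)
        assert low - high == pytest.approx(4 * math.log(10))

    def test_perfect_fit_is_unbounded(self):
        with pytest.raises(PerfectFitError):
            log_lik_gaussian(np.zeros(5))


class TestInformationCriteria:
    LL, K, N = 82.84202297236888, 4, 26

    def test_aic_aicc_bic_arithmetic(self):
        a = aic(self.LL, self.K)
        assert a == pytest.approx(-157.684, abs=5e-4)
        assert aicc(a, self.N, self.K) == pytest.approx(a + 40 / 21)
        assert bic(self.LL, self.N, self.K) == pytest.approx(
            4 * math.log(26) - 2 * self.LL)

    def test_equal_k_reduces_to_likelihood_difference(self):
        a1, a2 = aic(10.0, 3), aic(12.5, 3)
        assert a1 - a2 == pytest.approx(-2 * (10.0 - 12.5))
        assert (aicc(a1, 20, 3) - aicc(a2, 20, 3)) == pytest.approx(a1 - a2)

    def test_correction_vanishes_for_large_n(self):
        a = aic(self.LL, self.K)
        assert aicc(a, 10**9, self.K) == pytest.approx(a, abs=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-100, 100), st.integers(1, 6), st.integers(8, 100))
    def test_aicc_strictly_exceeds_aic(self, ll, k, n):
        a = aic(ll, k)
        assert aicc(a, n, k) > a

    def test_aicc_denominator_guard(self):
        with pytest.raises(ValueError):
            aicc(0.0, 5, 4)


class TestAkaikeWeights:
    def test_equal_values_share_weight(self):
        w = akaike_weights([3.0, 3.0, 3.0])
        np.testing.assert_allclose(w, 1 / 3)

    def test_delta_two_example(self):
        w = akaike_weights([0.0, 2.0])
        np.testing.assert_allclose(w, [0.7310585786, 0.2689414214],
                                   atol=1e-9)

    def test_delta_78_spans_sixteen_orders_of_magnitude(self):
        # the evidence ratio the study highlights for L3 vs B3
        w = akaike_weights([0.0, 78.0])
        assert w[1] < 1e-16
        assert w[0] > 1 - 1e-16

    def test_failed_fits_get_zero_weight(self):
        w = akaike_weights([1.0, np.nan, 3.0])
        assert w[1] == 0.0
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-500, 500), min_size=1, max_size=9),
           st.floats(-1000, 1000))
    def test_sum_one_bounds_and_shift_invariance(self, values, shift):
        w = akaike_weights(values)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((w >= 0) & (w <= 1))
        w2 = akaike_weights(np.asarray(values) + shift)
        np.testing.assert_allclose(w, w2, atol=1e-9)


class TestVarianceMeasures:
    def test_residual_variance_examples(self):
        assert residual_variance(0.0, 26, 3) == 0.0
        assert residual_variance(0.00229, 26, 3) == pytest.approx(9.9565e-5,
                                                                  rel=1e-4)

    def test_zero_residuals_give_zero_chi2(self):
        assert reduced_chi_square(np.zeros(10), 0.1, 10, 3) == 0.0

    def test_doubling_sigma_quarters_the_statistic(self):
        resid = np.array([0.1, -0.3, 0.2, 0.4, -0.2])
        one = reduced_chi_square(resid, 0.1, 5, 1)
        two = reduced_chi_square(resid, 0.2, 5, 1)
        assert one == pytest.approx(4 * two)

    def test_chi_square_brute_force(self):
        resid = np.array([0.3, -0.4])
        assert chi_square(resid, 0.5) == pytest.approx((0.09 + 0.16) / 0.25)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            reduced_chi_square(np.ones(5), 0.0, 5, 1)

    def test_true_model_reduced_chi_square_near_unity(self):
        # residuals ~ N(0, sigma^2): expectation of the statistic is ~1
        rng = np.random.default_rng(42)
        vals = [reduced_chi_square(rng.normal(0, 0.1, 26), 0.1, 26, 0)
                for _ in range(2000)]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.02)
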