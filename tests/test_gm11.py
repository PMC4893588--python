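"""Core grey-model chain: transform, accumulation, fit, response, forecast."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greycast import (
    GlucoseSeries,
    GreyFit,
    GreyParameters,
    InvalidInputError,
    ago_accumulate,
    fit_gm11,
    forecast,
    log_transform,
    restore_increments,
    time_response,
)
from greycast.gm11 import TransformedSeries, identity_transform


def make_fit(a, b, y0, n_fit=18, domain="log"):
    """Bare GreyFit carrying given parameters (no data fitted)."""
    return GreyFit(
        params=GreyParameters(a=a, b=b),
        domain=domain,
        y0_initial=y0,
        n_fit=n_fit,
        fitted_glucose=np.empty(0),
        residuals=np.empty(0),
        degenerate_a=abs(a) < 1e-10,
        condition_number=1.0,
    )


def exact_lstsq(z, y):
    """Independent least-squares oracle: exact rational normal equations.

    Solves min ||y - (-a*z + b)|| over (a, b) with Fraction arithmetic on
    the float inputs (floats are exact binary rationals), so the solution
    carries no rounding error of its own.
    """
    z = [Fraction(v) for v in z]
    y = [Fraction(v) for v in y]
    n = len(z)
    szz = sum(v * v for v in z)
    sz = sum(z)
    szy = sum(zi * yi for zi, yi in zip(z, y))
    sy = sum(y)
    # normal equations for design [-z, 1]
    det = szz * n - sz * sz
    a = (sz * sy - n * szy) / det
    b = (szz * sy - sz * szy) / det
    return float(a), float(b)


class TestTransforms:
    def test_log_of_powers_of_e(self):
        ts = log_transform(GlucoseSeries([1.0, math.e, math.e**2]))
        assert ts.domain == "log"
        np.testing.assert_allclose(ts.values, [0.0, 1.0, 2.0], atol=1e-15)

    def test_log_of_single_reading(self):
        ts = log_transform(GlucoseSeries([12.9]))
        assert ts.values[0] == pytest.approx(math.log(12.9), abs=1e-12)

    def test_nonpositive_value_rejected_with_index(self):
        with pytest.raises(InvalidInputError, match="index 2"):
            GlucoseSeries([5.0, 0.0, 6.0])

    def test_subunit_glucose_warns(self):
        with pytest.warns(UserWarning, match="below 1 mmol/L"):
            log_transform(GlucoseSeries([0.5, 2.0, 3.0]))

    def test_identity_transform_passthrough(self):
        s = GlucoseSeries([5.0, 6.0, 7.0, 8.0])
        ts = identity_transform(s)
        assert ts.domain == "identity"
        np.testing.assert_array_equal(ts.values, s.values)


class TestAccumulation:
    @pytest.mark.parametrize(
        "y0, y1, z",
        [
            ([1, 1, 1], [1, 2, 3], [1.5, 2.5]),
            ([2, 3, 5], [2, 5, 10], [3.5, 7.5]),
        ],
    )
    def test_hand_sums(self, y0, y1, z):
        acc = ago_accumulate(TransformedSeries(np.array(y0, float), "identity"))
        np.testing.assert_allclose(acc.values, y1)
        np.testing.assert_allclose(acc.background, z)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            ago_accumulate(TransformedSeries(np.array([1.0]), "identity"))

    @given(
        st.lists(
            st.integers(min_value=-1000, max_value=1000), min_size=2, max_size=40
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_first_differences_invert_accumulation_exactly(self, values):
        """1-AGO followed by first differencing is the identity (integer-exact)."""
        arr = np.array(values, dtype=float)
        acc = ago_accumulate(TransformedSeries(arr, "identity"))
        recovered = np.concatenate([[acc.values[0]], np.diff(acc.values)])
        np.testing.assert_array_equal(recovered, arr)


class TestFit:
    def test_geometric_sequence_closed_form_parameters(self):
        """Geometric transformed increments c*q^(i-1) satisfy the grey
        difference equation exactly with a = -2(q-1)/(q+1), b = 2c/(q+1)."""
        c, q, n = 1.0, 1.05, 18
        x = c * q ** np.arange(n)
        fit = fit_gm11(GlucoseSeries(x), domain="identity")
        assert fit.params.a == pytest.approx(-2 * (q - 1) / (q + 1), abs=1e-9)
        assert fit.params.b == pytest.approx(2 * c / (q + 1), abs=1e-9)
        # grey-equation residuals y0(k) + a*z(k) - b vanish
        acc = ago_accumulate(identity_transform(GlucoseSeries(x)))
        grey_resid = x[1:] + fit.params.a * acc.background - fit.params.b
        assert np.max(np.abs(grey_resid)) <= 1e-10

    def test_constant_series_degenerate_path(self):
        fit = fit_gm11(GlucoseSeries([8.0] * 5), domain="identity")
        assert fit.degenerate_a
        np.testing.assert_allclose(fit.fitted_glucose, 8.0, atol=1e-9)

    @pytest.mark.parametrize("domain", ["log", "identity"])
    @pytest.mark.parametrize("seed", range(10))
    def test_parameters_match_exact_rational_least_squares(self, seed, domain):
        rng = np.random.default_rng(seed)
        x = rng.uniform(4.0, 15.0, size=6)
        fit = fit_gm11(GlucoseSeries(x), domain=domain)
        y = np.log(x) if domain == "log" else x
        acc = ago_accumulate(TransformedSeries(y, domain))
        a_ref, b_ref = exact_lstsq(acc.background, y[1:])
        assert fit.params.a == pytest.approx(a_ref, abs=1e-8)
        assert fit.params.b == pytest.approx(b_ref, abs=1e-8)

    def test_window_below_minimum_rejected(self):
        with pytest.raises(InvalidInputError, match="at least 4"):
            fit_gm11(GlucoseSeries([5.0, 6.0, 7.0]))


class TestTimeResponse:
    def test_initial_condition_identity(self):
        # response constants of form (y0 - b/a)*e^{-a(i-1)} + b/a with
        # y0 - b/a = 90.701, b/a = -88.7 recover y0 at i = 1
        a = -0.02
        ba = -88.7
        y0 = 90.701 + ba
        fit = make_fit(a, ba * a, y0)
        assert time_response(fit, 1) == pytest.approx(2.001, abs=1e-12)

    def test_linear_limit(self):
        fit = make_fit(0.0, 0.1, 2.0)
        assert time_response(fit, 4) == pytest.approx(2.3, abs=1e-12)

    def test_hand_evaluated_decay(self):
        # a = ln 2, y0 = 1, b = 0: response is 2^{-(i-1)}
        fit = make_fit(math.log(2.0), 0.0, 1.0)
        assert time_response(fit, 3) == pytest.approx(0.25, abs=1e-12)

    def test_index_below_one_rejected(self):
        with pytest.raises(InvalidInputError):
            time_response(make_fit(0.1, 0.1, 1.0), 0)


class TestRestoreIncrements:
    @given(
        # |a| >= 1e-3: the identity is algebraic, but the differencing
        # route loses digits to cancellation in b/a as a -> 0 (the
        # degenerate branch takes over well before that matters in fits)
        a=st.floats(min_value=-0.5, max_value=0.5).filter(lambda v: abs(v) >= 1e-3),
        b=st.floats(min_value=-2.0, max_value=2.0),
        y0=st.floats(min_value=0.1, max_value=3.5),
        i=st.integers(min_value=2, max_value=40),
    )
    @settings(max_examples=1000, derandomize=True)
    def test_closed_form_equals_differencing(self, a, b, y0, i):
        """The closed-form increment and the difference of consecutive
        time responses are algebraically identical."""
        fit = make_fit(a, b, y0)
        closed = restore_increments(fit, i, method="closed")
        diff = restore_increments(fit, i, method="difference")
        assert closed == pytest.approx(diff, abs=1e-12, rel=1e-12)

    def test_degenerate_limit_constant_increments(self):
        fit = make_fit(0.0, 0.37, 1.0)
        for i in (2, 5, 11):
            assert restore_increments(fit, i) == 0.37

    def test_geometric_increment_recovered(self):
        # parameters from the closed-form identity at c = 1, q = 1.05
        fit = make_fit(-0.04878049, 0.97560976, 1.0)
        closed = restore_increments(fit, 2, method="closed")
        diff = restore_increments(fit, 2, method="difference")
        assert closed == pytest.approx(diff, abs=1e-12)
        # the continuous-time response approximates the generating
        # geometric increment q*c to O(a^3)
        assert closed == pytest.approx(1.05, abs=1e-3)


class TestForecast:
    def test_constant_series_extrapolates_constant(self):
        fit = fit_gm11(GlucoseSeries([8.0] * 5), domain="identity")
        result = forecast(fit, 3)
        np.testing.assert_allclose(result.predictions, [8.0, 8.0, 8.0], atol=1e-9)
        assert result.horizon_minutes == 15.0

    def test_closed_form_agrees_with_stepwise_differencing(self):
        c, q, n = 1.0, 1.05, 18
        fit = fit_gm11(GlucoseSeries(c * q ** np.arange(n)), domain="identity")
        result = forecast(fit, 1)
        stepwise = time_response(fit, n + 1) - time_response(fit, n)
        assert result.predictions[0] == pytest.approx(stepwise, abs=1e-12)

    def test_log_domain_forecasts_positive_and_monotone(self, postprandial_series):
        fit = fit_gm11(postprandial_series.window(1, 18), domain="log")
        assert fit.params.a < 0  # rising window
        result = forecast(fit, 6)
        assert np.all(result.predictions > 0)
        assert np.all(np.diff(result.predictions) > 0)

    @pytest.mark.parametrize("a, increasing", [(-0.05, True), (0.05, False)])
    def test_increment_monotonicity_follows_sign_of_a(self, a, increasing):
        fit = make_fit(a, 0.5, 2.0)
        inc = restore_increments(fit, np.arange(2, 12))
        assert np.all(np.diff(inc) > 0) == increasing
        assert np.all(np.diff(inc) < 0) == (not increasing)

    def test_identity_domain_nonpositive_prediction_flagged(self):
        # degenerate plain model with negative constant increments
        fit = make_fit(0.0, -0.5, 5.0, domain="identity")
        with pytest.warns(UserWarning, match="non-positive"):
            result = forecast(fit, 3)
        assert result.nonpositive
        np.testing.assert_allclose(result.predictions, -0.5)

    def test_zero_horizon_rejected(self):
        fit = fit_gm11(GlucoseSeries([8.0] * 5), domain="identity")
        with pytest.raises(InvalidInputError):
            forecast(fit, 0)
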