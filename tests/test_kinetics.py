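"""Forward Weibull-Arrhenius model: closed forms, limits and monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sonoextract as sx
from sonoextract.kinetics import ExtractionCurve, KineticsDataset

# Published characteristic times (s) at the temperature extremes, as
# reported alongside the identified parameter tables.
PRINTED_ALPHAS = [
    ("CE", "TPC", 5.0, 279.0),
    ("CE", "TPC", 25.0, 45.0),
    ("CE", "TFC", 5.0, 199.0),
    ("CE", "TFC", 25.0, 49.0),
    ("CE", "AA", 5.0, 154.0),
    ("CE", "AA", 25.0, 23.0),
    ("UAE1", "TPC", 5.0, 63.0),
    ("UAE1", "TPC", 25.0, 18.0),
    ("UAE2", "TPC", 5.0, 37.0),
    ("UAE2", "TPC", 25.0, 19.0),
    ("UAE1", "TFC", 5.0, 48.0),
    ("UAE1", "TFC", 25.0, 30.0),
    ("UAE2", "TFC", 5.0, 48.0),
    ("UAE2", "TFC", 25.0, 30.0),
    ("UAE1", "AA", 5.0, 57.0),
    ("UAE1", "AA", 25.0, 15.0),
    ("UAE2", "AA", 5.0, 26.0),
    ("UAE2", "AA", 25.0, 8.0),
]

params_strategy = st.builds(
    sx.WeibullArrheniusParams,
    alpha0=st.floats(1e-10, 1e-1),
    Ea=st.floats(0.0, 1e5),
    beta=st.floats(0.01, 3.0),
)


class TestAlphaAtTemperature:
    @pytest.mark.parametrize("condition,response,temp_C,printed", PRINTED_ALPHAS)
    def test_reproduces_printed_characteristic_times(
        self, condition, response, temp_C, printed
    ):
        """Forward Arrhenius evaluation of the identified parameters gives
        the characteristic times reported in the study text to within the
        rounding of the printed alpha0/Ea (5% relative)."""
        params = sx.REFERENCE_PARAMS[(condition, response)]
        alpha = sx.alpha_at_temperature(params, sx.celsius_to_kelvin(temp_C))
        assert alpha == pytest.approx(printed, rel=0.05)

    def test_high_precision_oracle_value(self):
        """Independent arbitrary-precision evaluation, frozen."""
        params = sx.WeibullArrheniusParams(1.69e-3, 23103.4, 0.618)
        assert sx.alpha_at_temperature(params, 278.15) == pytest.approx(
            36.872417898554863, rel=1e-12
        )

    def test_zero_activation_energy_gives_constant_scale(self):
        params = sx.WeibullArrheniusParams(0.37, 0.0, 1.0)
        for T in (250.0, 300.0, 400.0):
            assert sx.alpha_at_temperature(params, T) == pytest.approx(0.37)

    @given(params=params_strategy)
    @settings(max_examples=50, deadline=None)
    def test_alpha_decreasing_in_temperature(self, params):
        temps = np.linspace(260.0, 340.0, 9)
        alphas = [sx.alpha_at_temperature(params, T) for T in temps]
        assert all(a > 0 for a in alphas)
        if params.Ea > 1e-3:  # below that the change underflows doubles
            assert all(b < a for a, b in zip(alphas, alphas[1:]))
        elif params.Ea == 0.0:
            assert all(a == alphas[0] for a in alphas)

    def test_nonpositive_temperature_rejected(self):
        params = sx.WeibullArrheniusParams(1.0, 1000.0, 1.0)
        with pytest.raises(ValueError, match="temperature"):
            sx.alpha_at_temperature(params, 0.0)

    def test_no_overflow_for_extreme_ratio(self):
        params = sx.WeibullArrheniusParams(1e-14, 2e5, 0.5)
        val = sx.alpha_at_temperature(params, 200.0)
        assert np.isfinite(val) and val > 0


class TestWeibullYield:
    def test_zero_time_gives_zero_yield(self):
        assert sx.weibull_yield(0.0, 37.0, 0.618, 83.0) == 0.0

    def test_first_order_limit_at_characteristic_time(self):
        """At t = alpha with beta = 1 the curve sits at 1 - 1/e of Y_eq."""
        assert sx.weibull_yield(37.0, 37.0, 1.0, 100.0) == pytest.approx(
            63.212055882855768, rel=1e-12
        )

    def test_high_precision_oracle_value(self):
        """Frozen arbitrary-precision evaluation at sonicated-TPC inputs."""
        assert sx.weibull_yield(600.0, 37.0, 0.618, 83.0) == pytest.approx(
            82.691335004279030, rel=1e-12
        )

    def test_beta_one_matches_first_order_closed_form(self, rng):
        t = rng.uniform(0, 2000, 50)
        alpha, y_eq = 123.0, 77.0
        expected = y_eq * (1 - np.exp(-t / alpha))
        np.testing.assert_allclose(
            sx.weibull_yield(t, alpha, 1.0, y_eq), expected, rtol=1e-14
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            sx.weibull_yield(-1.0, 37.0, 0.618, 83.0)

    @given(params=params_strategy, y_eq=st.floats(1.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_nondecreasing(self, params, y_eq):
        """0 <= Y(t) < Y_eq and Y non-decreasing over a time grid."""
        alpha = sx.alpha_at_temperature(params, 298.15)
        t = np.linspace(0.0, 3600.0, 40)
        y = sx.weibull_yield(t, alpha, params.beta, y_eq)
        assert np.all(y >= 0.0) and np.all(y <= y_eq)
        # strictly below the asymptote wherever 1 - exp(-(t/alpha)^beta) is
        # distinguishable from 1 in double precision (exp(-x) > 2**-53)
        with np.errstate(divide="ignore", over="ignore"):
            exponent = np.where(t > 0, (t / alpha) ** params.beta, 0.0)
        assert np.all(y[exponent < 36.0] < y_eq)
        assert np.all(np.diff(y) >= -1e-12 * y_eq)


class TestPredictCurve:
    def test_time_zero_maps_to_zero(self):
        params = sx.REFERENCE_PARAMS[("CE", "TPC")]
        assert sx.predict_curve(params, 67.3, [0.0], 25.0)[0] == 0.0

    def test_warmer_runs_extract_faster(self):
        """With Ea > 0, yields at any t > 0 are higher at higher temperature."""
        params = sx.REFERENCE_PARAMS[("CE", "AA")]
        t = np.linspace(30.0, 1800.0, 25)
        y_cold = sx.predict_curve(params, 50.0, t, 5.0)
        y_warm = sx.predict_curve(params, 50.0, t, 25.0)
        assert np.all(y_warm > y_cold)

    def test_asymptote_equals_equilibrium_yield(self):
        params = sx.REFERENCE_PARAMS[("CE", "TPC")]
        val = sx.predict_curve(params, 67.3, [3600.0e6], 25.0)[0]
        assert val == pytest.approx(67.3, abs=1e-6)

    def test_composition_of_alpha_and_weibull(self):
        params = sx.REFERENCE_PARAMS[("UAE1", "AA")]
        t = np.array([60.0, 300.0, 1800.0])
        alpha = sx.alpha_at_temperature(params, sx.celsius_to_kelvin(15.0))
        np.testing.assert_allclose(
            sx.predict_curve(params, 70.0, t, 15.0),
            sx.weibull_yield(t, alpha, params.beta, 70.0),
            rtol=1e-14,
        )


class TestDomainTypes:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sx.WeibullArrheniusParams(-1.0, 1000.0, 0.5)
        with pytest.raises(ValueError):
            sx.WeibullArrheniusParams(1.0, -5.0, 0.5)
        with pytest.raises(ValueError):
            sx.WeibullArrheniusParams(1.0, 1000.0, 0.0)

    def test_curve_requires_sorted_times_and_matching_lengths(self):
        with pytest.raises(ValueError, match="sorted"):
            ExtractionCurve("CE", 5.0, "TPC", (60.0, 30.0), (1.0, 2.0), 67.3)
        with pytest.raises(ValueError, match="equal length"):
            ExtractionCurve("CE", 5.0, "TPC", (30.0, 60.0), (1.0,), 67.3)

    def test_dataset_rejects_mixed_labels_and_duplicate_temperatures(self):
        c1 = ExtractionCurve("CE", 5.0, "TPC", (60.0,), (10.0,), 67.3)
        c2 = ExtractionCurve("CE", 5.0, "TFC", (60.0,), (10.0,), 50.0)
        with pytest.raises(ValueError, match="responses"):
            KineticsDataset((c1, c2))
        c3 = ExtractionCurve("CE", 5.0, "TPC", (60.0,), (12.0,), 67.3)
        with pytest.raises(ValueError, match="distinct"):
            KineticsDataset((c1, c3))
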