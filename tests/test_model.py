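"""Simultaneous multi-temperature least-squares identification."""

import numpy as np
import pytest

import sonoextract as sx
from sonoextract.model import t_confidence_intervals


def _noiseless_dataset(alpha0, ea, beta, y_eq=74.7):
    design = sx.SyntheticDesign(
        true_params=sx.WeibullArrheniusParams(alpha0, ea, beta),
        equilibrium={5.0: y_eq, 15.0: y_eq, 25.0: y_eq},
        replicates=1,
        noise_sd=0.0,
        seed=0,
    )
    return sx.generate_extraction_dataset(design).dataset


class TestNoiselessRecovery:
    def test_generator_round_trip_recovers_truth(self):
        """Refitting noiseless curves from known parameters recovers them to
        much better than 1e-4 relative, with essentially zero RSS."""
        ds = _noiseless_dataset(5e-7, 43000.0, 0.53)
        res = sx.fit_weibull_arrhenius(ds)
        assert res.converged
        est = np.array([res.params.alpha0, res.params.Ea, res.params.beta])
        np.testing.assert_allclose(est, [5e-7, 43000.0, 0.53], rtol=1e-4)
        assert res.ssr < 1e-8

    def test_first_order_data_identifies_beta_one(self):
        """Yields following Y_eq*(1-exp(-t/alpha)) at a shared alpha, with the
        activation energy pinned at zero, give beta-hat = 1."""
        times = (60.0, 120.0, 180.0, 240.0, 300.0, 360.0, 480.0, 600.0, 1800.0)
        alpha, y_eq = 80.0, 80.0  # alpha inside the default alpha0 box
        curves = tuple(
            sx.ExtractionCurve(
                "CE", T, "TPC", times,
                tuple(y_eq * (1 - np.exp(-np.asarray(times) / alpha))),
                y_eq,
            )
            for T in (5.0, 15.0, 25.0)
        )
        config = sx.FitConfig(
            bounds=((-14.0, 2.0), (0.0, 0.0), (np.log(1e-3), np.log(3.0)))
        )
        res = sx.fit_weibull_arrhenius(sx.KineticsDataset(curves), config)
        assert res.params.beta == pytest.approx(1.0, rel=1e-6)
        assert res.params.alpha0 == pytest.approx(alpha, rel=1e-4)

    def test_zero_residuals_degenerate_intervals(self):
        """A perfect fit has sigma2 = 0, so the CI collapses to the estimate."""
        ds = _noiseless_dataset(5e-7, 43000.0, 0.53)
        res = sx.fit_weibull_arrhenius(ds)
        ci = res.conf_int(0.95)
        est = np.array([res.params.alpha0, res.params.Ea, res.params.beta])
        np.testing.assert_allclose(ci[:, 0], est, rtol=1e-6)
        np.testing.assert_allclose(ci[:, 1], est, rtol=1e-6)


class TestFitInvariances:
    def test_curve_order_permutation(self, noisy_generated):
        ds = noisy_generated.dataset
        res1 = sx.fit_weibull_arrhenius(ds)
        res2 = sx.fit_weibull_arrhenius(ds.reordered([2, 0, 1]))
        np.testing.assert_allclose(
            res1.params.as_array(), res2.params.as_array(), rtol=1e-6
        )

    def test_interval_width_grows_with_level(self, noisy_generated):
        res = sx.fit_weibull_arrhenius(noisy_generated.dataset)
        widths = [
            np.diff(res.conf_int(level), axis=1).ravel()
            for level in (0.80, 0.90, 0.95, 0.99)
        ]
        for narrow, wide in zip(widths, widths[1:]):
            assert np.all(wide > narrow)

    def test_estimates_respect_bounds(self, noisy_generated):
        res = sx.fit_weibull_arrhenius(noisy_generated.dataset)
        assert 1e-14 <= res.params.alpha0 <= 1e2
        assert 0.0 <= res.params.Ea <= 2e5
        assert 1e-3 <= res.params.beta <= 3.0


class TestInputValidation:
    def test_single_temperature_rejected(self):
        curve = sx.ExtractionCurve(
            "CE", 5.0, "TPC", (60.0, 120.0, 300.0, 600.0),
            (10.0, 20.0, 30.0, 40.0), 67.3,
        )
        with pytest.raises(ValueError, match="2 temperatures"):
            sx.WeibullArrheniusModel(sx.KineticsDataset((curve,)))

    def test_too_few_observations_rejected(self):
        curves = tuple(
            sx.ExtractionCurve("CE", T, "TPC", (60.0,), (10.0,), 67.3)
            for T in (5.0, 25.0)
        )
        with pytest.raises(ValueError, match="observations"):
            sx.WeibullArrheniusModel(sx.KineticsDataset(curves))

    def test_init_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            sx.FitConfig(init=(1e3, 1e4, 0.5))  # alpha0 above the box


class TestConfidenceIntervalMachinery:
    def test_linear_model_matches_closed_form_t_intervals(self, rng):
        """The covariance/CI recipe applied to a straight line reproduces the
        textbook linear-regression intervals to 1e-8."""
        import statsmodels.api as sm

        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 2.0 + 0.7 * x + rng.normal(0, 0.3, 5)
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = 3
        sigma2 = resid @ resid / dof
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        ours = t_confidence_intervals(coef, se, dof, 0.95)
        ref = sm.OLS(y, X).fit().conf_int(alpha=0.05)
        np.testing.assert_allclose(ours, np.asarray(ref), atol=1e-8)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            t_confidence_intervals(np.ones(2), np.ones(2), 5, 1.5)


class TestSummary:
    def test_summary_reports_estimates_and_diagnostics(self, uae2_tpc_dataset):
        res = sx.fit_weibull_arrhenius(uae2_tpc_dataset)
        text = res.summary()
        assert "UAE2" in text and "TPC" in text
        assert "alpha0" in text and "Ea" in text and "beta" in text
        assert "converged: True" in text

    def test_predict_at_fitted_temperature(self, uae2_tpc_dataset):
        res = sx.fit_weibull_arrhenius(uae2_tpc_dataset)
        curve = uae2_tpc_dataset.curves[0]
        pred = res.predict(curve.times, curve.temperature_C)
        np.testing.assert_allclose(pred, curve.yields_array(), atol=1e-6)
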