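"""Tests for the power-law regression, prediction intervals and multiannual fits."""

import numpy as np
import pytest

from krillsim.regression import (
    bias_reduction,
    coverage_probability,
    fit_multiannual,
    fit_power_law,
    lagged_design,
    multiannual_error_table,
    performance_report,
    predict_interval,
    prediction_error,
)


class TestFitPowerLaw:
    def test_exact_recovery_on_noise_free_power_law(self):
        x = np.array([10.0, 20.0, 30.0])
        y = np.exp(2.0) * x**1.5
        fit = fit_power_law(y, x)
        assert fit.beta0 == pytest.approx(2.0, abs=1e-10)
        assert fit.beta1 == pytest.approx(1.5, abs=1e-10)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_matches_hand_computed_normal_equations(self):
        """Five-point oracle: slope = Sxy/Sxx of the logs, intercept from means."""
        index = np.array([12.0, 19.0, 27.0, 41.0, 55.0])
        recruits = np.array([1.1e4, 3.0e4, 4.2e4, 9.7e4, 1.8e5])
        x, y = np.log(index), np.log(recruits)
        xb, yb = x.mean(), y.mean()
        sxx = ((x - xb) ** 2).sum()
        sxy = ((x - xb) * (y - yb)).sum()
        slope = sxy / sxx
        intercept = yb - slope * xb
        resid = y - intercept - slope * x
        sigma2 = (resid**2).sum() / (len(x) - 2)
        fit = fit_power_law(recruits, index)
        assert fit.beta1 == pytest.approx(slope, rel=1e-12)
        assert fit.beta0 == pytest.approx(intercept, rel=1e-12)
        assert fit.sigma2 == pytest.approx(sigma2, rel=1e-12)
        assert fit.var_beta1 == pytest.approx(sigma2 / sxx, rel=1e-12)
        assert fit.var_beta0 == pytest.approx(sigma2 * (1 / 5 + xb**2 / sxx), rel=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0, 0.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])  # constant index
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0], [1.0, 2.0])  # too few points

    def test_pi_line_params_bracket_the_mean_fit(self, rng):
        x = rng.uniform(10, 60, 200)
        y = np.exp(10 + 1.4 * np.log(x) + rng.normal(0, 0.3, 200))
        fit = fit_power_law(y, x)
        assert fit.pi_upper_params[0] > fit.beta0 > fit.pi_lower_params[0]
        # the bound lines share the mean fit's slope to first order
        assert fit.pi_upper_params[1] == pytest.approx(fit.beta1, abs=0.1)

    def test_recruit_rescaling_shifts_intercept_only(self, rng):
        """beta0 moves by exactly ln(c); beta1, coverage and %errors do not."""
        x = rng.uniform(10, 60, 300)
        y = np.exp(10 + 1.4 * np.log(x) + rng.normal(0, 0.4, 300))
        c = 0.01
        f1, f2 = fit_power_law(y, x), fit_power_law(c * y, x)
        assert f2.beta0 - f1.beta0 == pytest.approx(np.log(c), abs=1e-10)
        assert f2.beta1 == pytest.approx(f1.beta1, abs=1e-10)
        assert coverage_probability(f2, c * y, x) == pytest.approx(
            coverage_probability(f1, y, x), abs=1e-12
        )
        e1 = prediction_error(f1.predict(x), y)
        e2 = prediction_error(f2.predict(x), c * y)
        np.testing.assert_allclose(e1, e2, atol=1e-8)


class TestPredictInterval:
    def test_noise_free_interval_collapses(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        y = np.exp(1.0) * x**2
        fit = fit_power_law(y, x)
        point, lo, up = predict_interval(fit, 25.0)
        assert up - lo == pytest.approx(0.0, abs=1e-6 * point)

    def test_tiny_level_collapses_to_point(self, rng):
        x = rng.uniform(10, 60, 100)
        y = np.exp(8 + 1.2 * np.log(x) + rng.normal(0, 0.5, 100))
        fit = fit_power_law(y, x)
        point, lo, up = predict_interval(fit, 30.0, level=1e-9)
        assert lo == pytest.approx(point, rel=1e-6)
        assert up == pytest.approx(point, rel=1e-6)

    def test_ordering_and_positivity(self, rng):
        x = rng.uniform(10, 60, 100)
        y = np.exp(8 + 1.2 * np.log(x) + rng.normal(0, 0.5, 100))
        fit = fit_power_law(y, x)
        point, lo, up = predict_interval(fit, np.array([15.0, 30.0, 50.0]))
        assert np.all(lo > 0) and np.all(lo < point) and np.all(point < up)

    def test_calibration_on_known_model(self):
        """95% intervals from one synthetic draw cover ~95% of held-out draws."""
        rng = np.random.default_rng(7)
        x = rng.uniform(5, 60, 500)
        def gen():
            return np.exp(9 + 1.4 * np.log(x) + rng.normal(0, 0.5, 500))
        fit = fit_power_law(gen(), x)
        cov = np.mean([coverage_probability(fit, gen(), x) for _ in range(20)])
        assert cov == pytest.approx(95.0, abs=2.0)

    def test_band_method_is_constant_width_in_logs(self, rng):
        x = rng.uniform(10, 60, 100)
        y = np.exp(8 + 1.2 * np.log(x) + rng.normal(0, 0.5, 100))
        fit = fit_power_law(y, x)
        point, lo, up = predict_interval(fit, np.array([12.0, 55.0]), method="band")
        widths = np.log(up) - np.log(lo)
        assert widths[0] == pytest.approx(widths[1], rel=1e-12)


class TestCoverageAndError:
    def test_points_on_line_are_fully_covered(self):
        x = np.array([10.0, 20.0, 40.0, 50.0])
        y = np.exp(2.0) * x**1.3
        fit = fit_power_law(y, x)
        assert coverage_probability(fit, y, x) == 100.0

    @pytest.mark.parametrize(
        "pred, sim, expected",
        [(100.0, 100.0, 0.0), (200.0, 100.0, 100.0), (50.0, 100.0, -50.0)],
    )
    def test_prediction_error_identities(self, pred, sim, expected):
        assert prediction_error(pred, sim) == pytest.approx(expected)

    def test_scaling_identity(self):
        """error(c*R, R) = 100*(c - 1) for any truth R."""
        R = np.array([10.0, 1e4, 3e6])
        for c in (0.5, 1.7, 3.0):
            np.testing.assert_allclose(prediction_error(c * R, R), 100 * (c - 1))

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            prediction_error(10.0, 0.0)


class TestMultiannual:
    def test_k1_equals_power_law(self, rng):
        x = rng.uniform(10, 60, 100)
        y = np.exp(9 + 1.3 * np.log(x) + rng.normal(0, 0.4, 100))
        pl = fit_power_law(y, x)
        ma = fit_multiannual(y, x[:, None], k=1)
        assert ma.betas[0] == pytest.approx(pl.beta0, rel=1e-10)
        assert ma.betas[1] == pytest.approx(pl.beta1, rel=1e-10)
        assert ma.sigma2 == pytest.approx(pl.sigma2, rel=1e-10)

    def test_exact_recovery_of_two_lag_model(self, rng):
        lags = np.exp(rng.normal(3.0, 0.5, (60, 2)))
        y = np.exp(1.5 + 0.9 * np.log(lags[:, 0]) + 0.4 * np.log(lags[:, 1]))
        fit = fit_multiannual(y, lags, k=2)
        np.testing.assert_allclose(fit.betas, [1.5, 0.9, 0.4], atol=1e-10)
        np.testing.assert_allclose(fit.predict(lags), y, rtol=1e-10)

    def test_collinear_design_rejected(self, rng):
        col = np.exp(rng.normal(3.0, 0.5, 50))
        lags = np.column_stack([col, col])
        with pytest.raises(ValueError):
            fit_multiannual(np.exp(rng.normal(9, 1, 50)), lags, k=2)

    def test_performance_report_consistency(self, rng):
        x = rng.uniform(10, 60, 200)
        y = np.exp(9 + 1.3 * np.log(x) + rng.normal(0, 0.4, 200))
        fit = fit_power_law(y, x)
        errors = prediction_error(fit.predict(x), y)
        rep = performance_report(fit, y, x, errors_kk=errors / 2)
        assert rep.coverage_pct == coverage_probability(fit, y, x)
        assert rep.mean_abs_error_pct == pytest.approx(np.mean(np.abs(errors)))
        assert rep.error_quantiles[0.5] == pytest.approx(np.median(errors))
        assert rep.bias_reduction_pct == pytest.approx(50.0)

    def test_bias_reduction_identities(self):
        e = np.array([10.0, -20.0, 30.0])
        assert bias_reduction(e, e) == 0.0
        assert bias_reduction(e, e / 2) == pytest.approx(50.0)  # halved -> 50% relative
        assert bias_reduction(e, e / 2, relative=False) == pytest.approx(10.0)


class TestCampaignHelpers:
    def test_lagged_design_alignment(self, campaign_rv60):
        recruits, lags, sim_ids = lagged_design(campaign_rv60, 60.0, k_max=3)
        final = campaign_rv60[campaign_rv60["year"] == 10].set_index("sim_id")
        prev = campaign_rv60[campaign_rv60["year"] == 9].set_index("sim_id")
        sid = sim_ids[0]
        assert recruits[0] == final.loc[sid, "recruits"]
        assert lags[0, 0] == final.loc[sid, "f40_min_pct"]
        assert lags[0, 1] == prev.loc[sid, "f40_min_pct"]

    def test_error_table_shape(self, campaign_rv60):
        tab = multiannual_error_table(campaign_rv60, 60.0, k_max=3)
        n = lagged_design(campaign_rv60, 60.0, k_max=3)[0].size
        assert tab.shape[0] == 3 * n
        assert set(tab["k"]) == {1, 2, 3}

    def test_adding_lags_never_hurts_in_sample_fit(self, campaign_rv60):
        """In-sample mean absolute error is non-increasing in k (OLS nesting)."""
        tab = multiannual_error_table(campaign_rv60, 60.0, k_max=4)
        maes = tab.groupby("k")["prediction_error_pct"].apply(lambda e: e.abs().mean())
        # OLS minimises squared log-error, not |%| error, so allow tiny slack
        assert np.all(np.diff(maes.to_numpy()) < 0.5)
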