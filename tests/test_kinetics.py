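"""Rate fitting, calibration chain, dose-response and model objects."""

import numpy as np
import pytest

from labassay.kinetics import (
    CalibrationModel,
    ColorKineticsModel,
    DoseResponseModel,
    a_slope_to_activity,
    dose_response,
    estimate_conversion_factor,
    fit_rate,
    od_rate_to_molar_rate,
    select_linear_window,
    specific_activity,
)
from labassay.workflows import matched_calibration, scenario_kinetic_fit

#: the four printed chip dose-response points (conc mg/mL, k_a* 1/min)
CHIP_DOSE_POINTS = [(0.0, 0.001), (1.0, 0.028), (4.0, 0.059), (5.0, 0.078)]


class TestWindowSelection:
    def test_plate_window(self):
        assert select_linear_window(np.arange(0, 41.0), "microwell") == (5.0, 20.0)

    def test_chip_window_skips_lag(self):
        assert select_linear_window(np.arange(0, 61.0), "chip") == (10.0, 30.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="does not span"):
            select_linear_window(np.arange(0, 15.0), "microwell")

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError):
            select_linear_window(np.arange(0, 41.0), "cuvette")


class TestFitRate:
    def test_exact_line_recovered(self):
        t = np.arange(0, 41.0)
        fit = fit_rate(t, 5.0 + 0.107 * t, (5, 20))
        assert fit.slope == pytest.approx(0.107, abs=1e-12)
        assert fit.intercept == pytest.approx(5.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points == 16

    def test_replicate_slopes_agree_within_3_percent(self):
        """The two replicate a*-slopes 0.105 and 0.108 deviate by <=3%."""
        lo, hi = 0.105, 0.108
        assert (hi - lo) / ((hi + lo) / 2) <= 0.03

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_rate(np.array([0, 10, 40.0]), np.zeros(3), (5, 20))

    def test_noisy_slope_unbiased_over_seeds(self):
        """Monte-Carlo: mean recovered slope within 2% of truth."""
        t = np.arange(0, 41.0)
        slopes = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = 2.0 + 0.107 * t + rng.normal(0, 0.05, t.size)
            slopes.append(fit_rate(t, y, (5, 20)).slope)
        assert np.mean(slopes) == pytest.approx(0.107, rel=0.02)


class TestCalibrationChain:
    CAL = CalibrationModel(od_slope_factor=4.33, a_to_od_factor=120.0)

    def test_od_rate_conversion(self):
        assert od_rate_to_molar_rate(0.0, self.CAL) == 0.0
        assert od_rate_to_molar_rate(0.00433, self.CAL) == pytest.approx(1.0)
        assert od_rate_to_molar_rate(8.917e-4, self.CAL) == pytest.approx(0.206, abs=5e-4)

    def test_worked_example(self):
        """k_a* = 0.107 with factor 120 and slope 4.33/mM gives 0.21 mU/mL."""
        activity = a_slope_to_activity(0.107, self.CAL)
        assert round(activity, 2) == 0.21

    def test_linearity(self):
        one = a_slope_to_activity(0.107, self.CAL)
        assert a_slope_to_activity(0.214, self.CAL) == pytest.approx(2 * one)
        assert a_slope_to_activity(0.0, self.CAL) == 0.0

    def test_missing_factor_demands_calibration(self):
        with pytest.raises(ValueError, match="a_to_od_factor"):
            a_slope_to_activity(0.1, CalibrationModel())

    def test_single_pair_reproduces_printed_factor(self):
        assert estimate_conversion_factor([(0.107, 8.917e-4)]) == pytest.approx(120.0, abs=0.1)

    def test_exact_proportionality_recovered(self):
        od = np.array([1e-4, 5e-4, 1e-3])
        pairs = list(zip(117.0 * od, od))
        assert estimate_conversion_factor(pairs) == pytest.approx(117.0)

    def test_nonpositive_od_rejected(self):
        with pytest.raises(ValueError):
            estimate_conversion_factor([(0.1, 0.0)])

    def test_factor_stable_across_enzyme_levels(self, runs):
        """Paired noiseless plate runs at 3 levels agree with the level-1
        factor to within 5%."""
        pairs = []
        for name in (
            "plate_soluble_0.1mM_0.5mg",
            "plate_soluble_0.1mM_1mg",
            "plate_soluble_0.1mM_2mg",
        ):
            cal = matched_calibration(name)
            pairs.append(cal.a_to_od_factor)
        pooled = np.mean(pairs)
        assert pooled == pytest.approx(pairs[1], rel=0.05)

    def test_specific_activity(self):
        assert specific_activity(0.34, 1.0) == pytest.approx(0.34)
        assert specific_activity(1.52, 5.0) == pytest.approx(0.304)
        assert specific_activity(0.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            specific_activity(0.3, 0.0)


class TestDoseResponse:
    def test_exact_line_through_origin(self):
        pts = [(c, 0.02 * c) for c in (0.5, 1, 2, 5)]
        dr = dose_response(pts, "through-origin")
        assert dr.sensitivity == pytest.approx(0.02)
        assert dr.r_squared == pytest.approx(1.0)

    def test_printed_chip_points_bracket_reported_sensitivity(self):
        """The chip points give ~0.014 with intercept, ~0.0156 through origin,
        bracketing the reported 0.015; the mode is always carried along."""
        with_int = dose_response(CHIP_DOSE_POINTS, "with-intercept")
        origin = dose_response(CHIP_DOSE_POINTS, "through-origin")
        assert with_int.sensitivity == pytest.approx(0.01406, abs=2e-4)
        assert origin.sensitivity == pytest.approx(0.01557, abs=2e-4)
        assert with_int.sensitivity < 0.015 < origin.sensitivity
        assert with_int.fit_mode == "with-intercept"
        assert origin.fit_mode == "through-origin"

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            dose_response(CHIP_DOSE_POINTS, "robust")

    def test_inverse_is_self_consistent(self):
        model = DoseResponseModel(*zip(*CHIP_DOSE_POINTS))
        res = model.fit()
        predicted = res.predict(1.0)
        assert res.inverse(float(predicted)) == pytest.approx(1.0)


class TestModelObjects:
    def test_model_fit_summary(self):
        t = np.arange(0, 41.0)
        res = ColorKineticsModel(t, 1.0 + 0.05 * t, assay_format="microwell").fit()
        assert res.slope == pytest.approx(0.05)
        text = res.summary()
        assert "slope" in text and "5-20 min" in text

    def test_activity_conversion_from_results(self):
        t = np.arange(0, 41.0)
        res = ColorKineticsModel(t, 1.0 + 0.107 * t).fit()
        cal = CalibrationModel(od_slope_factor=4.33, a_to_od_factor=120.0)
        act = res.to_activity(cal, enzyme_conc=1.0)
        assert round(act.volumetric_activity, 2) == 0.21
        assert act.specific_activity == pytest.approx(act.volumetric_activity)

    def test_od_signal_uses_direct_conversion(self):
        t = np.arange(0, 41.0)
        res = ColorKineticsModel(t, 0.00433 * t, signal_kind="OD").fit()
        act = res.to_activity(CalibrationModel(od_slope_factor=4.33))
        assert act.volumetric_activity == pytest.approx(1.0, rel=1e-9)

    def test_dose_response_summary(self):
        res = DoseResponseModel(*zip(*CHIP_DOSE_POINTS)).fit()
        assert "sensitivity" in res.summary()

    def test_calibration_round_trip(self, tmp_path):
        cal = CalibrationModel(od_slope_factor=4.329, a_to_od_factor=17.9)
        path = tmp_path / "cal.json"
        cal.to_json(path)
        assert CalibrationModel.from_json(path) == cal

    def test_scenario_fit_has_positive_a_slope(self, runs):
        fit, _, _, _ = scenario_kinetic_fit(
            "plate_soluble_0.1mM_1mg", seed=0, overrides={"noise_sd": 0.0}
        )
        assert fit.slope > 0
        assert fit.r_squared > 0.99
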