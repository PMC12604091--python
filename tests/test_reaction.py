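"""Ground-truth chemistry: spot arithmetic, rate laws, integration."""

import numpy as np
import pytest

from labassay.reaction import (
    CHIP,
    MICROWELL,
    ChamberGeometry,
    KineticParameters,
    ReactionConditions,
    SpotArray,
    chamber_concentration,
    dissolution_rate,
    dmso_activity_factor,
    enzymatic_rate,
    integrate_reaction,
    per_spot_volume,
)


class TestSpotArithmetic:
    @pytest.mark.parametrize(
        "rows,expected_nl",
        [(5, 24.0), (10, 6.00), (12, 600.0 / 144.0)],  # printed: 24.0, 6.00, 4.17
    )
    def test_chip_spot_volumes(self, rows, expected_nl):
        arr = SpotArray(rows, rows, 0.6, 2.0)
        assert per_spot_volume(arr) == pytest.approx(expected_nl, abs=1e-9)

    def test_single_spot_identity(self):
        assert per_spot_volume(SpotArray(1, 1, 0.6, 2.0)) == pytest.approx(600.0)

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError):
            SpotArray(0, 5, 0.6, 2.0)

    def test_chip_dilution(self):
        # 0.6 uL of 2.0 mM into the 12 uL chamber -> 0.1 mM final
        assert chamber_concentration(SpotArray(10, 10, 0.6, 2.0), CHIP) == pytest.approx(0.1)

    def test_microwell_dilution(self):
        assert chamber_concentration(SpotArray(5, 5, 2.5, 2.0), MICROWELL) == pytest.approx(0.1)

    def test_zero_stock(self):
        assert chamber_concentration(SpotArray(5, 5, 2.5, 0.0), MICROWELL) == 0.0


class TestDmsoFactor:
    @pytest.mark.parametrize(
        "frac,factor", [(5.0, 1.00), (10.0, 0.78), (20.0, 0.38), (15.0, 0.58)]
    )
    def test_anchors_and_interpolation(self, frac, factor):
        assert dmso_activity_factor(frac) == pytest.approx(factor)

    @pytest.mark.parametrize("frac,factor", [(0.0, 1.00), (50.0, 0.38)])
    def test_clamped_outside_anchor_range(self, frac, factor):
        assert dmso_activity_factor(frac) == pytest.approx(factor)


class TestRateLaws:
    def setup_method(self):
        self.cond = ReactionConditions(1.0, 0.1, 5.0, MICROWELL)
        self.params = KineticParameters()

    def test_zero_substrate_zero_rate(self):
        assert enzymatic_rate(0.0, self.cond, self.params) == 0.0

    def test_linear_in_enzyme(self):
        double = ReactionConditions(2.0, 0.1, 5.0, MICROWELL)
        assert enzymatic_rate(0.5, double, self.params) == pytest.approx(
            2 * enzymatic_rate(0.5, self.cond, self.params)
        )

    def test_half_saturation(self):
        v_half = enzymatic_rate(self.params.km_app, self.cond, self.params)
        assert v_half == pytest.approx(self.params.kcat_app / 2.0)

    def test_anchor_rate(self):
        # 1.0 mg/mL at 0.1 mM ReC, 5% DMSO -> ~0.21 uM/min
        assert enzymatic_rate(0.1, self.cond, self.params) == pytest.approx(0.21, rel=1e-9)

    def test_dissolution_zero_mass(self):
        assert dissolution_rate(0.0, 6.0) == 0.0

    def test_dissolution_faster_for_smaller_spots(self):
        r_small = dissolution_rate(1.0, 4.17)
        r_large = dissolution_rate(1.0, 24.0)
        assert r_small > r_large > 0

    def test_dissolution_suppressed_by_agglomeration(self):
        base = dissolution_rate(1.0, 6.0)
        assert dissolution_rate(1.0, 6.0, agglomeration_factor=4.0) == pytest.approx(base / 4)
        assert dissolution_rate(1.0, 6.0, agglomeration_factor=1e12) == pytest.approx(0.0, abs=1e-9)


class TestIntegration:
    def test_zero_enzyme_decoupled_limit(self):
        """No enzyme: resorufin stays zero, dissolved ReC reaches the dilution limit."""
        arr = SpotArray(10, 10, 0.6, 2.0)
        cond = ReactionConditions(0.0, 0.1, 5.0, CHIP)
        truth = integrate_reaction(cond, array=arr, t_end=90.0, dt=0.02)
        assert np.all(truth.resorufin == 0.0)
        assert truth.rec_dissolved[-1] == pytest.approx(
            chamber_concentration(arr, CHIP), rel=1e-3
        )

    def test_soluble_first_order_closed_form(self):
        """km >> S with kcat/km fixed reduces to exponential substrate decay."""
        k1 = 0.05  # 1/min
        km = 1e6
        params = KineticParameters(kcat_app=k1 * km * 1000.0, km_app=km)
        cond = ReactionConditions(1.0, 0.1, 5.0, MICROWELL)
        truth = integrate_reaction(cond, params=params, t_end=30.0, dt=0.01)
        expected = 0.1 * np.exp(-k1 * truth.times)
        assert truth.rec_dissolved == pytest.approx(expected, rel=1e-3)

    def test_constant_rate_limit(self):
        """S >> consumed: the product time course is the constant-rate line."""
        cond = ReactionConditions(1.0, 0.1, 5.0, MICROWELL)
        truth = integrate_reaction(cond, t_end=0.5, dt=0.001)
        v0 = enzymatic_rate(0.1, cond) / 1000.0  # mM/min
        assert truth.resorufin[-1] == pytest.approx(v0 * truth.times[-1], rel=1e-3)

    def test_mass_balance_and_monotonicity(self):
        arr = SpotArray(5, 5, 2.5, 5.0, agglomeration_factor=4.0)
        cond = ReactionConditions(5.0, 0.25, 5.0, MICROWELL)
        truth = integrate_reaction(cond, array=arr, t_end=40.0, initial_dissolved_frac=0.5)
        assert truth.mass_balance_error() < 1e-6
        assert np.all(np.diff(truth.resorufin) >= 0)
        assert np.all(np.diff(truth.rec_remaining_spotted) <= 1e-12)

    def test_spotted_never_outpaces_soluble(self):
        arr = SpotArray(5, 5, 2.5, 5.0, agglomeration_factor=4.0)
        cond = ReactionConditions(5.0, 0.25, 5.0, MICROWELL)
        spotted = integrate_reaction(cond, array=arr, t_end=40.0, initial_dissolved_frac=0.5)
        soluble = integrate_reaction(cond, t_end=40.0)
        assert np.all(spotted.resorufin <= soluble.resorufin + 1e-12)
        assert np.all(spotted.rec_dissolved <= soluble.rec_dissolved[0] + 1e-12)

    def test_dissolution_steady_state_plateau(self):
        """Slow dissolution with consumption: dissolved ReC plateaus below nominal."""
        arr = SpotArray(5, 5, 2.5, 5.0, agglomeration_factor=4.0)
        cond = ReactionConditions(5.0, 0.25, 5.0, MICROWELL)
        truth = integrate_reaction(cond, array=arr, t_end=40.0, initial_dissolved_frac=0.5)
        late = truth.rec_dissolved[truth.times > 20]
        assert late.max() < 0.25  # below the complete-dissolution level
        # near-stationary: relative drift over the late phase is small
        assert abs(late[-1] - late[0]) / late.mean() < 0.25

    def test_smaller_spots_dissolve_faster(self):
        cond = ReactionConditions(0.0, 0.1, 5.0, CHIP)
        t95 = {}
        for rows in (5, 10):
            arr = SpotArray(rows, rows, 0.6, 2.0)
            truth = integrate_reaction(cond, array=arr, t_end=400.0, dt=0.05)
            t95[rows] = truth.times[np.argmax(truth.rec_remaining_spotted < 0.05)]
        assert t95[10] < t95[5]

    def test_step_size_convergence(self):
        cond = ReactionConditions(1.0, 0.1, 5.0, MICROWELL)
        a = integrate_reaction(cond, t_end=30.0, dt=0.02)
        b = integrate_reaction(cond, t_end=30.0, dt=0.01)
        rel = abs(a.resorufin[-1] - b.resorufin[-1]) / b.resorufin[-1]
        assert rel < 1e-4

    def test_invalid_inputs(self):
        cond = ReactionConditions(1.0, 0.1, 5.0, MICROWELL)
        with pytest.raises(ValueError):
            integrate_reaction(cond, t_end=-1.0)
        with pytest.raises(ValueError):
            integrate_reaction(cond, dt=0.0)
        with pytest.raises(ValueError):
            ChamberGeometry(volume=0.0, path_length=0.02)
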