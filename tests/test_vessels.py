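import numpy as np
import pytest

from cardioresp import (CollapseLaw, CompartmentParams, IntegrationError,
                        InvalidInputError, InvalidParameterError,
                        estimate_resistances, muscle_pump_pressure,
                        network_derivatives, packaged_scenario,
                        parallel_resistance, pulmonary_arterial_compliance,
                        split_systemic_resistance, starling_resistor_flow,
                        vessel_pressure, windkessel_transient)
from cardioresp.config import build_params, initial_state


class TestEstimateResistances:
    def test_hf_rest_arithmetic_is_exact(self):
        # Ras = (Pas - Pcv)/CO, Rap = (Pap - Pwedge)/CO, CO in cm^3/s
        ras, rap = estimate_resistances(89.0, 8.0, 26.0, 14.0, 3.7)
        co = 3.7 * 1000.0 / 60.0
        assert ras == (89.0 - 8.0) / co
        assert rap == (26.0 - 14.0) / co

    def test_vad_rest_arithmetic_is_exact(self):
        ras, rap = estimate_resistances(88.0, 8.0, 22.0, 14.0, 4.3)
        co = 4.3 * 1000.0 / 60.0
        assert ras == (88.0 - 8.0) / co
        assert rap == (22.0 - 14.0) / co

    @pytest.mark.parametrize("args", [
        (89.0, 8.0, 26.0, 14.0, 0.0),     # no flow
        (8.0, 89.0, 26.0, 14.0, 3.7),     # Pas below Pcv
        (89.0, 8.0, 14.0, 26.0, 3.7),     # Pap below Pwedge
    ])
    def test_rejects_unphysical_inputs(self, args):
        with pytest.raises(InvalidInputError):
            estimate_resistances(*args)


class TestResistanceSplit:
    def test_parallel_combination_recovers_total(self):
        parts = split_systemic_resistance(1.31)
        assert parallel_resistance(parts) == pytest.approx(1.31, rel=1e-12)

    def test_split_preserves_regional_ratios(self):
        # conductance fractions implied by the regional resistances
        # {upper body 5.2, kidneys 5.4, splanchnic 4.0, legs 9.4 each}
        parts = split_systemic_resistance(1.31)
        ref = np.array([5.2, 5.4, 4.0, 9.4, 9.4])
        assert np.allclose(parts / parts[0], ref / ref[0])

    def test_custom_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            split_systemic_resistance(1.0, fractions=[0.5, 0.4])

    def test_rejects_nonpositive_total(self):
        with pytest.raises(InvalidParameterError):
            split_systemic_resistance(0.0)

    def test_parallel_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            parallel_resistance([1.0, -2.0])


class TestWindkessel:
    def test_matches_closed_form_exponential(self):
        # dV/dt = Q - (V-Vu)/(RC): V(t) = V_inf + (V0 - V_inf) e^(-t/RC)
        r, c, vu, q, v0 = 1.2, 2.5, 100.0, 20.0, 130.0
        t, v = windkessel_transient(r, c, vu, q, v0, t_end=10.0, dt=1e-3)
        v_inf = vu + r * c * q
        exact = v_inf + (v0 - v_inf) * np.exp(-t / (r * c))
        assert np.max(np.abs(v - exact) / np.abs(exact)) < 1e-3


class TestVesselPressure:
    LIN = CompartmentParams(ra=1.0, rv=0.1, c=10.0, vu=200.0)
    COL = CompartmentParams(ra=1.0, rv=0.1, c=10.0, vu=200.0,
                            collapse=CollapseLaw(k_low=0.0008, knee_frac=0.5,
                                                 p_hi=12.0, k_hi=0.0008))

    def test_linear_region(self):
        assert vessel_pressure(250.0, self.LIN) == pytest.approx(5.0)
        assert vessel_pressure(250.0, self.LIN, p_ext=3.0) == pytest.approx(8.0)

    def test_collapse_law_matches_linear_in_normal_range(self):
        assert vessel_pressure(250.0, self.COL) == pytest.approx(
            vessel_pressure(250.0, self.LIN))

    def test_strictly_increasing_across_all_regimes(self):
        vols = np.linspace(5.0, 400.0, 500)
        p = np.array([vessel_pressure(v, self.COL) for v in vols])
        assert np.all(np.diff(p) > 0)

    def test_rejects_negative_volume(self):
        with pytest.raises(InvalidInputError):
            vessel_pressure(-1.0, self.LIN)


class TestPulmonaryCompliance:
    def test_constant_below_threshold(self):
        assert pulmonary_arterial_compliance(10.0, 1.3, base=3.0) == 3.0

    def test_decreases_to_floor_with_congestion(self):
        lo = pulmonary_arterial_compliance(20.0, 1.3, base=3.0)
        hi = pulmonary_arterial_compliance(60.0, 1.3, base=3.0)
        assert 3.0 > lo > hi
        assert hi == pytest.approx(0.5 * 3.0)

    def test_rejects_negative_wedge(self):
        with pytest.raises(InvalidInputError):
            pulmonary_arterial_compliance(-1.0, 1.3, base=3.0)


class TestMusclePump:
    def test_silent_at_rest(self):
        assert muscle_pump_pressure(0.3, 1.0, 0.0) == (0.0, 0.0)
        assert muscle_pump_pressure(0.3, 1.0, 20.0, active=False) == (0.0, 0.0)

    def test_legs_alternate_in_antiphase(self):
        ts = np.linspace(0.0, 1.0, 200, endpoint=False)
        vals = np.array([muscle_pump_pressure(t, 1.0, 20.0) for t in ts])
        assert vals.min() >= 0.0 and vals.max() <= 20.0 + 1e-12
        # at any instant at most one leg is squeezed
        assert np.all(np.minimum(vals[:, 0], vals[:, 1]) < 1e-9)
        assert vals[:, 0].max() > 1.0 and vals[:, 1].max() > 1.0

    def test_rejects_negative_amplitude(self):
        with pytest.raises(InvalidParameterError):
            muscle_pump_pressure(0.0, 1.0, -1.0)


class TestStarlingResistor:
    def test_waterfall_uses_external_pressure(self):
        open_flow = starling_resistor_flow(10.0, 5.0, 0.0, 1.0)
        squeezed = starling_resistor_flow(10.0, 5.0, 8.0, 1.0)
        assert open_flow == pytest.approx(5.0)
        assert squeezed == pytest.approx(2.0)

    def test_no_backflow(self):
        assert starling_resistor_flow(5.0, 10.0, 0.0, 1.0) == 0.0
        assert starling_resistor_flow(5.0, 2.0, 12.0, 1.0) == 0.0

    def test_rejects_nonpositive_resistance(self):
        with pytest.raises(InvalidParameterError):
            starling_resistor_flow(10.0, 5.0, 0.0, 0.0)


class TestNetworkDerivatives:
    def test_instantaneous_blood_mass_conservation(self):
        cfg = packaged_scenario("hf")
        p = build_params(cfg)
        y0 = initial_state(cfg, p)
        dy = network_derivatives(y0, p)
        assert abs(np.sum(dy[:14])) < 1e-9  # all volume states

    def test_nonfinite_state_names_offending_component(self):
        cfg = packaged_scenario("hf")
        p = build_params(cfg)
        y0 = initial_state(cfg, p)
        y0[1] = np.nan  # v_lv
        with pytest.raises(IntegrationError, match="v_lv"):
            network_derivatives(y0, p)
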