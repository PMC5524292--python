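import numpy as np
import pytest

from cardioresp import (BloodGasParams, InvalidInputError,
                        InvalidParameterError, MechanicsParams,
                        VentilationParams, alveolar_derivatives,
                        breathing_pattern, co2_content, co2_tension,
                        expiratory_flow, fick_cardiac_output,
                        lung_gas_exchange, o2_content, o2_tension,
                        pleural_pressure, tissue_gas_exchange,
                        ventilation_demand)

BLOOD = BloodGasParams()
VENT = VentilationParams()
MECH = MechanicsParams()


class TestO2Carriage:
    def test_half_saturation_at_p50(self):
        # at P50 the bound fraction is exactly half of capacity
        cap = o2_content(3000.0, BLOOD)  # asymptotic: fully saturated
        bound_half = o2_content(BLOOD.p50, BLOOD)
        dissolved = 0.003 * BLOOD.p50
        assert bound_half - dissolved == pytest.approx(
            (cap - 0.003 * 3000.0) / 2.0, rel=0.01)

    def test_content_tension_round_trip(self):
        for po2 in (25.0, 40.0, 70.0, 95.0):
            c = o2_content(po2, BLOOD)
            assert o2_tension(c, BLOOD) == pytest.approx(po2, rel=1e-6)

    def test_monotone_in_tension(self):
        po2 = np.linspace(5.0, 150.0, 60)
        c = np.array([o2_content(x, BLOOD) for x in po2])
        assert np.all(np.diff(c) > 0)

    def test_rejects_negative_inputs(self):
        with pytest.raises(InvalidInputError):
            o2_content(-1.0, BLOOD)
        with pytest.raises(InvalidInputError):
            o2_tension(-1.0, BLOOD)


class TestCO2Carriage:
    def test_linear_relation_anchored_at_40mmhg(self):
        assert co2_content(40.0, BLOOD) == pytest.approx(48.0)
        assert co2_content(45.0, BLOOD) == pytest.approx(48.0 + 5 * 0.45)

    def test_round_trip(self):
        for pco2 in (30.0, 40.0, 55.0):
            assert co2_tension(co2_content(pco2, BLOOD), BLOOD) == \
                pytest.approx(pco2)

    def test_rejects_negative_tension(self):
        with pytest.raises(InvalidInputError):
            co2_content(-5.0, BLOOD)


class TestTissueExchange:
    def test_uptake_meets_demand_when_supply_ample(self):
        u, dcv = tissue_gas_exchange(q_mls=60.0, ca_o2_mldl=19.0,
                                     cv_o2_mldl=14.0, demand_mlmin=250.0,
                                     store_ml=500.0)
        assert u == pytest.approx(250.0)

    def test_uptake_is_supply_limited(self):
        u, _ = tissue_gas_exchange(q_mls=5.0, ca_o2_mldl=19.0,
                                   cv_o2_mldl=1.0, demand_mlmin=500.0,
                                   store_ml=500.0)
        assert u == pytest.approx(0.97 * 5.0 * 19.0 / 100.0 * 60.0)

    def test_venous_store_balance_sign(self):
        # extraction below the inflow difference refills the store
        _, dcv = tissue_gas_exchange(q_mls=60.0, ca_o2_mldl=19.0,
                                     cv_o2_mldl=10.0, demand_mlmin=100.0,
                                     store_ml=500.0)
        assert dcv > 0.0

    def test_rejects_bad_inputs(self):
        with pytest.raises(InvalidInputError):
            tissue_gas_exchange(-1.0, 19.0, 10.0, 100.0, 500.0)
        with pytest.raises(InvalidInputError):
            tissue_gas_exchange(10.0, 19.0, 10.0, 100.0, 0.0)


class TestLungExchange:
    def test_fluxes_have_physiological_signs(self):
        vo2, vco2 = lung_gas_exchange(80.0, cmv_o2_mldl=14.0,
                                      cmv_co2_mldl=52.0, pa_o2=100.0,
                                      pa_co2=40.0, blood=BLOOD)
        assert vo2 > 0.0 and vco2 > 0.0

    def test_equilibrated_blood_exchanges_nothing(self):
        ceq_o2 = o2_content(100.0, BLOOD)
        ceq_co2 = co2_content(40.0, BLOOD)
        vo2, vco2 = lung_gas_exchange(80.0, ceq_o2, ceq_co2, 100.0, 40.0,
                                      BLOOD)
        assert vo2 == pytest.approx(0.0, abs=1e-9)
        assert vco2 == pytest.approx(0.0, abs=1e-9)

    def test_rejects_negative_flow(self):
        with pytest.raises(InvalidInputError):
            lung_gas_exchange(-1.0, 14.0, 52.0, 100.0, 40.0, BLOOD)


class TestAlveolarGas:
    def test_steady_state_balance(self):
        # VA*(PIO2 - PAO2) = 0.863 * VO2  ->  dPAO2/dt = 0
        vo2 = 250.0
        va = 0.863 * vo2 / (150.0 - 100.0)
        dpo2, _ = alveolar_derivatives(100.0, 40.0, va, vo2, 200.0)
        assert dpo2 == pytest.approx(0.0, abs=1e-12)

    def test_co2_accumulates_when_unventilated(self):
        _, dpco2 = alveolar_derivatives(100.0, 40.0, 0.0, 250.0, 200.0)
        assert dpco2 > 0.0

    def test_rejects_bad_inputs(self):
        with pytest.raises(InvalidInputError):
            alveolar_derivatives(100.0, 40.0, -1.0, 250.0, 200.0)


class TestVentilationControl:
    def test_resting_command_at_set_point(self):
        ve = ventilation_demand(VENT, paco2_art=40.0, vco2_mlmin=200.0,
                                pao2_art=95.0)
        assert ve == pytest.approx(VENT.ve_rest)

    def test_hypercapnia_feedforward_and_hypoxia_raise_ventilation(self):
        base = ventilation_demand(VENT, 40.0, 200.0, 95.0)
        assert ventilation_demand(VENT, 45.0, 200.0, 95.0) > base
        assert ventilation_demand(VENT, 40.0, 1000.0, 95.0) > base
        assert ventilation_demand(VENT, 40.0, 200.0, 55.0) > base

    def test_breathing_pattern_partition(self):
        f, vt, va = breathing_pattern(33.0, VENT)
        assert f * vt == pytest.approx(33.0)
        assert va == pytest.approx((vt - VENT.dead_space) * f)
        assert f > VENT.f0

    def test_breathing_pattern_rejects_nonpositive_ve(self):
        with pytest.raises(InvalidInputError):
            breathing_pattern(0.0, VENT)


class TestMechanics:
    def test_pleural_swing_tracks_tidal_volume(self):
        p0 = pleural_pressure(0.0, 0.6, 14.0, MECH)
        p_end_insp = pleural_pressure(MECH.ti_frac - 1e-9, 0.6, 14.0, MECH)
        assert p0 == pytest.approx(MECH.ppl0)
        assert p_end_insp == pytest.approx(MECH.ppl0 - MECH.echest * 0.6,
                                           rel=1e-6)

    def test_expiration_decays_toward_baseline(self):
        p1 = pleural_pressure(0.5, 0.6, 14.0, MECH)
        p2 = pleural_pressure(0.9, 0.6, 14.0, MECH)
        assert MECH.ppl0 - MECH.echest * 0.6 < p1 < p2 <= MECH.ppl0

    def test_expiratory_flow_is_recoil_over_resistance(self):
        assert expiratory_flow(0.5, MECH) == pytest.approx(8.0 * 0.5 / 2.0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(InvalidInputError):
            pleural_pressure(1.0, 0.6, 14.0, MECH)
        with pytest.raises(InvalidInputError):
            expiratory_flow(-0.1, MECH)
        with pytest.raises(InvalidParameterError):
            MechanicsParams(ti_frac=1.5)


class TestFick:
    def test_cardiac_output_from_fick_principle(self):
        # VO2 = 259 ml/min, avO2 = 7 ml/dl -> CO = 3.7 l/min
        assert fick_cardiac_output(259.0, 19.0, 12.0) == \
            pytest.approx(259.0 / 70.0)

    def test_rejects_nonpositive_av_difference(self):
        with pytest.raises(InvalidInputError):
            fick_cardiac_output(250.0, 12.0, 12.0)
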