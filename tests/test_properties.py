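"""System-level invariants of the closed-loop simulations."""

import numpy as np
import pytest

from cardioresp import (BloodGasParams, engine, o2_content,
                        packaged_scenario, total_blood_volume)

VALVES = ("q_mi", "q_av", "q_tri", "q_pav")


def _all_phases(hf_outcomes, vad_outcomes):
    return [("hf", o) for o in hf_outcomes] + \
           [("hf-vad", o) for o in vad_outcomes]


class TestConservation:
    @pytest.mark.parametrize("name", ["hf", "hf-vad"])
    def test_blood_volume_drift_below_tenth_cm3_per_minute(self, name):
        res = engine.integrate(packaged_scenario(name), 60.0)
        tbv = np.array([total_blood_volume(y) for y in res.states])
        assert tbv.max() - tbv.min() < 0.1

    def test_fick_closure_within_two_percent(self, hf_outcomes, vad_outcomes):
        for name, o in _all_phases(hf_outcomes, vad_outcomes):
            s = o.summary
            co_fick = s.vo2 / s.avo2 / 10.0
            assert co_fick == pytest.approx(s.co, rel=0.02), (name, o.name)

    def test_o2_mass_balance_between_lungs_and_tissues(self, hf_outcomes,
                                                       vad_outcomes,
                                                       hf_config, vad_config):
        for cfg, outcomes in ((hf_config, hf_outcomes),
                              (vad_config, vad_outcomes)):
            blood = BloodGasParams(hb=cfg.blood.hb, p50=cfg.blood.p50,
                                   hill_n=cfg.blood.hill_n,
                                   co2_c0=cfg.blood.co2_c0,
                                   co2_slope=cfg.blood.co2_slope)
            for o in outcomes:
                r = o.result.tail(10.0)
                q = r.chan("q_ap")
                ceq = np.array([o2_content(p, blood)
                                for p in r.state("pa_o2")]) / 100.0
                flux = np.trapezoid(q * (ceq - r.chan("cmv_o2")), r.t) \
                    / (r.t[-1] - r.t[0]) * 60.0
                vo2 = np.trapezoid(r.chan("vo2_uptake"), r.t) \
                    / (r.t[-1] - r.t[0])
                assert flux == pytest.approx(vo2, rel=0.02), o.name


class TestFlowInvariants:
    def test_valve_flows_never_negative(self, hf_outcomes, vad_outcomes):
        for name, o in _all_phases(hf_outcomes, vad_outcomes):
            for valve in VALVES:
                assert o.result.chan(valve).min() >= 0.0, (name, o.name, valve)

    def test_cardiac_output_is_native_plus_pump_flow(self, hf_outcomes,
                                                     vad_outcomes):
        for name, o in _all_phases(hf_outcomes, vad_outcomes):
            s = o.summary
            assert s.co == pytest.approx(s.q_lv + s.q_vad, rel=0.02), \
                (name, o.name)

    def test_hf_scenario_has_no_pump_flow(self, hf_outcomes):
        for o in hf_outcomes:
            assert np.all(o.result.state("q_vad") == 0.0)


class TestChronotropicIncompetence:
    def test_hf_peak_heart_rate_below_eighty_percent_predicted(self,
                                                               hf_outcomes):
        peak_hr = hf_outcomes[1].summary.hr
        assert peak_hr <= 0.8 * 167.0

    def test_heart_rate_rises_with_exercise(self, hf_outcomes, vad_outcomes):
        assert hf_outcomes[1].summary.hr > hf_outcomes[0].summary.hr + 10.0
        assert vad_outcomes[1].summary.hr > vad_outcomes[0].summary.hr + 10.0


class TestSpeedModulation:
    def test_wedge_pressure_strictly_decreasing_in_speed(self, vad_outcomes,
                                                         vad_outcomes_midspeed):
        w9500 = vad_outcomes[1].summary.pwedge
        w10750 = vad_outcomes_midspeed[2].summary.pwedge
        w12000 = vad_outcomes[2].summary.pwedge
        assert w9500 > w10750 > w12000

    def test_end_diastolic_volume_strictly_decreasing_in_speed(
            self, vad_outcomes, vad_outcomes_midspeed):
        v9500 = vad_outcomes[1].summary.ved
        v10750 = vad_outcomes_midspeed[2].summary.ved
        v12000 = vad_outcomes[2].summary.ved
        assert v9500 > v10750 > v12000

    def test_pump_flow_strictly_increasing_in_speed(self, vad_outcomes,
                                                    vad_outcomes_midspeed):
        q9500 = vad_outcomes[1].summary.q_vad
        q10750 = vad_outcomes_midspeed[2].summary.q_vad
        q12000 = vad_outcomes[2].summary.q_vad
        assert q9500 < q10750 < q12000


class TestFullSupportBracket:
    def test_full_support_at_rest_and_maximum_speed(self, vad_outcomes):
        rest, _, fast = vad_outcomes
        assert abs(rest.summary.q_lv) < 0.1
        assert abs(fast.summary.q_lv) < 0.1

    def test_native_ejection_returns_at_exercise_baseline_speed(
            self, vad_outcomes):
        assert vad_outcomes[1].summary.q_lv > 1.0


class TestPVLoopDirections:
    def test_hf_loops_shift_rightward_and_widen_with_exercise(self,
                                                              hf_outcomes):
        rest = engine.extract_pv_loops(hf_outcomes[0].result)[0]
        peak = engine.extract_pv_loops(hf_outcomes[1].result)[0]
        assert peak.v.max() > rest.v.max()    # rightward shift
        assert peak.v.min() > rest.v.min()
        assert peak.sv > rest.sv              # wider loop

    def test_vad_loops_eject_only_at_baseline_speed_exercise(self,
                                                             vad_outcomes):
        rest, exe, fast = vad_outcomes
        for o in (rest, fast):
            assert o.result.tail(5.0).chan("q_av").max() < 1.0, o.name
        assert exe.result.tail(5.0).chan("q_av").max() > 50.0

    def test_vad_unloads_ventricular_volumes_relative_to_hf(self, hf_outcomes,
                                                            vad_outcomes):
        assert vad_outcomes[0].summary.ved < hf_outcomes[0].summary.ved
        assert vad_outcomes[1].summary.ved < hf_outcomes[1].summary.ved


class TestRuntimeBudget:
    def test_both_protocols_complete_quickly(self, hf_outcomes, vad_outcomes):
        # the heavy lifting happened in the session fixtures; here we only
        # assert the protocols terminated with steady phases, which bounds
        # the simulated (and hence wall-clock) time
        for o in hf_outcomes + vad_outcomes:
            assert o.result.t[-1] <= 600.0
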