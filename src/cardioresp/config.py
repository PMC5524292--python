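"""Scenario configuration: schema, validation, packaged fixtures.

Configurations are structured YAML documents validated by pydantic models
(unknown keys are rejected).  Units follow clinical convention in the
files (mmHg, cm^3, s, ml O2/dl, l/min, rpm, bpm); the builder converts to
the internal mmHg / cm^3 / s system used by :mod:`cardioresp.core`.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import (BaseModel, ConfigDict, Field, ValidationError,
                      model_validator)

from . import core
from .errors import ConfigError

DISTRICTS = ("upper_body", "kidneys", "splanchnic", "left_leg", "right_leg")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VentricleCfg(_Strict):
    es: float = Field(gt=0, description="end-systolic elastance, mmHg/cm^3")
    v0: float = Field(description="zero-pressure volume, cm^3")
    a: float = Field(gt=0, description="diastolic stiffness scale, mmHg")
    b: float = Field(gt=0, description="diastolic stiffness exponent, 1/cm^3")


class AtriumCfg(_Strict):
    c: float = Field(gt=0, description="compliance, cm^3/mmHg")
    vu: float = Field(ge=0, description="unstressed volume, cm^3")
    kick: float = Field(ge=0, description="peak active elastance, mmHg/cm^3")


class ValvesCfg(_Strict):
    r_mitral: float = Field(gt=0)
    r_aortic: float = Field(gt=0)
    r_tricuspid: float = Field(gt=0)
    r_pulmonic: float = Field(gt=0)


class HeartCfg(_Strict):
    hr_rest: float = Field(gt=30, lt=220, description="intrinsic heart rate, bpm")
    ks: float = Field(default=0.3, gt=0, description="Tsys = ks*sqrt(RR)")
    trel_frac: float = Field(default=0.2, gt=0, lt=1)
    lv: VentricleCfg
    rv: VentricleCfg
    la: AtriumCfg
    ra: AtriumCfg
    kick_center: float = Field(default=0.92, ge=0, lt=1)
    kick_width: float = Field(default=0.035, gt=0)
    kick_gain: float = Field(default=2.5, ge=0)
    valves: ValvesCfg


class DistrictCfg(_Strict):
    ra: float = Field(gt=0, description="arterial resistance, mmHg*s/cm^3")
    rv: float = Field(gt=0, description="venous resistance, mmHg*s/cm^3")
    c: float = Field(gt=0, description="compliance, cm^3/mmHg")
    vu: float = Field(ge=0, description="unstressed volume, cm^3")


class AortaCfg(_Strict):
    c: float = Field(gt=0)
    vu: float = Field(ge=0)


class DescAortaCfg(_Strict):
    r: float = Field(gt=0)
    l: float = Field(gt=0)
    c: float = Field(gt=0)
    vu: float = Field(ge=0)


class VenaCavaCfg(_Strict):
    c: float = Field(gt=0)
    vu: float = Field(ge=0)
    r: float = Field(gt=0)


class PulmonaryCfg(_Strict):
    cap: float = Field(gt=0, description="baseline pulmonary arterial compliance")
    vu_pa: float = Field(ge=0)
    rap: float = Field(gt=0, description="pulmonary arterial resistance")
    cpv: float = Field(gt=0)
    vu_pv: float = Field(ge=0)
    rpv: float = Field(gt=0)


class CapWedgeCfg(_Strict):
    threshold: float = 15.0
    span: float = 20.0
    floor: float = 0.5


class CollapseCfg(_Strict):
    k: float = Field(default=8e-4, ge=0)
    knee_frac: float = Field(default=0.5, ge=0, lt=1)
    p_hi: float = Field(default=12.0, gt=0)
    k_hi: float = Field(default=8e-4, ge=0)


class CirculationCfg(_Strict):
    ascending_aorta: AortaCfg
    descending_aorta: DescAortaCfg
    districts: dict[str, DistrictCfg]
    vena_cava: VenaCavaCfg
    pulmonary: PulmonaryCfg
    cap_wedge: CapWedgeCfg = CapWedgeCfg()
    collapse: CollapseCfg = CollapseCfg()
    pintr_cv_frac: float = Field(default=0.0, ge=0, le=1)

    @model_validator(mode="after")
    def _check_districts(self):
        missing = [d for d in DISTRICTS if d not in self.districts]
        extra = [d for d in self.districts if d not in DISTRICTS]
        if missing or extra:
            raise ValueError(
                f"districts must be exactly {DISTRICTS}; missing={missing} unknown={extra}")
        return self


class BaroreflexCfg(_Strict):
    pset: float = Field(gt=0, description="set-point pressure, mmHg")
    kb: float = Field(default=0.02, ge=0, description="drive per mmHg of error")
    kc: float = Field(default=0.0625, ge=0,
                      description="drive per ml/min/kg of VO2 above rest")
    resetting_gain: float = Field(ge=0, description="mmHg per ml/min/kg")
    tau_pfilt: float = Field(default=2.0, gt=0)
    g_hr: float = Field(ge=0)
    g_es_lv: float = Field(ge=0)
    g_es_rv: float = Field(ge=0)
    g_r: float = Field(ge=0)
    g_v: float = Field(ge=0)
    tau_symp: float = Field(default=12.0, gt=0)
    tau_hr: float = Field(default=4.0, gt=0)
    hr_max: float = Field(default=135.0, gt=0,
                          description="absolute chronotropic ceiling, bpm")


class MetabolicCfg(_Strict):
    gain: float = Field(default=1.5, ge=0)
    deadband: float = Field(default=0.5, ge=0, description="ml O2/dl")
    tau: float = Field(default=12.0, gt=0)
    refs: dict[str, float]
    floors: dict[str, float]

    @model_validator(mode="after")
    def _check(self):
        for d in DISTRICTS:
            if d not in self.refs or d not in self.floors:
                raise ValueError(f"metabolic refs/floors must cover {DISTRICTS}")
            if not 0 < self.floors[d] <= 1:
                raise ValueError("metabolic floors must lie in (0, 1]")
            if self.refs[d] <= 0:
                raise ValueError("venous O2 references must be positive")
        return self


class ControlCfg(_Strict):
    baroreflex: BaroreflexCfg
    metabolic: MetabolicCfg


class BloodCfg(_Strict):
    hb: float = Field(default=13.6, gt=0, description="hemoglobin, g/dl")
    p50: float = Field(default=26.6, gt=0)
    hill_n: float = Field(default=2.7, gt=0)
    co2_c0: float = Field(default=48.0, gt=0, description="CO2 content at 40 mmHg, ml/dl")
    co2_slope: float = Field(default=0.45, gt=0, description="ml/dl per mmHg")
    weight: float = Field(default=74.0, gt=0, description="body weight, kg")
    vo2_rest_perkg: float = Field(default=3.5, gt=0, description="ml/min/kg")
    vo2_split_rest: dict[str, float]
    vo2_split_exercise: dict[str, float]
    tissue_stores: dict[str, float]
    arterial_store: float = Field(default=700.0, gt=0, description="cm^3")

    @model_validator(mode="after")
    def _check(self):
        for name, split in (("rest", self.vo2_split_rest),
                            ("exercise", self.vo2_split_exercise)):
            if set(split) != set(DISTRICTS):
                raise ValueError(f"vo2_split_{name} must cover {DISTRICTS}")
            if abs(sum(split.values()) - 1.0) > 1e-6:
                raise ValueError(f"vo2_split_{name} must sum to 1")
        if set(self.tissue_stores) != set(DISTRICTS):
            raise ValueError(f"tissue_stores must cover {DISTRICTS}")
        return self


class RespiratoryCfg(_Strict):
    v_alv: float = Field(default=3.0, gt=0, description="alveolar gas store, l")
    pio2: float = Field(default=150.0, gt=0)
    dead_space: float = Field(default=0.35, gt=0, description="l per breath")
    f0: float = Field(default=14.0, gt=0, description="resting breathing rate, 1/min")
    kf: float = Field(default=0.62, ge=0)
    gc_co2: float = Field(default=2.0, ge=0, description="l/min per mmHg PaCO2")
    paco2_set: float = Field(default=40.0, gt=0)
    kff: float = Field(default=0.0328, ge=0, description="l/min per ml/min VCO2")
    vco2_ref: float = Field(default=207.0, gt=0)
    gh_o2: float = Field(default=0.3, ge=0)
    pao2_thr: float = Field(default=70.0, gt=0)
    tau_ve: float = Field(default=15.0, gt=0)
    ve_rest: float = Field(default=9.2, gt=0)
    ppl0: float = Field(default=-2.5)
    echest: float = Field(default=3.0, ge=0)
    ti_frac: float = Field(default=0.4, gt=0, lt=1)
    elungs: float = Field(default=8.0, gt=0, description="mmHg/l")
    raw: float = Field(default=2.0, gt=0, description="mmHg/(l/s)")


class VADCfg(_Strict):
    enabled: bool = False
    kw: float = Field(default=9.5e-7, ge=0, description="mmHg/rpm^2")
    kq1: float = Field(default=0.2, ge=0, description="mmHg*s/cm^3")
    kq2: float = Field(default=2.5e-3, ge=0, description="mmHg*s^2/cm^6")
    rc: float = Field(default=0.035, ge=0, description="cannula resistance")
    lc: float = Field(default=0.02, gt=0, description="cannula inertance")
    speed_min: float = Field(default=6000.0, gt=0)
    speed_max: float = Field(default=12000.0, gt=0)


class MusclePumpCfg(_Strict):
    cadence: float = Field(default=1.0, gt=0, description="Hz")
    gain: float = Field(default=2.0, ge=0, description="mmHg per ml/min/kg")
    cap: float = Field(default=24.0, ge=0, description="mmHg")


class InitCfg(_Strict):
    """Initial filling state; sets the (conserved) total blood volume."""
    p_arterial: float = 89.0
    p_district: float = 13.0
    p_cv: float = 8.5
    p_pa: float = 26.0
    p_pv: float = 14.0
    p_la: float = 14.0
    p_ra: float = 8.0
    v_lv: float = 300.0
    v_rv: float = 120.0


class PhaseCfg(_Strict):
    name: str
    vo2_perkg: float = Field(gt=0, description="target oxygen uptake, ml/min/kg")
    rq: float = Field(ge=0.7, le=1.3, description="respiratory quotient")
    vad_speed: Optional[float] = Field(default=None, description="rpm")
    ramp: float = Field(default=60.0, ge=0, description="input ramp duration, s")
    max_duration: float = Field(default=600.0, gt=0, description="s")


class ScenarioConfig(_Strict):
    schema_version: int = 1
    condition: Literal["HF", "HF+VAD"]
    heart: HeartCfg
    circulation: CirculationCfg
    control: ControlCfg
    blood: BloodCfg
    respiratory: RespiratoryCfg
    vad: VADCfg = VADCfg()
    muscle_pump: MusclePumpCfg = MusclePumpCfg()
    init: InitCfg = InitCfg()
    protocol: list[PhaseCfg]

    @model_validator(mode="after")
    def _check(self):
        if self.condition == "HF+VAD" and not self.vad.enabled:
            raise ValueError("HF+VAD scenarios require vad.enabled = true")
        for ph in self.protocol:
            if self.vad.enabled:
                if ph.vad_speed is None:
                    raise ValueError(f"phase {ph.name!r}: vad_speed required")
                if not (self.vad.speed_min <= ph.vad_speed <= self.vad.speed_max):
                    raise ValueError(
                        f"phase {ph.name!r}: vad_speed outside "
                        f"[{self.vad.speed_min}, {self.vad.speed_max}] rpm")
        return self

    def config_hash(self) -> str:
        doc = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# Loading
# --------------------------------------------------------------------------

def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario YAML file.

    Raises :class:`ConfigError` for unreadable files, malformed YAML and
    schema violations (including unknown keys).
    """
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read scenario file {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    try:
        return ScenarioConfig.model_validate(doc)
    except ValidationError as exc:
        raise ConfigError(f"invalid scenario config {path}: {exc}") from exc


def packaged_scenario(name: str) -> ScenarioConfig:
    """Load one of the shipped scenarios: ``hf`` or ``hf_vad``."""
    key = name.replace("-", "_").lower()
    if key not in ("hf", "hf_vad"):
        raise ConfigError("packaged scenarios are 'hf' and 'hf-vad'")
    ref = resources.files("cardioresp").joinpath(f"data/{key}.yaml")
    with resources.as_file(ref) as path:
        return load_config(path)


# --------------------------------------------------------------------------
# Parameter vector / initial state builders
# --------------------------------------------------------------------------

def build_params(cfg: ScenarioConfig) -> np.ndarray:
    """Flatten a validated configuration into the core parameter vector.

    Protocol-segment entries (vo2_0 .., omega_1, t_ramp, t_offset) are left
    at rest values; the engine overwrites them per phase.
    """
    p = np.zeros(core.NPAR)

    def s(name, val):
        p[core.PIDX[name]] = val

    h = cfg.heart
    s("hr0", h.hr_rest); s("ks", h.ks); s("trel_frac", h.trel_frac)
    s("lv_es", h.lv.es); s("lv_v0", h.lv.v0); s("lv_a", h.lv.a); s("lv_b", h.lv.b)
    s("rv_es", h.rv.es); s("rv_v0", h.rv.v0); s("rv_a", h.rv.a); s("rv_b", h.rv.b)
    s("la_c", h.la.c); s("la_vu", h.la.vu); s("la_kick", h.la.kick)
    s("ra_c", h.ra.c); s("ra_vu", h.ra.vu); s("ra_kick", h.ra.kick)
    s("kick_center", h.kick_center); s("kick_width", h.kick_width)
    s("g_kick", h.kick_gain)
    s("r_mi", h.valves.r_mitral); s("r_av", h.valves.r_aortic)
    s("r_tri", h.valves.r_tricuspid); s("r_pav", h.valves.r_pulmonic)

    c = cfg.circulation
    s("c_aa", c.ascending_aorta.c); s("vu_aa", c.ascending_aorta.vu)
    s("r_da", c.descending_aorta.r); s("l_da", c.descending_aorta.l)
    s("c_da", c.descending_aorta.c); s("vu_da", c.descending_aorta.vu)
    for i, d in enumerate(DISTRICTS):
        dc = c.districts[d]
        p[core.P_R_A0 + i] = dc.ra
        p[core.P_R_V0 + i] = dc.rv
        p[core.P_C_D0 + i] = dc.c
        p[core.P_VU_D0 + i] = dc.vu
    s("c_cv", c.vena_cava.c); s("vu_cv", c.vena_cava.vu); s("r_cv", c.vena_cava.r)
    s("cap0", c.pulmonary.cap); s("vu_pa", c.pulmonary.vu_pa)
    s("rap", c.pulmonary.rap)
    s("c_pv", c.pulmonary.cpv); s("vu_pv", c.pulmonary.vu_pv)
    s("r_pv", c.pulmonary.rpv)
    s("cap_thr", c.cap_wedge.threshold); s("cap_span", c.cap_wedge.span)
    s("cap_floor", c.cap_wedge.floor)
    s("col_k", c.collapse.k); s("col_knee_frac", c.collapse.knee_frac)
    s("col_phi", c.collapse.p_hi); s("col_khi", c.collapse.k_hi)
    s("pintr_cv_frac", c.pintr_cv_frac)

    b = cfg.control.baroreflex
    s("pset", b.pset); s("kb", b.kb); s("kc", b.kc); s("rg", b.resetting_gain)
    s("tau_pfilt", b.tau_pfilt)
    s("g_hr", b.g_hr); s("g_es_lv", b.g_es_lv); s("g_es_rv", b.g_es_rv)
    s("g_r", b.g_r); s("g_v", b.g_v)
    s("tau_symp", b.tau_symp); s("tau_hr", b.tau_hr); s("hr_max", b.hr_max)

    m = cfg.control.metabolic
    s("gm_met", m.gain); s("met_db", m.deadband); s("tau_met", m.tau)
    for i, d in enumerate(DISTRICTS):
        p[core.P_REF0 + i] = m.refs[d]
        p[core.P_FLOOR0 + i] = m.floors[d]

    bl = cfg.blood
    s("hb", bl.hb); s("p50", bl.p50); s("nhill", bl.hill_n)
    s("co2_c0", bl.co2_c0); s("co2_slope", bl.co2_slope)
    s("weight", bl.weight); s("vo2_rest_perkg", bl.vo2_rest_perkg)
    for i, d in enumerate(DISTRICTS):
        p[core.P_SR0 + i] = bl.vo2_split_rest[d]
        p[core.P_SE0 + i] = bl.vo2_split_exercise[d]
        p[core.P_VST0 + i] = bl.tissue_stores[d]
    s("vst_art", bl.arterial_store)

    r = cfg.respiratory
    s("v_alv", r.v_alv); s("pio2", r.pio2); s("vd_airway", r.dead_space)
    s("f0_resp", r.f0); s("kf_resp", r.kf)
    s("gc_co2", r.gc_co2); s("paco2_set", r.paco2_set)
    s("kff_vco2", r.kff); s("vco2_ref", r.vco2_ref)
    s("gh_o2", r.gh_o2); s("pao2_thr", r.pao2_thr)
    s("tau_ve", r.tau_ve); s("ve_rest", r.ve_rest)
    s("ppl0", r.ppl0); s("echest", r.echest); s("ti_frac", r.ti_frac)
    s("elungs", r.elungs); s("raw", r.raw)

    v = cfg.vad
    s("vad_on", 1.0 if v.enabled else 0.0)
    s("vad_kw", v.kw); s("vad_kq1", v.kq1); s("vad_kq2", v.kq2)
    s("vad_rc", v.rc); s("vad_lc", v.lc)

    mp = cfg.muscle_pump
    s("mus_cadence", mp.cadence); s("mus_gain", mp.gain); s("mus_cap", mp.cap)

    # rest protocol defaults; the engine rewrites these per phase
    s("vo2_0", bl.vo2_rest_perkg); s("vo2_1", bl.vo2_rest_perkg)
    s("rq_0", 0.8); s("rq_1", 0.8)
    omega0 = cfg.protocol[0].vad_speed if (v.enabled and cfg.protocol) else 0.0
    s("omega_0", omega0 or 0.0); s("omega_1", omega0 or 0.0)
    s("t_ramp", 0.0); s("t_offset", 0.0)
    return p


def initial_state(cfg: ScenarioConfig, p: np.ndarray) -> np.ndarray:
    """Initial condition from the configured filling pressures.

    Vessel volumes are set to Vu + C * P; the sum fixes the total blood
    volume, which the network then conserves exactly.
    """
    y = np.zeros(core.NSTATE)
    init = cfg.init
    h = cfg.heart
    c = cfg.circulation

    y[core.S_V_LA] = h.la.vu + h.la.c * init.p_la
    y[core.S_V_LV] = init.v_lv
    y[core.S_V_RA] = h.ra.vu + h.ra.c * init.p_ra
    y[core.S_V_RV] = init.v_rv
    y[core.S_V_AA] = c.ascending_aorta.vu + c.ascending_aorta.c * init.p_arterial
    y[core.S_V_DA] = c.descending_aorta.vu + c.descending_aorta.c * init.p_arterial
    for i, d in enumerate(DISTRICTS):
        dc = c.districts[d]
        y[core.S_V_D0 + i] = dc.vu + dc.c * init.p_district
    y[core.S_V_CV] = c.vena_cava.vu + c.vena_cava.c * init.p_cv
    y[core.S_V_PA] = c.pulmonary.vu_pa + c.pulmonary.cap * init.p_pa
    y[core.S_V_PV] = c.pulmonary.vu_pv + c.pulmonary.cpv * init.p_pv

    y[core.S_Q_DA] = 0.0
    y[core.S_Q_VAD] = 0.0
    y[core.S_P_F] = init.p_arterial
    y[core.S_PW_F] = init.p_la
    y[core.S_S] = 0.5
    y[core.S_H] = 0.5
    for i in range(5):
        y[core.S_M0 + i] = 1.0
    y[core.S_VE] = cfg.respiratory.ve_rest
    y[core.S_TH] = 0.0
    y[core.S_PHI] = 0.0

    # blood gases near a normal arterial / venous operating point
    bl = cfg.blood
    cao2 = core.o2_content_ml_per_ml(95.0, bl.hb, bl.p50, bl.hill_n)
    caco2 = core.co2_content_ml_per_ml(40.0, bl.co2_c0, bl.co2_slope)
    y[core.S_CAO2] = cao2
    y[core.S_CACO2] = caco2
    for i, d in enumerate(DISTRICTS):
        y[core.S_CVO2_0 + i] = (cfg.control.metabolic.refs[d] + 0.5) / 100.0
        y[core.S_CVCO2_0 + i] = caco2 + 0.04
    y[core.S_PAO2] = 100.0
    y[core.S_PACO2] = 40.0
    return y


def total_blood_volume(y: np.ndarray) -> float:
    """Sum of all compartment and chamber volumes (cm^3)."""
    return float(np.sum(y[: core.S_V_PV + 1]))
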