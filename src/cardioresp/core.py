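"""Numerical core of the cardiorespiratory simulator.

Everything in this module is numba-jitted and operates on flat float64
arrays: a parameter vector ``p`` (see :data:`PARAM_NAMES`) and a state
vector ``y`` (see :data:`STATE_NAMES`).  Higher-level modules build these
vectors from validated configuration objects and wrap the raw outputs in
friendly containers.

Internal unit system: pressures in mmHg, volumes in cm^3, time in s,
flows in cm^3/s, gas contents in ml gas per ml blood, partial pressures
in mmHg, ventilation in l/min.  The model is fully deterministic: a
fixed-step classical Runge-Kutta scheme is used, so identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --------------------------------------------------------------------------
# Parameter vector layout
# --------------------------------------------------------------------------

PARAM_NAMES = (
    # cardiac timing and chambers
    "hr0", "ks", "trel_frac",
    "lv_es", "lv_v0", "lv_a", "lv_b",
    "rv_es", "rv_v0", "rv_a", "rv_b",
    "la_c", "la_vu", "la_kick",
    "ra_c", "ra_vu", "ra_kick",
    "kick_center", "kick_width", "g_kick",
    "r_mi", "r_av", "r_tri", "r_pav",
    # systemic arterial tree
    "c_aa", "vu_aa", "r_da", "l_da", "c_da", "vu_da",
    # district arterial / venous resistances
    "r_ub_a", "r_kid_a", "r_sp_a", "r_ll_a", "r_rl_a",
    "r_ub_v", "r_kid_v", "r_sp_v", "r_ll_v", "r_rl_v",
    # district compliances and unstressed volumes
    "c_ub", "c_kid", "c_sp", "c_ll", "c_rl",
    "vu_ub", "vu_kid", "vu_sp", "vu_ll", "vu_rl",
    # central veins and pulmonary circulation
    "c_cv", "vu_cv", "r_cv",
    "cap0", "vu_pa", "rap", "c_pv", "vu_pv", "r_pv",
    "cap_thr", "cap_span", "cap_floor",
    # venous collapse / distension nonlinearity
    "col_k", "col_knee_frac", "col_phi", "col_khi",
    "pintr_cv_frac",
    # baroreflex / autonomic control
    "pset", "kb", "kc", "rg", "tau_pfilt",
    "g_hr", "g_es_lv", "g_es_rv", "g_r", "g_v",
    "tau_symp", "tau_hr", "hr_max",
    # metabolic control
    "gm_met", "met_db",
    "floor_ub", "floor_kid", "floor_sp", "floor_ll", "floor_rl",
    "tau_met",
    "ref_ub", "ref_kid", "ref_sp", "ref_ll", "ref_rl",
    # blood gas / metabolism
    "hb", "p50", "nhill", "co2_c0", "co2_slope",
    "weight", "vo2_rest_perkg",
    "sr_ub", "sr_kid", "sr_sp", "sr_ll", "sr_rl",
    "se_ub", "se_kid", "se_sp", "se_ll", "se_rl",
    "vst_ub", "vst_kid", "vst_sp", "vst_ll", "vst_rl", "vst_art",
    # ventilation
    "v_alv", "pio2", "vd_airway", "f0_resp", "kf_resp",
    "gc_co2", "paco2_set", "kff_vco2", "vco2_ref",
    "gh_o2", "pao2_thr", "tau_ve", "ve_rest",
    "ppl0", "echest", "ti_frac", "elungs", "raw",
    # VAD
    "vad_on", "vad_kw", "vad_kq1", "vad_kq2", "vad_rc", "vad_lc",
    # leg muscle pump
    "mus_cadence", "mus_gain", "mus_cap",
    # protocol segment (ramped inputs)
    "vo2_0", "vo2_1", "rq_0", "rq_1", "omega_0", "omega_1",
    "t_ramp", "t_offset",
)

PIDX = {name: i for i, name in enumerate(PARAM_NAMES)}
NPAR = len(PARAM_NAMES)

# integer constants used inside jitted code
P_HR0 = PIDX["hr0"]; P_KS = PIDX["ks"]; P_TREL = PIDX["trel_frac"]
P_LV_ES = PIDX["lv_es"]; P_LV_V0 = PIDX["lv_v0"]; P_LV_A = PIDX["lv_a"]; P_LV_B = PIDX["lv_b"]
P_RV_ES = PIDX["rv_es"]; P_RV_V0 = PIDX["rv_v0"]; P_RV_A = PIDX["rv_a"]; P_RV_B = PIDX["rv_b"]
P_LA_C = PIDX["la_c"]; P_LA_VU = PIDX["la_vu"]; P_LA_K = PIDX["la_kick"]
P_RA_C = PIDX["ra_c"]; P_RA_VU = PIDX["ra_vu"]; P_RA_K = PIDX["ra_kick"]
P_KC = PIDX["kick_center"]; P_KW = PIDX["kick_width"]; P_GKICK = PIDX["g_kick"]
P_R_MI = PIDX["r_mi"]; P_R_AV = PIDX["r_av"]; P_R_TRI = PIDX["r_tri"]; P_R_PAV = PIDX["r_pav"]
P_C_AA = PIDX["c_aa"]; P_VU_AA = PIDX["vu_aa"]; P_R_DA = PIDX["r_da"]; P_L_DA = PIDX["l_da"]
P_C_DA = PIDX["c_da"]; P_VU_DA = PIDX["vu_da"]
P_R_A0 = PIDX["r_ub_a"]          # 5 consecutive district arterial resistances
P_R_V0 = PIDX["r_ub_v"]          # 5 consecutive district venous resistances
P_C_D0 = PIDX["c_ub"]            # 5 consecutive district compliances
P_VU_D0 = PIDX["vu_ub"]          # 5 consecutive district unstressed volumes
P_C_CV = PIDX["c_cv"]; P_VU_CV = PIDX["vu_cv"]; P_R_CV = PIDX["r_cv"]
P_CAP0 = PIDX["cap0"]; P_VU_PA = PIDX["vu_pa"]; P_RAP = PIDX["rap"]
P_C_PV = PIDX["c_pv"]; P_VU_PV = PIDX["vu_pv"]; P_R_PV = PIDX["r_pv"]
P_CAP_THR = PIDX["cap_thr"]; P_CAP_SPAN = PIDX["cap_span"]; P_CAP_FLOOR = PIDX["cap_floor"]
P_COL_K = PIDX["col_k"]; P_COL_KNEE = PIDX["col_knee_frac"]
P_COL_PHI = PIDX["col_phi"]; P_COL_KHI = PIDX["col_khi"]
P_PCVF = PIDX["pintr_cv_frac"]
P_PSET = PIDX["pset"]; P_KB = PIDX["kb"]; P_KCC = PIDX["kc"]; P_RG = PIDX["rg"]
P_TAU_PF = PIDX["tau_pfilt"]
P_G_HR = PIDX["g_hr"]; P_G_ES_LV = PIDX["g_es_lv"]; P_G_ES_RV = PIDX["g_es_rv"]
P_G_R = PIDX["g_r"]; P_G_V = PIDX["g_v"]
P_TAU_S = PIDX["tau_symp"]; P_TAU_H = PIDX["tau_hr"]; P_HR_MAX = PIDX["hr_max"]
P_GM = PIDX["gm_met"]; P_MDB = PIDX["met_db"]
P_FLOOR0 = PIDX["floor_ub"]      # 5 consecutive
P_TAU_MET = PIDX["tau_met"]
P_REF0 = PIDX["ref_ub"]          # 5 consecutive
P_HB = PIDX["hb"]; P_P50 = PIDX["p50"]; P_NHILL = PIDX["nhill"]
P_CO2C0 = PIDX["co2_c0"]; P_CO2SL = PIDX["co2_slope"]
P_WT = PIDX["weight"]; P_VO2R = PIDX["vo2_rest_perkg"]
P_SR0 = PIDX["sr_ub"]            # 5 consecutive rest VO2 splits
P_SE0 = PIDX["se_ub"]            # 5 consecutive exercise VO2 splits
P_VST0 = PIDX["vst_ub"]          # 5 consecutive tissue store volumes
P_VST_ART = PIDX["vst_art"]
P_V_ALV = PIDX["v_alv"]; P_PIO2 = PIDX["pio2"]; P_VD = PIDX["vd_airway"]
P_F0 = PIDX["f0_resp"]; P_KF = PIDX["kf_resp"]
P_GC = PIDX["gc_co2"]; P_PACO2SET = PIDX["paco2_set"]
P_KFF = PIDX["kff_vco2"]; P_VCO2REF = PIDX["vco2_ref"]
P_GH = PIDX["gh_o2"]; P_PAO2THR = PIDX["pao2_thr"]
P_TAU_VE = PIDX["tau_ve"]; P_VE_REST = PIDX["ve_rest"]
P_PPL0 = PIDX["ppl0"]; P_ECH = PIDX["echest"]; P_TIF = PIDX["ti_frac"]
P_ELUNG = PIDX["elungs"]; P_RAW = PIDX["raw"]
P_VAD_ON = PIDX["vad_on"]; P_VAD_KW = PIDX["vad_kw"]
P_VAD_K1 = PIDX["vad_kq1"]; P_VAD_K2 = PIDX["vad_kq2"]
P_VAD_RC = PIDX["vad_rc"]; P_VAD_LC = PIDX["vad_lc"]
P_MUS_CAD = PIDX["mus_cadence"]; P_MUS_G = PIDX["mus_gain"]; P_MUS_CAP = PIDX["mus_cap"]
P_VO2_0 = PIDX["vo2_0"]; P_VO2_1 = PIDX["vo2_1"]
P_RQ_0 = PIDX["rq_0"]; P_RQ_1 = PIDX["rq_1"]
P_OM_0 = PIDX["omega_0"]; P_OM_1 = PIDX["omega_1"]
P_TRAMP = PIDX["t_ramp"]; P_TOFF = PIDX["t_offset"]

# --------------------------------------------------------------------------
# State vector layout
# --------------------------------------------------------------------------

STATE_NAMES = (
    "v_la", "v_lv", "v_ra", "v_rv",
    "v_aa", "v_da", "v_ub", "v_kid", "v_sp", "v_ll", "v_rl",
    "v_cv", "v_pa", "v_pv",
    "q_da", "q_vad",
    "p_f", "pw_f", "s_tone", "h_tone",
    "m_ub", "m_kid", "m_sp", "m_ll", "m_rl",
    "ve", "theta", "phi",
    "ca_o2", "ca_co2",
    "cv_o2_ub", "cv_o2_kid", "cv_o2_sp", "cv_o2_ll", "cv_o2_rl",
    "cv_co2_ub", "cv_co2_kid", "cv_co2_sp", "cv_co2_ll", "cv_co2_rl",
    "pa_o2", "pa_co2",
)
SIDX = {name: i for i, name in enumerate(STATE_NAMES)}
NSTATE = len(STATE_NAMES)

S_V_LA = 0; S_V_LV = 1; S_V_RA = 2; S_V_RV = 3
S_V_AA = 4; S_V_DA = 5; S_V_D0 = 6            # 5 district volumes ub..rl
S_V_CV = 11; S_V_PA = 12; S_V_PV = 13
S_Q_DA = 14; S_Q_VAD = 15
S_P_F = 16; S_PW_F = 17; S_S = 18; S_H = 19
S_M0 = 20                                      # 5 metabolic multipliers
S_VE = 25; S_TH = 26; S_PHI = 27
S_CAO2 = 28; S_CACO2 = 29
S_CVO2_0 = 30                                  # 5
S_CVCO2_0 = 35                                 # 5
S_PAO2 = 40; S_PACO2 = 41

# --------------------------------------------------------------------------
# Derived (diagnostic) channel layout, recorded alongside the state
# --------------------------------------------------------------------------

DERIVED_NAMES = (
    "p_la", "p_lv", "p_ra", "p_rv",
    "p_aa", "p_da", "p_cv", "p_pa", "p_pv",
    "q_mi", "q_av", "q_tri", "q_pav", "q_ap", "q_pvla",
    "hr", "vc", "pintr", "a_drive", "pset_eff",
    "cmv_o2", "vo2_uptake", "vco2_lung", "paco2_art", "pao2_art",
    "f_resp", "vt", "va", "pm_l", "vo2_demand", "cap_eff",
)
DIDX = {name: i for i, name in enumerate(DERIVED_NAMES)}
ND = len(DERIVED_NAMES)

D_P_LA = 0; D_P_LV = 1; D_P_RA = 2; D_P_RV = 3
D_P_AA = 4; D_P_DA = 5; D_P_CV = 6; D_P_PA = 7; D_P_PV = 8
D_Q_MI = 9; D_Q_AV = 10; D_Q_TRI = 11; D_Q_PAV = 12; D_Q_AP = 13; D_Q_PVLA = 14
D_HR = 15; D_VC = 16; D_PINTR = 17; D_A = 18; D_PSET = 19
D_CMV = 20; D_VO2U = 21; D_VCO2 = 22; D_PACO2A = 23; D_PAO2A = 24
D_F = 25; D_VT = 26; D_VA = 27; D_PML = 28; D_VO2D = 29; D_CAPEFF = 30


# --------------------------------------------------------------------------
# Scalar physics helpers (jitted, shared by module-level APIs and the RHS)
# --------------------------------------------------------------------------

@njit(cache=True)
def activation_wave(frac, frac_sys, trel_frac):
    """Ventricular contraction function vc on the normalized cycle phase.

    Squared half-sine rising 0 -> 1 over systole, cosine relaxation over a
    short tail (trel_frac * Tsys), zero through the rest of diastole.
    """
    if frac < 0.0:
        frac = frac - np.floor(frac)
    elif frac >= 1.0:
        frac = frac - np.floor(frac)
    if frac < frac_sys:
        s = np.sin(0.5 * np.pi * frac / frac_sys)
        return s * s
    end_rel = frac_sys * (1.0 + trel_frac)
    if frac < end_rel:
        x = (frac - frac_sys) / (frac_sys * trel_frac)
        return 0.5 * (1.0 + np.cos(np.pi * x))
    return 0.0


@njit(cache=True)
def atrial_wave(frac, center, width):
    """Wrapped Gaussian activation for the late-diastolic atrial kick."""
    d = frac - center
    if d > 0.5:
        d -= 1.0
    elif d < -0.5:
        d += 1.0
    return np.exp(-0.5 * (d / width) ** 2)


@njit(cache=True)
def ventricular_p(v, vc, es, v0, a, b, pintr):
    """Time-varying elastance systole blended with exponential diastole."""
    return vc * es * (v - v0) + (1.0 - vc) * a * np.exp(b * v) + pintr


@njit(cache=True)
def atrial_p(v, c, vu, e_act, pintr):
    return (v - vu) / c + e_act * (v - vu) + pintr


@njit(cache=True)
def valve_q(p_up, p_down, r):
    dp = p_up - p_down
    if dp <= 0.0:
        return 0.0
    return dp / r


@njit(cache=True)
def vessel_p(v, c, vu, k_col, knee_frac, p_hi, k_hi, p_ext):
    """Compartment pressure with smooth low-volume collapse stiffening and
    high-distension stiffening.  Linear (V - Vu)/C in the normal range."""
    p = (v - vu) / c
    knee = knee_frac * vu
    if v < knee:
        d = knee - v
        p -= k_col * d * d
    v_hi = vu + c * p_hi
    if v > v_hi:
        d = v - v_hi
        p += k_hi * d * d
    return p + p_ext


@njit(cache=True)
def hill_sat(po2, p50, n):
    if po2 <= 0.0:
        return 0.0
    x = (po2 / p50) ** n
    return x / (1.0 + x)


@njit(cache=True)
def o2_content_ml_per_ml(po2, hb, p50, n):
    """O2 content in ml O2 per ml blood (Hill-bound + dissolved)."""
    return (1.34 * hb * hill_sat(po2, p50, n) + 0.003 * po2) / 100.0


@njit(cache=True)
def o2_tension_from_content(c, hb, p50, n):
    """Inverse dissociation by damped fixed point on the dissolved term."""
    po2 = 0.0
    for _ in range(40):
        bound = c - 3e-5 * po2
        sat = bound * 100.0 / (1.34 * hb)
        if sat < 1e-6:
            sat = 1e-6
        if sat > 0.999:
            sat = 0.999
        nxt = p50 * (sat / (1.0 - sat)) ** (1.0 / n)
        if nxt - po2 < 1e-10 and po2 - nxt < 1e-10:
            po2 = nxt
            break
        po2 = 0.5 * (po2 + nxt)
    return po2


@njit(cache=True)
def co2_content_ml_per_ml(pco2, c0, slope):
    c = c0 + slope * (pco2 - 40.0)
    if c < 0.0:
        c = 0.0
    return c / 100.0


@njit(cache=True)
def co2_tension_from_content(c, c0, slope):
    return 40.0 + (c * 100.0 - c0) / slope


@njit(cache=True)
def pump_head(q, omega, kw, k1, k2):
    """Axial pump pressure head H(Q, omega); falls with flow at fixed speed."""
    return kw * omega * omega - k1 * q - k2 * q * np.abs(q)


@njit(cache=True)
def _ramp(t, x0, x1, t_ramp):
    if t <= 0.0:
        return x0
    if t >= t_ramp or t_ramp <= 0.0:
        return x1
    return x0 + (x1 - x0) * t / t_ramp


@njit(cache=True)
def _clip(x, lo, hi):
    if x < lo:
        return lo
    if x > hi:
        return hi
    return x


# --------------------------------------------------------------------------
# Full model evaluation
# --------------------------------------------------------------------------

@njit(cache=True)
def eval_model(t, y, p, dy, der, want_der):
    """Fill dy (state derivative) and, when want_der, the derived channels."""

    # ---- protocol inputs (ramped) -------------------------------------
    vo2_perkg = _ramp(t, p[P_VO2_0], p[P_VO2_1], p[P_TRAMP])
    rq = _ramp(t, p[P_RQ_0], p[P_RQ_1], p[P_TRAMP])
    omega = _ramp(t, p[P_OM_0], p[P_OM_1], p[P_TRAMP])
    dvo2 = vo2_perkg - p[P_VO2R]
    if dvo2 < 0.0:
        dvo2 = 0.0

    # ---- autonomic drive ----------------------------------------------
    pset_eff = p[P_PSET] + p[P_RG] * dvo2
    a_drive = _clip(0.5 + p[P_KB] * (pset_eff - y[S_P_F]) + p[P_KCC] * dvo2,
                    0.0, 1.0)
    s = y[S_S]
    h = y[S_H]
    hr = p[P_HR0] * (1.0 + p[P_G_HR] * (h - 0.5))
    hr = _clip(hr, 30.0, p[P_HR_MAX])
    rr = 60.0 / hr
    tsys = p[P_KS] * np.sqrt(rr)
    frac_sys = tsys / rr

    es_lv = p[P_LV_ES] * (1.0 + p[P_G_ES_LV] * (s - 0.5))
    es_rv = p[P_RV_ES] * (1.0 + p[P_G_ES_RV] * (s - 0.5))
    r_mult = 1.0 + p[P_G_R] * (s - 0.5)
    vu_mult = 1.0 - p[P_G_V] * (s - 0.5)
    kick_mult = 1.0 + p[P_GKICK] * (s - 0.5)
    if kick_mult < 0.0:
        kick_mult = 0.0

    # ---- respiration waveform / intrathoracic pressure -----------------
    ve = y[S_VE]
    f = p[P_F0] + p[P_KF] * (ve - p[P_VE_REST])
    if f < 6.0:
        f = 6.0
    vt = ve / f
    fphase = y[S_PHI] - np.floor(y[S_PHI])
    ti = p[P_TIF]
    if vt > 1e-9:
        if fphase < ti:
            sb = 0.5 * (1.0 - np.cos(np.pi * fphase / ti))
        else:
            tau_exp = p[P_RAW] / p[P_ELUNG]          # passive time constant, s
            t_since = (fphase - ti) * (60.0 / f)
            sb = np.exp(-t_since / tau_exp)
    else:
        sb = 0.0
    pintr = p[P_PPL0] - p[P_ECH] * vt * sb
    va_lmin = (vt - p[P_VD]) * f
    if va_lmin < 0.5:
        va_lmin = 0.5

    # ---- cardiac activation --------------------------------------------
    frac = y[S_TH] - np.floor(y[S_TH])
    vc = activation_wave(frac, frac_sys, p[P_TREL])
    akt = atrial_wave(frac, p[P_KC], p[P_KW])
    e_la = p[P_LA_K] * kick_mult * akt
    e_ra = p[P_RA_K] * kick_mult * akt

    # ---- chamber and vessel pressures ----------------------------------
    p_la = atrial_p(y[S_V_LA], p[P_LA_C], p[P_LA_VU], e_la, pintr)
    p_ra = atrial_p(y[S_V_RA], p[P_RA_C], p[P_RA_VU], e_ra, pintr)
    p_lv = ventricular_p(y[S_V_LV], vc, es_lv, p[P_LV_V0],
                         p[P_LV_A], p[P_LV_B], pintr)
    p_rv = ventricular_p(y[S_V_RV], vc, es_rv, p[P_RV_V0],
                         p[P_RV_A], p[P_RV_B], pintr)

    p_aa = (y[S_V_AA] - p[P_VU_AA]) / p[P_C_AA] + pintr
    p_da = (y[S_V_DA] - p[P_VU_DA]) / p[P_C_DA]

    # leg muscle pump external pressure
    amp = p[P_MUS_G] * dvo2
    if amp > p[P_MUS_CAP]:
        amp = p[P_MUS_CAP]
    t_abs = t + p[P_TOFF]
    wave = np.sin(2.0 * np.pi * p[P_MUS_CAD] * t_abs)
    pm_l = 0.0
    pm_r = 0.0
    if amp > 0.0:
        if wave > 0.0:
            pm_l = amp * wave * wave
        else:
            pm_r = amp * wave * wave

    # district pressures (ub, kid, sp, ll, rl); kid is non-collapsible
    p_d = np.empty(5)
    for i in range(5):
        vu_i = p[P_VU_D0 + i] * vu_mult
        if i == 1:
            kc_i = 0.0
        else:
            kc_i = p[P_COL_K]
        p_ext = 0.0
        if i == 3:
            p_ext = pm_l
        elif i == 4:
            p_ext = pm_r
        p_d[i] = vessel_p(y[S_V_D0 + i], p[P_C_D0 + i], vu_i, kc_i,
                          p[P_COL_KNEE], p[P_COL_PHI], p[P_COL_KHI], p_ext)

    p_cv = vessel_p(y[S_V_CV], p[P_C_CV], p[P_VU_CV] * vu_mult, p[P_COL_K],
                    p[P_COL_KNEE], p[P_COL_PHI], p[P_COL_KHI],
                    p[P_PCVF] * pintr)

    # pulmonary arterial compliance falls with chronically raised wedge
    x = (y[S_PW_F] - p[P_CAP_THR]) / p[P_CAP_SPAN]
    x = _clip(x, 0.0, 1.0)
    cap_eff = p[P_CAP0] * (1.0 - (1.0 - p[P_CAP_FLOOR]) * x)
    p_pa = (y[S_V_PA] - p[P_VU_PA]) / cap_eff + pintr
    p_pv = (y[S_V_PV] - p[P_VU_PV]) / p[P_C_PV] + pintr

    # ---- flows ----------------------------------------------------------
    q_mi = valve_q(p_la, p_lv, p[P_R_MI])
    q_av = valve_q(p_lv, p_aa, p[P_R_AV])
    q_tri = valve_q(p_ra, p_rv, p[P_R_TRI])
    q_pav = valve_q(p_rv, p_pa, p[P_R_PAV])

    q_da = y[S_Q_DA]
    q_vad = y[S_Q_VAD]

    q_in_d = np.empty(5)
    q_out_d = np.empty(5)
    for i in range(5):
        r_a = p[P_R_A0 + i] * y[S_M0 + i] * r_mult
        q_in_d[i] = (p_da - p_d[i]) / r_a
        if i >= 3:
            # leg veins: Starling resistor with venous valves under Pmus
            pe = pm_l if i == 3 else pm_r
            p_dn = p_cv if p_cv > pe else pe
            q = (p_d[i] - p_dn) / p[P_R_V0 + i]
            if q < 0.0:
                q = 0.0
            q_out_d[i] = q
        else:
            q_out_d[i] = (p_d[i] - p_cv) / p[P_R_V0 + i]

    q_cvra = (p_cv - p_ra) / p[P_R_CV]
    q_ap = (p_pa - p_pv) / p[P_RAP]
    q_pvla = (p_pv - p_la) / p[P_R_PV]

    # ---- VAD ------------------------------------------------------------
    if p[P_VAD_ON] > 0.5:
        head = pump_head(q_vad, omega, p[P_VAD_KW], p[P_VAD_K1], p[P_VAD_K2])
        dq_vad = (p_lv - p_aa + head - p[P_VAD_RC] * q_vad) / p[P_VAD_LC]
    else:
        dq_vad = 0.0
        q_vad = 0.0

    # ---- volume derivatives ---------------------------------------------
    dy[S_V_LA] = q_pvla - q_mi
    dy[S_V_LV] = q_mi - q_av - q_vad
    dy[S_V_RA] = q_cvra - q_tri
    dy[S_V_RV] = q_tri - q_pav
    dy[S_V_AA] = q_av + q_vad - q_da
    sum_in = 0.0
    for i in range(5):
        sum_in += q_in_d[i]
    dy[S_V_DA] = q_da - sum_in
    sum_out = 0.0
    for i in range(5):
        dy[S_V_D0 + i] = q_in_d[i] - q_out_d[i]
        sum_out += q_out_d[i]
    dy[S_V_CV] = sum_out - q_cvra
    dy[S_V_PA] = q_pav - q_ap
    dy[S_V_PV] = q_ap - q_pvla

    dy[S_Q_DA] = (p_aa - p_da - p[P_R_DA] * q_da) / p[P_L_DA]
    dy[S_Q_VAD] = dq_vad

    # ---- control dynamics ------------------------------------------------
    dy[S_P_F] = (p_aa - y[S_P_F]) / p[P_TAU_PF]
    dy[S_PW_F] = (p_la - y[S_PW_F]) / 8.0
    dy[S_S] = (a_drive - s) / p[P_TAU_S]
    dy[S_H] = (a_drive - h) / p[P_TAU_H]

    # ---- metabolism and gas transport -------------------------------------
    vo2_tot = vo2_perkg * p[P_WT]                      # ml/min demand
    vo2_rest_tot = p[P_VO2R] * p[P_WT]
    dvo2_tot = vo2_tot - vo2_rest_tot
    if dvo2_tot < 0.0:
        dvo2_tot = 0.0

    ca = y[S_CAO2]
    ca_co2 = y[S_CACO2]
    u_tot = 0.0
    vco2_tot = 0.0
    qv_sum = 0.0
    cmix_o2 = 0.0
    cmix_co2 = 0.0
    for i in range(5):
        demand = (vo2_rest_tot * p[P_SR0 + i] + dvo2_tot * p[P_SE0 + i]) / 60.0
        q_del = q_in_d[i]
        if q_del < 0.0:
            q_del = 0.0
        # delivery-limited uptake; local tissue O2 stores (down to a
        # 1 ml/dl venous floor, ~3 s release) buffer brief flow dips such
        # as the muscle-pump squeeze phase
        cv_i = y[S_CVO2_0 + i]
        reserve = cv_i - 0.01
        if reserve < 0.0:
            reserve = 0.0
        supply = 0.97 * q_del * ca + reserve * p[P_VST0 + i] / 3.0
        u = demand if demand < supply else supply
        cv = y[S_CVO2_0 + i]
        vst = p[P_VST0 + i]
        dy[S_CVO2_0 + i] = (q_del * (ca - cv) - u) / vst
        dy[S_CVCO2_0 + i] = (q_del * (ca_co2 - y[S_CVCO2_0 + i]) + rq * u) / vst
        u_tot += u
        vco2_tot += rq * u
        # mixed venous composition from district outflows
        qo = q_out_d[i]
        if qo > 0.0:
            qv_sum += qo
            cmix_o2 += qo * cv
            cmix_co2 += qo * y[S_CVCO2_0 + i]
        # metabolic vasodilation statics
        ref = p[P_REF0 + i]
        deficit = (ref - p[P_MDB]) - cv * 100.0
        if deficit < 0.0:
            deficit = 0.0
        m_stat = 1.0 - p[P_GM] * deficit / ref
        fl = p[P_FLOOR0 + i]
        if m_stat < fl:
            m_stat = fl
        dy[S_M0 + i] = (m_stat - y[S_M0 + i]) / p[P_TAU_MET]

    if qv_sum > 1e-9:
        cmix_o2 /= qv_sum
        cmix_co2 /= qv_sum
    else:
        cmix_o2 = ca
        cmix_co2 = ca_co2

    # lung exchange: end-capillary blood equilibrates to alveolar tensions
    ceq_o2 = o2_content_ml_per_ml(y[S_PAO2], p[P_HB], p[P_P50], p[P_NHILL])
    ceq_co2 = co2_content_ml_per_ml(y[S_PACO2], p[P_CO2C0], p[P_CO2SL])
    q_pulm = q_ap if q_ap > 0.0 else 0.0
    vo2_lung = q_pulm * (ceq_o2 - cmix_o2)             # ml O2 / s
    vco2_lung = q_pulm * (cmix_co2 - ceq_co2)          # ml CO2 / s
    dy[S_CAO2] = q_pulm * (ceq_o2 - ca) / p[P_VST_ART]
    dy[S_CACO2] = q_pulm * (ceq_co2 - ca_co2) / p[P_VST_ART]

    # alveolar stores: V_alv dPA/dt = VA(PI - PA) - 863 * Vgas, all per
    # minute with Vgas in L/min; per second this reduces to 0.863 * (ml/s)
    va_ls = va_lmin / 60.0
    dy[S_PAO2] = (va_ls * (p[P_PIO2] - y[S_PAO2])
                  - 0.863 * vo2_lung) / p[P_V_ALV]
    dy[S_PACO2] = (-va_ls * y[S_PACO2]
                   + 0.863 * vco2_lung) / p[P_V_ALV]

    # ---- ventilation control ---------------------------------------------
    paco2_art = co2_tension_from_content(ca_co2, p[P_CO2C0], p[P_CO2SL])
    pao2_art = o2_tension_from_content(ca, p[P_HB], p[P_P50], p[P_NHILL])
    vco2_lmin_ml = vco2_lung * 60.0                    # ml/min
    dvc = vco2_lmin_ml - p[P_VCO2REF]
    if dvc < 0.0:
        dvc = 0.0
    hyp = p[P_PAO2THR] - pao2_art
    if hyp < 0.0:
        hyp = 0.0
    ve_chemo = (p[P_VE_REST] + p[P_GC] * (paco2_art - p[P_PACO2SET])
                + p[P_KFF] * dvc + p[P_GH] * hyp)
    ve_chemo = _clip(ve_chemo, 3.0, 80.0)
    dy[S_VE] = (ve_chemo - ve) / p[P_TAU_VE]

    # ---- clocks ----------------------------------------------------------
    dy[S_TH] = hr / 60.0
    dy[S_PHI] = f / 60.0

    # ---- derived channels --------------------------------------------------
    if want_der:
        der[D_P_LA] = p_la
        der[D_P_LV] = p_lv
        der[D_P_RA] = p_ra
        der[D_P_RV] = p_rv
        der[D_P_AA] = p_aa
        der[D_P_DA] = p_da
        der[D_P_CV] = p_cv
        der[D_P_PA] = p_pa
        der[D_P_PV] = p_pv
        der[D_Q_MI] = q_mi
        der[D_Q_AV] = q_av
        der[D_Q_TRI] = q_tri
        der[D_Q_PAV] = q_pav
        der[D_Q_AP] = q_ap
        der[D_Q_PVLA] = q_pvla
        der[D_HR] = hr
        der[D_VC] = vc
        der[D_PINTR] = pintr
        der[D_A] = a_drive
        der[D_PSET] = pset_eff
        der[D_CMV] = cmix_o2
        der[D_VO2U] = u_tot * 60.0
        der[D_VCO2] = vco2_lmin_ml
        der[D_PACO2A] = paco2_art
        der[D_PAO2A] = pao2_art
        der[D_F] = f
        der[D_VT] = vt
        der[D_VA] = va_lmin
        der[D_PML] = pm_l
        der[D_VO2D] = vo2_tot
        der[D_CAPEFF] = cap_eff
    return 0


@njit(cache=True)
def rhs(t, y, p):
    dy = np.empty(NSTATE)
    der = np.empty(1)
    eval_model(t, y, p, dy, der, False)
    return dy


@njit(cache=True)
def simulate(p, y0, t0, t1, dt, rec_stride):
    """Fixed-step RK4 integration with downsampled recording.

    Returns (t_out, y_out, d_out, y_final, ok).  ``ok`` is False when a
    non-finite value is detected, in which case outputs are truncated.
    """
    nstep = int(np.ceil((t1 - t0) / dt))
    nrec = nstep // rec_stride + 1
    t_out = np.empty(nrec)
    y_out = np.empty((nrec, NSTATE))
    d_out = np.empty((nrec, ND))

    y = y0.copy()
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    ytmp = np.empty(NSTATE)
    der = np.empty(ND)

    t = t0
    irec = 0
    eval_model(t, y, p, k1, der, True)
    t_out[0] = t
    y_out[0, :] = y
    d_out[0, :] = der
    irec = 1
    ok = True

    for istep in range(nstep):
        eval_model(t, y, p, k1, der, False)
        for j in range(NSTATE):
            ytmp[j] = y[j] + 0.5 * dt * k1[j]
        eval_model(t + 0.5 * dt, ytmp, p, k2, der, False)
        for j in range(NSTATE):
            ytmp[j] = y[j] + 0.5 * dt * k2[j]
        eval_model(t + 0.5 * dt, ytmp, p, k3, der, False)
        for j in range(NSTATE):
            ytmp[j] = y[j] + dt * k3[j]
        eval_model(t + dt, ytmp, p, k4, der, False)
        for j in range(NSTATE):
            y[j] = y[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        if p[P_VAD_ON] < 0.5:
            y[S_Q_VAD] = 0.0
        t = t0 + (istep + 1) * dt

        bad = False
        for j in range(NSTATE):
            if not np.isfinite(y[j]):
                bad = True
        if bad:
            ok = False
            break
        if (istep + 1) % rec_stride == 0 and irec < nrec:
            eval_model(t, y, p, k1, der, True)
            t_out[irec] = t
            y_out[irec, :] = y
            d_out[irec, :] = der
            irec += 1

    return t_out[:irec], y_out[:irec], d_out[:irec], y, ok
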