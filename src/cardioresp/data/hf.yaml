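# Severe heart failure scenario (unassisted).
# Clinically printed parameters: HR 81 bpm, LV stiffness a=0.0532, b=0.0194,
# Elvs 0.5, Vlv0 50, Ervs 0.37, regional arterial resistances, Rap 0.18,
# venous O2 references, Pset 88.  Remaining values are the tuned baseline
# reproducing the rest hemodynamics (CO 3.7 l/min, Pas 89, Pap 26,
# Pwedge 14, Pra 8 mmHg, VED 320, VES 275 cm^3).
schema_version: 1
condition: HF
heart:
  hr_rest: 81.0
  ks: 0.3
  trel_frac: 0.2
  lv: {es: 0.5, v0: 50.0, a: 0.0532, b: 0.0194}
  rv: {es: 0.37, v0: -40.0, a: 0.085, b: 0.045}
  la: {c: 6.0, vu: 30.0, kick: 0.4}
  ra: {c: 10.0, vu: 30.0, kick: 0.08}
  kick_center: 0.92
  kick_width: 0.05
  kick_gain: 0.9
  valves: {r_mitral: 0.004, r_aortic: 0.007, r_tricuspid: 0.0035, r_pulmonic: 0.02}
circulation:
  ascending_aorta: {c: 0.28, vu: 60.0}
  descending_aorta: {r: 0.02, l: 0.0005, c: 1.0, vu: 150.0}
  districts:
    upper_body: {ra: 5.2, rv: 0.52, c: 9.0, vu: 350.0}
    kidneys:    {ra: 5.4, rv: 0.54, c: 3.0, vu: 60.0}
    splanchnic: {ra: 4.0, rv: 0.40, c: 32.0, vu: 1100.0}
    left_leg:   {ra: 9.4, rv: 0.94, c: 7.0, vu: 300.0}
    right_leg:  {ra: 9.4, rv: 0.94, c: 7.0, vu: 300.0}
  vena_cava: {c: 28.0, vu: 350.0, r: 0.008}
  pulmonary: {cap: 3.0, vu_pa: 60.0, rap: 0.18, cpv: 12.0, vu_pv: 180.0, rpv: 0.006}
  cap_wedge: {threshold: 15.0, span: 20.0, floor: 0.5}
  collapse: {k: 0.0008, knee_frac: 0.5, p_hi: 12.0, k_hi: 0.0008}
  pintr_cv_frac: 0.0
control:
  baroreflex:
    pset: 88.0
    kb: 0.05
    kc: 0.0625
    resetting_gain: 0.82
    tau_pfilt: 2.0
    g_hr: 0.88
    g_es_lv: 0.0
    g_es_rv: 1.9
    g_r: 0.08
    g_v: 0.5
    tau_symp: 12.0
    tau_hr: 4.0
    hr_max: 135.0
  metabolic:
    gain: 1.5
    deadband: 0.5
    tau: 12.0
    refs:   {upper_body: 10.0, kidneys: 13.5, splanchnic: 11.0, left_leg: 10.0, right_leg: 10.0}
    floors: {upper_body: 0.50, kidneys: 0.60, splanchnic: 0.50, left_leg: 0.18, right_leg: 0.18}
blood:
  hb: 13.6
  p50: 26.6
  hill_n: 2.7
  co2_c0: 48.0
  co2_slope: 0.45
  weight: 74.0
  vo2_rest_perkg: 3.5
  vo2_split_rest:     {upper_body: 0.26, kidneys: 0.13, splanchnic: 0.30, left_leg: 0.155, right_leg: 0.155}
  vo2_split_exercise: {upper_body: 0.05, kidneys: 0.01, splanchnic: 0.02, left_leg: 0.46, right_leg: 0.46}
  tissue_stores: {upper_body: 300.0, kidneys: 100.0, splanchnic: 500.0, left_leg: 500.0, right_leg: 500.0}
  arterial_store: 700.0
respiratory:
  v_alv: 3.0
  pio2: 150.0
  dead_space: 0.35
  f0: 14.0
  kf: 0.62
  gc_co2: 2.0
  paco2_set: 40.0
  kff: 0.036
  vco2_ref: 207.0
  gh_o2: 0.3
  pao2_thr: 70.0
  tau_ve: 15.0
  ve_rest: 9.8
  ppl0: -2.5
  echest: 3.0
  ti_frac: 0.4
  elungs: 8.0
  raw: 2.0
vad:
  enabled: false
muscle_pump: {cadence: 1.0, gain: 2.0, cap: 24.0}
init:
  p_arterial: 89.0
  p_district: 14.5
  p_cv: 10.0
  p_pa: 26.0
  p_pv: 16.0
  p_la: 16.0
  p_ra: 9.5
  v_lv: 320.0
  v_rv: 120.0
protocol:
  - {name: rest,          vo2_perkg: 3.5,  rq: 0.8, ramp: 0.0,  max_duration: 600.0}
  - {name: peak_exercise, vo2_perkg: 11.5, rq: 1.2, ramp: 60.0, max_duration: 600.0}
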