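"""Respiratory mechanics, gas transport and ventilation control.

Blood carries O2 on a Hill dissociation curve (plus dissolved O2) and CO2
on a linearized content relation.  Each circulatory district consumes O2
and produces CO2 into its own venous store; the lungs equilibrate
pulmonary capillary blood to the alveolar tensions, which evolve from
alveolar mass balance.  Minute ventilation is driven by a CO2 chemostat
plus an exercise (CO2-flux) feedforward and a hypoxic term, and the
breathing pattern partitions it into rate and tidal volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core
from .errors import InvalidInputError, InvalidParameterError


@dataclass(frozen=True)
class BloodGasParams:
    """Carriage properties of blood.

    hb: hemoglobin (g/dl); p50/hill_n: O2 dissociation; co2_c0: CO2
    content at 40 mmHg (ml/dl); co2_slope: ml/dl per mmHg.
    """
    hb: float = 13.6
    p50: float = 26.6
    hill_n: float = 2.7
    co2_c0: float = 48.0
    co2_slope: float = 0.45

    def __post_init__(self):
        if min(self.hb, self.p50, self.hill_n, self.co2_c0,
               self.co2_slope) <= 0:
            raise InvalidParameterError("blood gas parameters must be positive")


@dataclass(frozen=True)
class VentilationParams:
    """Ventilation controller and breathing-pattern constants."""
    ve_rest: float = 9.2
    gc_co2: float = 2.0
    paco2_set: float = 40.0
    kff: float = 0.0328
    vco2_ref: float = 207.0
    gh_o2: float = 0.3
    pao2_thr: float = 70.0
    tau: float = 15.0
    f0: float = 14.0
    kf: float = 0.62
    dead_space: float = 0.35

    def __post_init__(self):
        if self.ve_rest <= 0 or self.tau <= 0 or self.f0 <= 0:
            raise InvalidParameterError("ve_rest, tau and f0 must be positive")
        if min(self.gc_co2, self.kff, self.gh_o2, self.kf) < 0:
            raise InvalidParameterError("controller gains must be >= 0")
        if self.dead_space <= 0:
            raise InvalidParameterError("dead space must be positive")


@dataclass(frozen=True)
class MechanicsParams:
    """Pleural pressure waveform constants."""
    ppl0: float = -2.5
    echest: float = 3.0
    ti_frac: float = 0.4
    elungs: float = 8.0
    raw: float = 2.0

    def __post_init__(self):
        if not 0 < self.ti_frac < 1:
            raise InvalidParameterError("inspiratory fraction must be in (0,1)")
        if self.elungs <= 0 or self.raw <= 0 or self.echest < 0:
            raise InvalidParameterError(
                "lung elastance and Raw must be > 0, chest elastance >= 0")


def o2_content(po2: float, blood: BloodGasParams) -> float:
    """O2 content (ml O2/dl blood) at a given tension: Hill-bound + dissolved."""
    if po2 < 0:
        raise InvalidInputError("PO2 must be >= 0")
    return 100.0 * core.o2_content_ml_per_ml(po2, blood.hb, blood.p50,
                                             blood.hill_n)


def o2_tension(content_mldl: float, blood: BloodGasParams) -> float:
    """Inverse dissociation: tension (mmHg) from content (ml O2/dl)."""
    if content_mldl < 0:
        raise InvalidInputError("O2 content must be >= 0")
    return float(core.o2_tension_from_content(content_mldl / 100.0, blood.hb,
                                              blood.p50, blood.hill_n))


def co2_content(pco2: float, blood: BloodGasParams) -> float:
    """CO2 content (ml/dl) from tension via the linearized relation."""
    if pco2 < 0:
        raise InvalidInputError("PCO2 must be >= 0")
    return 100.0 * core.co2_content_ml_per_ml(pco2, blood.co2_c0,
                                              blood.co2_slope)


def co2_tension(content_mldl: float, blood: BloodGasParams) -> float:
    """Inverse of :func:`co2_content`."""
    return float(core.co2_tension_from_content(content_mldl / 100.0,
                                               blood.co2_c0, blood.co2_slope))


def tissue_gas_exchange(q_mls: float, ca_o2_mldl: float, cv_o2_mldl: float,
                        demand_mlmin: float, store_ml: float,
                        extraction_cap: float = 0.97
                        ) -> tuple[float, float]:
    """One district's O2 balance: (uptake ml/min, dCv/dt in ml/dl per s).

    Uptake equals the metabolic demand unless delivery limits it; at most
    ``extraction_cap`` of the delivered O2 can be extracted.
    """
    if q_mls < 0 or store_ml <= 0:
        raise InvalidInputError("flow must be >= 0 and store > 0")
    supply = extraction_cap * q_mls * ca_o2_mldl / 100.0          # ml O2/s
    u = min(demand_mlmin / 60.0, supply)
    dcv = (q_mls * (ca_o2_mldl - cv_o2_mldl) / 100.0 - u) / store_ml
    return u * 60.0, dcv * 100.0


def lung_gas_exchange(q_pulm_mls: float, cmv_o2_mldl: float,
                      cmv_co2_mldl: float, pa_o2: float, pa_co2: float,
                      blood: BloodGasParams) -> tuple[float, float]:
    """Pulmonary O2 uptake and CO2 output (ml/min), assuming end-capillary
    equilibration of blood with alveolar gas.  CO2 is positive out of the
    blood into the alveoli."""
    if q_pulm_mls < 0:
        raise InvalidInputError("pulmonary flow must be >= 0")
    ceq_o2 = o2_content(pa_o2, blood)
    ceq_co2 = co2_content(pa_co2, blood)
    vo2 = q_pulm_mls * (ceq_o2 - cmv_o2_mldl) / 100.0 * 60.0
    vco2 = q_pulm_mls * (cmv_co2_mldl - ceq_co2) / 100.0 * 60.0
    return vo2, vco2


def alveolar_derivatives(pa_o2: float, pa_co2: float, va_lmin: float,
                         vo2_mlmin: float, vco2_mlmin: float,
                         pio2: float = 150.0, v_alv: float = 3.0
                         ) -> tuple[float, float]:
    """Alveolar tension dynamics (mmHg/s) from alveolar mass balance:
    V_alv * dPA/dt = VA * (PI - PA) -/+ 0.863 * Vgas(ml/min), per minute."""
    if va_lmin < 0 or v_alv <= 0:
        raise InvalidInputError("VA must be >= 0 and V_alv > 0")
    dpo2 = (va_lmin * (pio2 - pa_o2) - 0.863 * vo2_mlmin) / v_alv / 60.0
    dpco2 = (-va_lmin * pa_co2 + 0.863 * vco2_mlmin) / v_alv / 60.0
    return dpo2, dpco2


def ventilation_demand(params: VentilationParams, paco2_art: float,
                       vco2_mlmin: float, pao2_art: float) -> float:
    """Steady-state minute-ventilation command (l/min).

    CO2 chemostat around the set point, plus a feedforward on CO2
    production above the resting reference and a hypoxic term below the
    PaO2 threshold.
    """
    ve = (params.ve_rest
          + params.gc_co2 * (paco2_art - params.paco2_set)
          + params.kff * max(0.0, vco2_mlmin - params.vco2_ref)
          + params.gh_o2 * max(0.0, params.pao2_thr - pao2_art))
    return float(np.clip(ve, 3.0, 80.0))


def breathing_pattern(ve_lmin: float, params: VentilationParams
                      ) -> tuple[float, float, float]:
    """Partition minute ventilation into (rate 1/min, Vt l, VA l/min).

    Breathing rate rises linearly with ventilation above rest; alveolar
    ventilation discounts the series dead space on every breath.
    """
    if ve_lmin <= 0:
        raise InvalidInputError("minute ventilation must be positive")
    f = max(6.0, params.f0 + params.kf * (ve_lmin - params.ve_rest))
    vt = ve_lmin / f
    va = max(0.0, (vt - params.dead_space) * f)
    return float(f), float(vt), float(va)


def pleural_pressure(phase_frac: float, vt_l: float, f_permin: float,
                     params: MechanicsParams) -> float:
    """Pleural pressure over one breath (phase in [0, 1)).

    Half-cosine active inspiration over ``ti_frac`` of the breath; passive
    expiration decays exponentially with the mechanical time constant
    tau = Raw / Elungs.
    """
    if not 0 <= phase_frac < 1:
        raise InvalidInputError("phase fraction must lie in [0, 1)")
    if vt_l < 0 or f_permin <= 0:
        raise InvalidInputError("Vt >= 0 and f > 0 required")
    ti = params.ti_frac
    if vt_l <= 1e-9:
        s = 0.0
    elif phase_frac < ti:
        s = 0.5 * (1.0 - np.cos(np.pi * phase_frac / ti))
    else:
        tau = params.raw / params.elungs
        t_since = (phase_frac - ti) * (60.0 / f_permin)
        s = np.exp(-t_since / tau)
    return float(params.ppl0 - params.echest * vt_l * s)


def expiratory_flow(volume_above_frc_l: float, params: MechanicsParams
                    ) -> float:
    """Passive expiratory airflow (l/s): elastic recoil over airway
    resistance, Q = Elungs * V / Raw (positive out of the lung)."""
    if volume_above_frc_l < 0:
        raise InvalidInputError("volume above FRC must be >= 0")
    return params.elungs * volume_above_frc_l / params.raw


def fick_cardiac_output(vo2_mlmin: float, ca_o2_mldl: float,
                        cv_o2_mldl: float) -> float:
    """Cardiac output (l/min) from the Fick principle."""
    avdiff = ca_o2_mldl - cv_o2_mldl
    if avdiff <= 0:
        raise InvalidInputError("arteriovenous O2 difference must be positive")
    return vo2_mlmin / avdiff / 10.0
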