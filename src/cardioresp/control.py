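"""Autonomic and metabolic control.

A single sympathetic drive combines the arterial baroreflex with a
central (feedforward) exercise command.  The set point itself resets
upward with exercise intensity.  Two first-order tone states filter the
drive — a fast one for heart rate and a slower one for the vascular and
inotropic effectors — and the effector responses are algebraic in tone.
Regional metabolic vasodilation tracks each district's venous O2 content
against its resting reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

_TONE_LO, _TONE_HI = 0.0, 1.0


@dataclass(frozen=True)
class BaroreflexParams:
    """Drive generation and effector gains.

    pset: resting arterial set point (mmHg); kb: drive per mmHg of
    pressure error; kc: central-command drive per ml/min/kg of extra VO2;
    resetting_gain: set-point shift in mmHg per ml/min/kg of extra VO2.
    """
    pset: float
    kb: float = 0.02
    kc: float = 0.0625
    resetting_gain: float = 0.85
    g_hr: float = 1.0
    g_es_lv: float = 0.3
    g_es_rv: float = 2.5
    g_r: float = 0.6
    g_v: float = 0.25
    tau_symp: float = 12.0
    tau_hr: float = 4.0
    hr_max: float = 135.0

    def __post_init__(self):
        if self.pset <= 0:
            raise InvalidParameterError("set point must be positive")
        if self.tau_symp <= 0 or self.tau_hr <= 0:
            raise InvalidParameterError("time constants must be positive")
        if min(self.kb, self.kc, self.resetting_gain, self.g_hr,
               self.g_es_lv, self.g_es_rv, self.g_r, self.g_v) < 0:
            raise InvalidParameterError("gains must be >= 0")


@dataclass(frozen=True)
class MetabolicParams:
    """Local vasodilation law for one district.

    ref: resting venous O2 content (ml O2/dl); floor: minimum resistance
    multiplier; deadband: tolerated content drop before dilation starts.
    """
    ref: float
    floor: float
    gain: float = 1.5
    deadband: float = 0.5
    tau: float = 12.0

    def __post_init__(self):
        if self.ref <= 0:
            raise InvalidParameterError("venous O2 reference must be positive")
        if not 0 < self.floor <= 1:
            raise InvalidParameterError("floor must lie in (0, 1]")
        if self.gain < 0 or self.deadband < 0 or self.tau <= 0:
            raise InvalidParameterError("gain/deadband >= 0 and tau > 0 required")


@dataclass
class ControlState:
    """Filtered controller states."""
    p_filt: float            # low-pass arterial pressure seen by the baroreceptors
    s_tone: float = 0.5      # slow sympathetic tone (vessels, inotropy)
    h_tone: float = 0.5      # fast chronotropic tone
    m: np.ndarray = field(default_factory=lambda: np.ones(5))


def baroreflex_reset(params: BaroreflexParams, dvo2_perkg: float) -> float:
    """Exercise resetting: the defended pressure rises with intensity."""
    if dvo2_perkg < 0:
        dvo2_perkg = 0.0
    return params.pset + params.resetting_gain * dvo2_perkg


def autonomic_drive(params: BaroreflexParams, p_filt: float,
                    dvo2_perkg: float) -> float:
    """Combined baroreflex + central-command drive, clipped to [0, 1].

    0.5 is the resting operating point; hypotension relative to the
    (reset) set point and exercise intensity both push the drive up.
    """
    pset_eff = baroreflex_reset(params, dvo2_perkg)
    a = 0.5 + params.kb * (pset_eff - p_filt) + params.kc * max(0.0, dvo2_perkg)
    return float(np.clip(a, _TONE_LO, _TONE_HI))


def baroreflex_update(state: ControlState, params: BaroreflexParams,
                      p_arterial: float, dvo2_perkg: float, dt: float,
                      tau_pfilt: float = 2.0) -> ControlState:
    """Advance the filtered pressure and tone states by one step (Euler)."""
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    a = autonomic_drive(params, state.p_filt, dvo2_perkg)
    p_f = state.p_filt + dt * (p_arterial - state.p_filt) / tau_pfilt
    s = state.s_tone + dt * (a - state.s_tone) / params.tau_symp
    h = state.h_tone + dt * (a - state.h_tone) / params.tau_hr
    return ControlState(p_filt=p_f, s_tone=float(np.clip(s, 0, 1)),
                        h_tone=float(np.clip(h, 0, 1)), m=state.m.copy())


def heart_rate_command(params: BaroreflexParams, h_tone: float,
                       hr0: float) -> float:
    """Heart rate from chronotropic tone, bounded by the disease ceiling."""
    if hr0 <= 0:
        raise InvalidParameterError("intrinsic heart rate must be positive")
    hr = hr0 * (1.0 + params.g_hr * (h_tone - 0.5))
    return float(np.clip(hr, 30.0, params.hr_max))


def effector_multipliers(params: BaroreflexParams, s_tone: float
                         ) -> dict[str, float]:
    """Algebraic effector responses to the slow sympathetic tone.

    Returns multipliers for LV/RV end-systolic elastance, arterial
    resistance, venous unstressed volume and the atrial kick.
    """
    ds = s_tone - 0.5
    return {
        "es_lv": 1.0 + params.g_es_lv * ds,
        "es_rv": 1.0 + params.g_es_rv * ds,
        "r_arterial": 1.0 + params.g_r * ds,
        "vu_venous": 1.0 - params.g_v * ds,
    }


def metabolic_vasodilation(params: MetabolicParams, cv_o2_mldl: float
                           ) -> float:
    """Static resistance multiplier from local venous O2 content.

    Content at or above (ref - deadband) leaves resistance unchanged;
    below it the multiplier falls linearly with the deficit, saturating
    at the district floor.
    """
    if cv_o2_mldl < 0:
        raise InvalidParameterError("venous O2 content must be >= 0")
    deficit = max(0.0, (params.ref - params.deadband) - cv_o2_mldl)
    m = 1.0 - params.gain * deficit / params.ref
    return float(max(params.floor, m))


def metabolic_update(m: float, params: MetabolicParams, cv_o2_mldl: float,
                     dt: float) -> float:
    """First-order relaxation of the resistance multiplier to its static value."""
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    m_stat = metabolic_vasodilation(params, cv_o2_mldl)
    return m + dt * (m_stat - m) / params.tau
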