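"""Cardiac chambers: time-varying elastance ventricles and contracting atria.

The ventricles follow the classical time-varying elastance description: a
contraction function ``vc(t)`` blends an end-systolic elastance line
``P = Es * (V - V0)`` with an exponential diastolic stiffness relation
``P = a * exp(b * V)``; the intrathoracic pressure adds to both.  Atria are
linear compliances with a late-diastolic active "kick" that tops off
ventricular filling.  Heart valves are competent resistive diodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core
from .errors import InvalidParameterError


@dataclass(frozen=True)
class VentricleParams:
    """End-systolic elastance line plus exponential diastolic stiffness.

    Es: mmHg/cm^3; V0: cm^3; a: mmHg; b: 1/cm^3.
    """
    es: float
    v0: float
    a: float
    b: float

    def __post_init__(self):
        if self.es <= 0 or self.a <= 0 or self.b <= 0:
            raise InvalidParameterError(
                "ventricle requires Es > 0, a > 0, b > 0")


@dataclass(frozen=True)
class AtriumParams:
    """Linear compliance with a late-diastolic active elastance window.

    kick_timing is the (onset, offset) of the contraction expressed as
    fractions of the RR interval.
    """
    c: float
    v0: float
    kick_amplitude: float = 0.0
    kick_timing: tuple[float, float] = (0.85, 0.99)

    def __post_init__(self):
        on, off = self.kick_timing
        if self.c <= 0:
            raise InvalidParameterError("atrial compliance must be positive")
        if self.kick_amplitude < 0:
            raise InvalidParameterError("kick amplitude must be >= 0")
        if not (0 <= on < 1 and 0 <= off < 1):
            raise InvalidParameterError(
                "kick timing fractions must lie in [0, 1)")

    @property
    def kick_center(self) -> float:
        on, off = self.kick_timing
        span = (off - on) % 1.0
        return (on + span / 2.0) % 1.0

    @property
    def kick_width(self) -> float:
        on, off = self.kick_timing
        span = (off - on) % 1.0
        return max(span / 4.0, 1e-6)


@dataclass(frozen=True)
class CardiacTiming:
    """Cycle timing: RR = 60/HR, Tsys + Tdias = RR."""
    hr: float
    rr: float
    tsys: float
    tdias: float


@dataclass
class ChamberState:
    """Instantaneous volume (cm^3) and pressure (mmHg) of one chamber."""
    v: float
    p: float = np.nan


def cardiac_cycle_timing(hr: float, ks: float = 0.3) -> CardiacTiming:
    """Partition the cycle into systole and diastole at a given heart rate.

    Systole scales with the square root of the cycle length,
    ``Tsys = ks * sqrt(RR)``, so the diastolic fraction shrinks as heart
    rate rises (diastole shortens more than systole during tachycardia).
    """
    if not (30.0 <= hr <= 220.0):
        raise InvalidParameterError(f"heart rate {hr} bpm outside [30, 220]")
    rr = 60.0 / hr
    tsys = ks * np.sqrt(rr)
    tdias = rr - tsys
    if tdias <= 0:
        raise InvalidParameterError(
            f"systole ({tsys:.3f}s) would exceed the cycle length ({rr:.3f}s)")
    return CardiacTiming(hr=hr, rr=rr, tsys=tsys, tdias=tdias)


def ventricular_activation(t: float, timing: CardiacTiming,
                           trel_frac: float = 0.2) -> float:
    """Contraction function vc in [0, 1]; 0 in diastole, 1 at end systole.

    Squared half-sine over systole with a short cosine relaxation tail.
    Times outside the cycle are wrapped modulo RR.
    """
    frac = (t % timing.rr) / timing.rr
    frac_sys = timing.tsys / timing.rr
    return float(core.activation_wave(frac, frac_sys, trel_frac))


def ventricular_pressure(state: ChamberState, t: float,
                         params: VentricleParams, timing: CardiacTiming,
                         pintr: float = 0.0, trel_frac: float = 0.2) -> float:
    """Instantaneous ventricular pressure from the elastance blend.

    At vc = 1 this is exactly the end-systolic line Es*(V - V0) + Pintr;
    at vc = 0 it is exactly the diastolic relation a*exp(b*V) + Pintr.
    """
    if state.v < 0:
        raise InvalidParameterError("ventricular volume must be >= 0")
    vc = ventricular_activation(t, timing, trel_frac)
    return float(core.ventricular_p(state.v, vc, params.es, params.v0,
                                    params.a, params.b, pintr))


def atrial_pressure(state: ChamberState, t: float, params: AtriumParams,
                    timing: CardiacTiming, pintr: float = 0.0) -> float:
    """Atrial pressure: passive (V - V0)/C plus the late-diastolic kick."""
    frac = (t % timing.rr) / timing.rr
    e_act = params.kick_amplitude * core.atrial_wave(
        frac, params.kick_center, params.kick_width)
    return float(core.atrial_p(state.v, params.c, params.v0, e_act, pintr))


def valve_flow(p_up: float, p_down: float, r: float) -> float:
    """Competent valve: forward flow (P_up - P_down)/R, zero when closed."""
    if r <= 0:
        raise InvalidParameterError("valve resistance must be positive")
    return float(core.valve_q(p_up, p_down, r))
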