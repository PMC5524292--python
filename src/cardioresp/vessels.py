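"""Vascular network: Windkessel compartments, venous collapse, muscle pump.

The systemic and pulmonary circulations are resistance-compliance(-inertance)
compartments in series and parallel.  Veins are collapsible: their P-V
relation stiffens away from the linear range.  Leg venous outflow passes
through Starling resistors squeezed by the cycling muscle pump, and the
pulmonary arterial compliance falls when the wedge pressure is chronically
elevated (congestive stiffening of the pulmonary vasculature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import core
from .errors import InvalidInputError, InvalidParameterError

#: conductance fractions that reproduce the regional split of the systemic
#: arterial resistance used for the heart-failure baseline
#: (upper body, kidneys, splanchnic, left leg, right leg)
DEFAULT_SPLIT_FRACTIONS = None  # computed below


@dataclass(frozen=True)
class CollapseLaw:
    """Smooth nonlinear corrections to the linear P-V relation of a vein."""
    k_low: float = 8e-4
    knee_frac: float = 0.5
    p_hi: float = 12.0
    k_hi: float = 8e-4


@dataclass(frozen=True)
class CompartmentParams:
    """One circulatory district / vessel segment.

    ra/rv: inflow and outflow resistance (mmHg*s/cm^3); c: compliance
    (cm^3/mmHg); l: inertance (only aortic / pulmonary arterial trunks);
    vu: unstressed volume (cm^3); collapse: nonlinear law for veins.
    """
    ra: float
    rv: float
    c: float
    vu: float
    l: float = 0.0
    collapse: CollapseLaw | None = None

    def __post_init__(self):
        if self.ra <= 0 or self.rv <= 0:
            raise InvalidParameterError("resistances must be positive")
        if self.c <= 0:
            raise InvalidParameterError("compliance must be positive")
        if self.l < 0 or self.vu < 0:
            raise InvalidParameterError("inertance and Vu must be >= 0")


def vessel_pressure(v: float, params: CompartmentParams,
                    p_ext: float = 0.0) -> float:
    """Compartment pressure (V - Vu)/C + P_ext, with smooth stiffening
    outside the linear range for collapsible compartments."""
    if v < 0:
        raise InvalidInputError("volume must be >= 0")
    col = params.collapse
    if col is None:
        return float((v - params.vu) / params.c + p_ext)
    return float(core.vessel_p(v, params.c, params.vu, col.k_low,
                               col.knee_frac, col.p_hi, col.k_hi, p_ext))


def pulmonary_arterial_compliance(pwedge: float, ras: float, base: float,
                                  threshold: float = 15.0, span: float = 20.0,
                                  floor: float = 0.5,
                                  ras_gain: float = 0.0) -> float:
    """Pulmonary arterial compliance as a function of wedge pressure.

    Above ``threshold`` the compliance falls linearly to ``floor * base``
    over ``span`` mmHg (congestive stiffening).  A systemic-resistance
    hook is exposed (``ras_gain``) but inert by default.
    """
    if pwedge < 0:
        raise InvalidInputError("wedge pressure must be >= 0")
    x = np.clip((pwedge - threshold) / span, 0.0, 1.0)
    cap = base * (1.0 - (1.0 - floor) * x)
    if ras_gain != 0.0:
        cap *= 1.0 / (1.0 + ras_gain * ras)
    return float(cap)


def muscle_pump_pressure(t: float, cadence: float, amplitude: float,
                         active: bool = True) -> tuple[float, float]:
    """External pressure on the (left, right) leg veins from pedalling.

    Periodic, non-negative, legs in antiphase; identically zero at rest.
    """
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be >= 0")
    if not active or amplitude == 0.0:
        return 0.0, 0.0
    w = np.sin(2.0 * np.pi * cadence * t)
    left = amplitude * w * w if w > 0 else 0.0
    right = amplitude * w * w if w <= 0 else 0.0
    return float(left), float(right)


def starling_resistor_flow(p_up: float, p_down: float, p_ext: float,
                           r: float) -> float:
    """Vascular waterfall: the effective downstream pressure is the larger
    of the luminal downstream and surrounding pressures; no backflow."""
    if r <= 0:
        raise InvalidParameterError("resistance must be positive")
    p_eff = max(p_down, p_ext)
    return max(0.0, (p_up - p_eff) / r)


def estimate_resistances(pas: float, pcv: float, pap: float, pwedge: float,
                         co_lmin: float) -> tuple[float, float]:
    """Systemic and pulmonary arterial resistance from mean hemodynamics.

    Ras = (Pas - Pcv)/CO and Rap = (Pap - Pwedge)/CO with CO converted
    from l/min to cm^3/s; results in mmHg*s/cm^3.
    """
    if co_lmin <= 0:
        raise InvalidInputError("cardiac output must be positive")
    if pas <= pcv:
        raise InvalidInputError("Pas must exceed Pcv")
    if pap <= pwedge:
        raise InvalidInputError("Pap must exceed Pwedge")
    co = co_lmin * 1000.0 / 60.0
    return (pas - pcv) / co, (pap - pwedge) / co


def _conductance_fractions(resistances: Sequence[float]) -> np.ndarray:
    g = 1.0 / np.asarray(resistances, dtype=float)
    return g / g.sum()


# fractions implied by the heart-failure regional resistances
# {upper body 5.2, kidneys 5.4, splanchnic 4.0, legs 9.4 each}
DEFAULT_SPLIT_FRACTIONS = tuple(_conductance_fractions([5.2, 5.4, 4.0, 9.4, 9.4]))


def split_systemic_resistance(ras: float,
                              fractions: Sequence[float] | None = None
                              ) -> np.ndarray:
    """Split a total systemic arterial resistance into regional resistances.

    ``fractions`` are per-region conductance fractions (must sum to 1);
    the parallel combination of the returned resistances equals ``ras``.
    """
    if ras <= 0:
        raise InvalidParameterError("Ras must be positive")
    if fractions is None:
        fractions = DEFAULT_SPLIT_FRACTIONS
    f = np.asarray(fractions, dtype=float)
    if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
        raise InvalidParameterError(
            "conductance fractions must be positive and sum to 1")
    return ras / f


def parallel_resistance(resistances: Sequence[float]) -> float:
    """Parallel combination 1 / sum(1/R_i)."""
    r = np.asarray(resistances, dtype=float)
    if np.any(r <= 0):
        raise InvalidParameterError("resistances must be positive")
    return float(1.0 / np.sum(1.0 / r))


def network_derivatives(state: np.ndarray, params: np.ndarray,
                        t: float = 0.0) -> np.ndarray:
    """Time derivative of the full model state (see core layout).

    Raises IntegrationError when the state contains non-finite values.
    """
    from .errors import IntegrationError
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        bad = [core.STATE_NAMES[i] for i in np.where(~np.isfinite(y))[0]]
        raise IntegrationError(f"non-finite state components: {bad}")
    return core.rhs(t, y, np.asarray(params, dtype=float))


def windkessel_transient(r_out: float, c: float, vu: float, q_in: float,
                         v0: float, t_end: float, dt: float = 1e-3
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Numerically integrate a single 2-element Windkessel compartment.

    dV/dt = Q_in - P/R with P = (V - Vu)/C, using the same classical
    Runge-Kutta scheme as the full simulator.  Returns (t, V).  The
    analytic solution is exponential with time constant R*C.
    """
    n = int(round(t_end / dt))
    ts = np.linspace(0.0, n * dt, n + 1)
    vs = np.empty(n + 1)
    v = v0
    vs[0] = v

    def f(vv):
        return q_in - ((vv - vu) / c) / r_out

    for i in range(n):
        k1 = f(v)
        k2 = f(v + 0.5 * dt * k1)
        k3 = f(v + 0.5 * dt * k2)
        k4 = f(v + dt * k3)
        v = v + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        vs[i + 1] = v
    return ts, vs
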