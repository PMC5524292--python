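"""Continuous-flow ventricular assist device (axial pump).

The pump connects the LV apex to the ascending aorta through inflow and
outflow cannulas.  Its pressure head rises with the square of impeller
speed and falls with flow; cannula resistance and inertance shape the
flow dynamics.  Flow is signed: strongly unloaded ventricles at high
speed can never push flow backwards through a running axial pump here
because the head stays positive over the operating range, but the model
does not clamp it — regurgitation at low speed is representable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import core
from .errors import InvalidInputError, InvalidParameterError


@dataclass(frozen=True)
class VADParams:
    """Head curve H = kw*omega^2 - kq1*Q - kq2*Q|Q| plus cannula R, L.

    kw: mmHg/rpm^2; kq1: mmHg*s/cm^3; kq2: mmHg*s^2/cm^6; rc: cannula
    resistance (mmHg*s/cm^3); lc: cannula inertance (mmHg*s^2/cm^3);
    speed range in rpm.
    """
    kw: float = 9.5e-7
    kq1: float = 0.2
    kq2: float = 2.5e-3
    rc: float = 0.035
    lc: float = 0.02
    speed_min: float = 6000.0
    speed_max: float = 12000.0

    def __post_init__(self):
        if self.kw <= 0 or self.lc <= 0:
            raise InvalidParameterError("kw and lc must be positive")
        if min(self.kq1, self.kq2, self.rc) < 0:
            raise InvalidParameterError("kq1, kq2, rc must be >= 0")
        if not 0 < self.speed_min < self.speed_max:
            raise InvalidParameterError("require 0 < speed_min < speed_max")


@dataclass
class VADState:
    """Pump flow (cm^3/s) and impeller speed (rpm)."""
    q: float
    omega: float


def check_speed(params: VADParams, omega: float) -> float:
    """Validate an impeller speed against the device's operating range."""
    if not params.speed_min <= omega <= params.speed_max:
        raise InvalidInputError(
            f"pump speed {omega} rpm outside "
            f"[{params.speed_min}, {params.speed_max}] rpm")
    return float(omega)


def vad_pressure_head(q_mls: float, omega: float, params: VADParams) -> float:
    """Pressure head across the pump (mmHg) at flow Q and speed omega."""
    return float(core.pump_head(q_mls, omega, params.kw, params.kq1,
                                params.kq2))


def vad_flow_derivative(q_mls: float, omega: float, p_lv: float,
                        p_aorta: float, params: VADParams) -> float:
    """dQ/dt (cm^3/s^2) across the LV -> pump -> aorta branch."""
    head = vad_pressure_head(q_mls, omega, params)
    return (p_lv - p_aorta + head - params.rc * q_mls) / params.lc


def steady_flow(omega: float, dp: float, params: VADParams) -> float:
    """Steady pump flow at speed ``omega`` against pressure rise ``dp``
    (aortic minus ventricular pressure), solving H(Q) = dp + rc*Q for the
    forward branch of the head curve."""
    # kq2*Q^2 + (kq1 + rc)*Q + (dp - kw*omega^2) = 0, forward root
    a = params.kq2
    b = params.kq1 + params.rc
    c = dp - params.kw * omega * omega
    if a < 1e-15:
        return -c / b
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise InvalidInputError("no steady operating point at this speed")
    return (-b + np.sqrt(disc)) / (2.0 * a)


def calibrate_vad(flows_lmin: Sequence[float], speeds_rpm: Sequence[float],
                  heads_mmhg: Sequence[float],
                  kq2: float = 2.5e-3) -> VADParams:
    """Least-squares fit of (kw, kq1) to measured operating points.

    Each observation is (flow, speed, head).  The quadratic flow loss
    coefficient ``kq2`` is held fixed (it is poorly identified from a few
    operating points); kw and kq1 are solved linearly from
    H + kq2*Q|Q| = kw*omega^2 - kq1*Q.
    """
    q = np.asarray(flows_lmin, dtype=float) * 1000.0 / 60.0
    w = np.asarray(speeds_rpm, dtype=float)
    h = np.asarray(heads_mmhg, dtype=float)
    if not (q.shape == w.shape == h.shape) or q.size < 2:
        raise InvalidInputError(
            "need at least two (flow, speed, head) observations")
    a = np.column_stack([w * w, -q])
    b = h + kq2 * q * np.abs(q)
    (kw, kq1), *_ = np.linalg.lstsq(a, b, rcond=None)
    if kw <= 0:
        raise InvalidInputError("fit produced a non-positive speed coefficient")
    return VADParams(kw=float(kw), kq1=float(max(kq1, 0.0)), kq2=kq2)
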