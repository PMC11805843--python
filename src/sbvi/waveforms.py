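"""Patient flow-waveform synthesis from routine echocardiographic scalars.

The aortic jet velocity profile is not recorded as a time series in routine
echo reports; what is available are a handful of scalars (peak velocity,
acceleration time, stroke volume, heart rate, valve area). This module
reconstructs a one-period linear-velocity waveform consistent with those
scalars: zero at flow onset, a unique peak of ``peak_velocity`` at
``acceleration_time``, a smooth return to zero at the ejection duration, and
zero flow in diastole. The ejection duration itself is not measured directly;
it is found by requiring that valve area times the velocity-time integral
reproduce the continuity-method stroke volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EchoInputs",
    "Waveform",
    "InvalidGeometryError",
    "InfeasibleTargetError",
    "synthesize_flow",
    "optimize_ejection_duration",
]

#: conversion factor, 1 mmHg in dyn/cm^2
MMHG_TO_DYN_CM2 = 1333.22


class InvalidGeometryError(ValueError):
    """Raised when waveform timing parameters are not physiologically ordered."""


class InfeasibleTargetError(ValueError):
    """Raised when no ejection duration can reproduce the stroke volume."""


@dataclass(frozen=True)
class EchoInputs:
    """Echocardiographic scalars plus a brachial blood-pressure reading.

    Parameters
    ----------
    heart_rate : float
        Heart rate in beats/min; defines the signal period ``60/heart_rate``.
    peak_velocity : float
        Peak aortic valve velocity in cm/s (continuous-wave Doppler).
    acceleration_time : float
        Time from flow onset to peak velocity, in seconds.
    stroke_volume : float
        Stroke volume in mL (continuity method).
    aortic_valve_area : float
        Aortic valve area in cm^2; converts linear velocity to volumetric flow.
    systolic_bp, diastolic_bp : float
        Brachial cuff pressures in mmHg.
    """

    heart_rate: float
    peak_velocity: float
    acceleration_time: float
    stroke_volume: float
    aortic_valve_area: float
    systolic_bp: float
    diastolic_bp: float

    def __post_init__(self) -> None:
        for name in (
            "heart_rate",
            "peak_velocity",
            "acceleration_time",
            "stroke_volume",
            "aortic_valve_area",
            "systolic_bp",
            "diastolic_bp",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidGeometryError(f"{name} must be strictly positive, got {v!r}")
        if self.acceleration_time >= self.period:
            raise InvalidGeometryError(
                f"acceleration_time {self.acceleration_time} s must be shorter than "
                f"the cardiac period {self.period:.3f} s"
            )
        if self.systolic_bp <= self.diastolic_bp:
            raise InvalidGeometryError(
                f"systolic_bp ({self.systolic_bp}) must exceed diastolic_bp ({self.diastolic_bp})"
            )

    @property
    def period(self) -> float:
        """Cardiac period in seconds."""
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class Waveform:
    """One cardiac period of a uniformly sampled signal.

    ``values[i]`` is the sample at ``t = i * dt``; the implied period is
    ``len(values) * dt`` (the sample at ``t = period`` wraps to index 0).
    """

    values: np.ndarray
    dt: float
    unit_tag: str = "velocity_cm_s"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("Waveform requires a 1-D array of at least 2 samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def period(self) -> float:
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def with_values(self, values: np.ndarray, unit_tag: str | None = None) -> "Waveform":
        return replace(self, values=values, unit_tag=unit_tag or self.unit_tag)


def _smoothstep5(s: np.ndarray) -> np.ndarray:
    """Quintic smoothstep 6s^5 - 15s^4 + 10s^3 on [0, 1].

    Monotone from 0 to 1 with zero first and second derivatives at both ends,
    so piecing two of them together yields a C^2 pulse.
    """
    s = np.clip(s, 0.0, 1.0)
    return s * s * s * (s * (6.0 * s - 15.0) + 10.0)


def flow_profile(
    t: np.ndarray, peak_velocity: float, acceleration_time: float, ejection_duration: float
) -> np.ndarray:
    """Evaluate the systolic velocity pulse at arbitrary times (seconds).

    Degree-5 spline with interior knots at the acceleration time and the end
    of ejection: a quintic smoothstep rise on ``[0, AT]`` and mirrored fall on
    ``[AT, ED]``; identically zero outside ``[0, ED]``. The pulse is C^2 on
    the whole cycle and its closed-form area is ``peak_velocity * ED / 2``.
    """
    t = np.asarray(t, dtype=float)
    v = np.zeros_like(t)
    rise = (t >= 0) & (t <= acceleration_time)
    fall = (t > acceleration_time) & (t <= ejection_duration)
    v[rise] = peak_velocity * _smoothstep5(t[rise] / acceleration_time)
    v[fall] = peak_velocity * _smoothstep5(
        (ejection_duration - t[fall]) / (ejection_duration - acceleration_time)
    )
    return v


def synthesize_flow(
    echo: EchoInputs, ejection_duration: float, n_samples: int = 512
) -> Waveform:
    """Build the one-period linear-velocity flow waveform for a patient.

    Parameters
    ----------
    echo : EchoInputs
    ejection_duration : float
        Systolic interval in seconds; must satisfy
        ``acceleration_time < ejection_duration < period``.
    n_samples : int
        Samples per period (>= 64).

    Returns
    -------
    Waveform
        Velocity in cm/s; zero at t=0, unique global maximum equal to
        ``peak_velocity`` at ``acceleration_time`` (nearest sample), zero from
        ``ejection_duration`` to the end of the period.
    """
    if n_samples < 64:
        raise ValueError(f"n_samples must be >= 64, got {n_samples}")
    at, period = echo.acceleration_time, echo.period
    if not (0.0 < at < ejection_duration < period):
        raise InvalidGeometryError(
            f"require 0 < AT ({at}) < ED ({ejection_duration}) < period ({period:.3f})"
        )
    dt = period / n_samples
    t = np.arange(n_samples) * dt
    v = flow_profile(t, echo.peak_velocity, at, ejection_duration)
    if np.any(v < 0):  # cannot happen for the smoothstep pulse; guard retained
        logger.warning("negative flow excursion clamped to zero")
        v = np.maximum(v, 0.0)
    return Waveform(values=v, dt=dt, unit_tag="velocity_cm_s")


def waveform_auc(w: Waveform) -> float:
    """Trapezoidal area under one period, treating the signal as periodic."""
    closed = np.append(w.values, w.values[0])
    return float(np.trapezoid(closed, dx=w.dt))


def optimize_ejection_duration(
    echo: EchoInputs, n_samples: int = 512, volume_tol: float = 0.1
) -> float:
    """Find the ejection duration whose flow AUC reproduces the stroke volume.

    Bisection on ED over ``(AT + 2 dt, period - 2 dt)``: the area under the
    velocity pulse grows monotonically with ED, so the ejection duration that
    makes ``AVA * integral(v dt)`` equal the continuity stroke volume is
    unique. Deterministic for fixed inputs.

    Returns
    -------
    float
        Ejection duration in seconds such that the synthesized waveform's
        trapezoidal AUC times the valve area matches ``stroke_volume`` within
        ``volume_tol`` mL.

    Raises
    ------
    InfeasibleTargetError
        If the stroke volume exceeds what the longest admissible ejection can
        deliver; the error message names the maximum achievable volume.
    """
    dt = echo.period / n_samples
    lo = echo.acceleration_time + 2 * dt
    hi = echo.period - 2 * dt
    if lo >= hi:
        raise InvalidGeometryError(
            f"no admissible ejection window: AT={echo.acceleration_time} s, "
            f"period={echo.period:.3f} s at {n_samples} samples"
        )

    def volume(ed: float) -> float:
        return echo.aortic_valve_area * waveform_auc(synthesize_flow(echo, ed, n_samples))

    v_hi = volume(hi)
    if v_hi < echo.stroke_volume - volume_tol:
        raise InfeasibleTargetError(
            f"stroke volume {echo.stroke_volume} mL unreachable; maximum achievable "
            f"is {v_hi:.2f} mL at ED={hi:.3f} s"
        )
    v_lo = volume(lo)
    if v_lo >= echo.stroke_volume:
        # shortest admissible ejection already delivers the target volume
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        v_mid = volume(mid)
        if abs(v_mid - echo.stroke_volume) <= volume_tol:
            return mid
        if v_mid < echo.stroke_volume:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
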