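"""Fourier harmonic decomposition and the pressure/flow impedance algebra.

Aortic input impedance is defined harmonic-by-harmonic: decompose one period
of pressure and of flow into Fourier harmonics, take the ratio of amplitudes
and the difference of phases at each harmonic. The same algebra rearranged
gives the forward map from a candidate impedance spectrum and a known flow
spectrum to a pressure spectrum, which is the core of the inverse search.

Amplitude convention: one-sided. Harmonic 0 carries the signal mean and
harmonic k >= 1 the peak amplitude of ``a_k cos(2 pi k f1 t + phi_k)``, so the
DC amplitude of a pressure spectrum is literally the mean pressure. Any
self-consistent convention cancels in the impedance ratio; this one makes the
steady terms of the afterload metrics read off directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .waveforms import MMHG_TO_DYN_CM2, Waveform

__all__ = [
    "HarmonicSpectrum",
    "ImpedanceSpectrum",
    "AliasingError",
    "UndefinedHarmonicError",
    "wrap_phase",
    "decompose",
    "reconstruct",
    "impedance_from_pq",
    "pressure_from_zq",
]


class AliasingError(ValueError):
    """Requested more harmonics than the sampling supports."""


class UndefinedHarmonicError(ValueError):
    """Impedance requested at a harmonic where the flow amplitude vanishes."""


def wrap_phase(phi):
    """Wrap angles to (-pi, pi]; the tie at the branch cut resolves to +pi."""
    phi = np.asarray(phi, dtype=float)
    wrapped = np.mod(-phi + np.pi, 2.0 * np.pi)
    out = -(wrapped - np.pi)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HarmonicSpectrum:
    """One-sided amplitude/phase spectrum on the harmonic grid k * fundamental_hz.

    ``amplitudes[k] >= 0``; ``phases[k]`` in (-pi, pi]. Harmonic 0 has phase 0
    for a non-negative mean (phase pi encodes a negative mean so that
    reconstruction is always exact).
    """

    amplitudes: np.ndarray
    phases: np.ndarray
    fundamental_hz: float
    unit_tag: str = ""

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        phis = np.asarray(self.phases, dtype=float)
        if amps.shape != phis.shape or amps.ndim != 1:
            raise ValueError("amplitudes and phases must be 1-D arrays of equal length")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")
        if self.fundamental_hz <= 0:
            raise ValueError("fundamental_hz must be positive")
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "phases", wrap_phase(phis))

    @property
    def n_harmonics(self) -> int:
        """Highest harmonic index (the spectrum covers 0..n_harmonics)."""
        return len(self.amplitudes) - 1

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.arange(len(self.amplitudes)) * self.fundamental_hz

    def with_arrays(self, amplitudes, phases, unit_tag: str | None = None) -> "HarmonicSpectrum":
        return replace(
            self, amplitudes=amplitudes, phases=phases, unit_tag=unit_tag or self.unit_tag
        )


class ImpedanceSpectrum(HarmonicSpectrum):
    """Input-impedance spectrum: pressure per linear velocity, dyn*s/cm^3."""

    def __init__(self, amplitudes, phases, fundamental_hz, unit_tag="impedance_dyn_s_cm3"):
        super().__init__(amplitudes, phases, fundamental_hz, unit_tag)


def decompose(w: Waveform, n_harmonics: int | None = None) -> HarmonicSpectrum:
    """FFT decomposition of one period into harmonics 0..n_harmonics.

    Raises
    ------
    AliasingError
        If ``n_harmonics`` exceeds ``n_samples // 2``.
    """
    n = w.n_samples
    nyq = n // 2
    if n_harmonics is None:
        n_harmonics = nyq
    if n_harmonics > nyq:
        raise AliasingError(f"n_harmonics={n_harmonics} exceeds Nyquist index {nyq} for {n} samples")
    x = np.fft.rfft(w.values)
    scale = np.full(nyq + 1, 2.0 / n)
    scale[0] = 1.0 / n
    if n % 2 == 0:
        scale[nyq] = 1.0 / n  # the Nyquist bin is not doubled
    coeffs = x[: n_harmonics + 1] * scale[: n_harmonics + 1]
    amps = np.abs(coeffs)
    phases = np.angle(coeffs)
    phases[amps == 0] = 0.0
    return HarmonicSpectrum(
        amplitudes=amps,
        phases=phases,
        fundamental_hz=1.0 / w.period,
        unit_tag=w.unit_tag,
    )


def reconstruct(spec: HarmonicSpectrum, n_samples: int, unit_tag: str | None = None) -> Waveform:
    """Cosine-sum reconstruction ``w(t) = a0 cos(phi0) + sum_k a_k cos(2 pi k f1 t + phi_k)``."""
    period = 1.0 / spec.fundamental_hz
    dt = period / n_samples
    t = np.arange(n_samples) * dt
    k = np.arange(len(spec.amplitudes))
    arg = 2.0 * np.pi * np.outer(k, t) * spec.fundamental_hz + spec.phases[:, None]
    values = spec.amplitudes @ np.cos(arg)
    return Waveform(values=values, dt=dt, unit_tag=unit_tag or spec.unit_tag or "pressure_mmHg")


def _check_grids(a: HarmonicSpectrum, b: HarmonicSpectrum) -> None:
    if len(a.amplitudes) != len(b.amplitudes):
        raise ValueError("spectra have different harmonic counts")
    if not np.isclose(a.fundamental_hz, b.fundamental_hz, rtol=1e-9, atol=1e-12):
        raise ValueError(
            f"fundamental frequencies differ: {a.fundamental_hz} vs {b.fundamental_hz}"
        )


def impedance_from_pq(
    p: HarmonicSpectrum, q: HarmonicSpectrum, min_flow_amplitude: float = 1e-12
) -> ImpedanceSpectrum:
    """Impedance spectrum Z_k = P_k / Q_k with pressure converted mmHg -> dyn/cm^2.

    Pressure in mmHg, flow in linear velocity cm/s; the result is in
    dyn*s/cm^3. Phases subtract: ``phi_Z = wrap(phi_P - phi_Q)``.

    Raises
    ------
    UndefinedHarmonicError
        If the flow amplitude vanishes (< ``min_flow_amplitude``) at any
        harmonic; the message flags which harmonics are undefined.
    """
    _check_grids(p, q)
    bad = np.flatnonzero(q.amplitudes < min_flow_amplitude)
    if bad.size:
        raise UndefinedHarmonicError(
            f"flow amplitude below {min_flow_amplitude} at harmonics {bad.tolist()}; "
            "impedance undefined there (drop them or reduce the harmonic count)"
        )
    amps = p.amplitudes * MMHG_TO_DYN_CM2 / q.amplitudes
    phases = wrap_phase(p.phases - q.phases)
    phases = np.where(amps == 0, 0.0, phases)
    return ImpedanceSpectrum(amps, phases, p.fundamental_hz)


def pressure_from_zq(z: ImpedanceSpectrum, q: HarmonicSpectrum) -> HarmonicSpectrum:
    """Forward map: pressure spectrum (mmHg) from impedance and flow spectra."""
    _check_grids(z, q)
    amps = z.amplitudes * q.amplitudes / MMHG_TO_DYN_CM2
    phases = wrap_phase(z.phases + q.phases)
    phases = np.where(amps == 0, 0.0, phases)
    return HarmonicSpectrum(amps, phases, z.fundamental_hz, unit_tag="pressure_mmHg")
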