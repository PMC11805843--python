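"""Afterload metrics derived from impedance spectra and pressure/flow waveforms.

Characteristic impedance (Zc) is the high-frequency plateau of the input
impedance, read here as the outlier-trimmed mean of the 2-10 Hz amplitudes.
With Zc in hand, the pressure wave separates into forward (ventricle-born)
and backward (reflected) components, wave intensity quantifies the energy
flux each carries, and hydraulic work splits the ventricle's external power
into a steady (mean pressure x mean flow) and a pulsatile part.

Internal computation is SI (Pa, m/s, m^3/s, W); inputs and outputs use the
clinical units stated on each function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectral import ImpedanceSpectrum
from .waveforms import MMHG_TO_DYN_CM2, Waveform

logger = logging.getLogger(__name__)

__all__ = [
    "VascularParameters",
    "EmptyBandError",
    "characteristic_impedance",
    "separate_waves",
    "wave_intensity",
    "hydraulic_work",
    "vascular_parameters",
]

MMHG_TO_PA = 133.322
#: dyn*s/cm^3 (pressure per linear velocity, CGS) -> Pa*s/m
ZC_CGS_TO_SI = 10.0
#: presentation scaling for wave-intensity totals (reported as SI x 1e-4)
WI_REPORT_SCALE = 1e-4


class EmptyBandError(ValueError):
    """No impedance harmonics fall in the 2-10 Hz characteristic band."""


@dataclass(frozen=True)
class VascularParameters:
    """Derived afterload metrics.

    ``wi_forward_total`` / ``wi_backward_total`` are in W*m^-2*s^-1, reported
    scaled by 1e-4 (see ``wi_forward_1e4``); ``work_*`` in watts.
    """

    zc: float
    wi_forward_total: float
    wi_backward_total: float
    work_steady: float
    work_pulsatile: float
    work_total: float

    @property
    def wi_forward_1e4(self) -> float:
        return self.wi_forward_total * WI_REPORT_SCALE

    @property
    def wi_backward_1e4(self) -> float:
        return self.wi_backward_total * WI_REPORT_SCALE

    def as_dict(self) -> dict:
        return {
            "zc_dyn_s_cm3": self.zc,
            "wi_forward_1e4": self.wi_forward_1e4,
            "wi_backward_1e4": self.wi_backward_1e4,
            "work_steady_w": self.work_steady,
            "work_pulsatile_w": self.work_pulsatile,
            "work_total_w": self.work_total,
        }


def characteristic_impedance(
    z: ImpedanceSpectrum, band_hz: tuple[float, float] = (2.0, 10.0)
) -> float:
    """Outlier-trimmed mean impedance amplitude over the 2-10 Hz band.

    Single pass: restrict to harmonics with band_hz[0] <= f <= band_hz[1],
    drop amplitudes more than two standard deviations above the band mean,
    return the mean of the remainder (dyn*s/cm^3). If the exclusion empties
    the band the untrimmed mean is returned with a warning.
    """
    f = z.frequencies_hz
    in_band = (f >= band_hz[0]) & (f <= band_hz[1])
    if not np.any(in_band):
        raise EmptyBandError(
            f"no harmonics in [{band_hz[0]}, {band_hz[1]}] Hz "
            f"(fundamental {z.fundamental_hz:.3f} Hz, {z.n_harmonics} harmonics)"
        )
    amps = z.amplitudes[in_band]
    mu = float(np.mean(amps))
    sigma = float(np.std(amps, ddof=1)) if len(amps) > 1 else 0.0
    keep = amps <= mu + 2.0 * sigma
    if not np.any(keep):
        logger.warning("all band harmonics excluded as outliers; returning untrimmed mean")
        return mu
    return float(np.mean(amps[keep]))


def _check_pair(p: Waveform, u: Waveform) -> None:
    if p.n_samples != u.n_samples or not np.isclose(p.dt, u.dt, rtol=1e-9):
        raise ValueError("pressure and velocity waveforms must share the sampling grid")


def separate_waves(p: Waveform, u: Waveform, zc: float) -> tuple[Waveform, Waveform]:
    """Linear wave separation of pressure into forward and backward components.

    ``p`` in mmHg, ``u`` in cm/s, ``zc`` in dyn*s/cm^3. Mean-subtracted
    signals: p_f = (p~ + zc u~)/2, p_b = (p~ - zc u~)/2, with zc applied in
    CGS and the results converted back to mmHg. ``p_f + p_b`` equals the
    mean-subtracted pressure exactly.
    """
    _check_pair(p, u)
    if zc <= 0:
        raise ValueError(f"characteristic impedance must be positive, got {zc}")
    p_cgs = (p.values - p.values.mean()) * MMHG_TO_DYN_CM2
    u_osc = u.values - u.values.mean()
    pf = (p_cgs + zc * u_osc) / 2.0 / MMHG_TO_DYN_CM2
    pb = (p_cgs - zc * u_osc) / 2.0 / MMHG_TO_DYN_CM2
    return p.with_values(pf), p.with_values(pb)


def _periodic_gradient(x: np.ndarray, dt: float) -> np.ndarray:
    """Central differences with periodic wrap."""
    return (np.roll(x, -1) - np.roll(x, 1)) / (2.0 * dt)


def wave_intensity(p: Waveform, u: Waveform, zc: float) -> tuple[float, float]:
    """Total forward and backward wave intensity (W*m^-2*s^-1, SI).

    Time-normalized wave intensity dI = (dp/dt)(du/dt) separates via the
    characteristic impedance into
    ``dI+- = +-(1/(4 zc)) (dp/dt +- zc du/dt)^2``; the totals are the
    trapezoidal time integrals over one period, so the forward total is >= 0
    and the backward total <= 0 by construction. Derivatives are central
    differences with periodic wrap.

    ``p`` in mmHg, ``u`` in cm/s, ``zc`` in dyn*s/cm^3 (converted internally
    to Pa, m/s, Pa*s/m).
    """
    _check_pair(p, u)
    if zc <= 0:
        raise ValueError(f"characteristic impedance must be positive, got {zc}")
    zc_si = zc * ZC_CGS_TO_SI
    dpdt = _periodic_gradient(p.values * MMHG_TO_PA, p.dt)
    dudt = _periodic_gradient(u.values * 0.01, u.dt)
    di_plus = (dpdt + zc_si * dudt) ** 2 / (4.0 * zc_si)
    di_minus = -((dpdt - zc_si * dudt) ** 2) / (4.0 * zc_si)
    closed = lambda x: np.append(x, x[0])
    forward = float(np.trapezoid(closed(di_plus), dx=p.dt))
    backward = float(np.trapezoid(closed(di_minus), dx=p.dt))
    return forward, backward


def hydraulic_work(p: Waveform, q_vol: Waveform) -> tuple[float, float, float]:
    """Steady, pulsatile, and total hydraulic power in watts.

    ``p`` in mmHg, ``q_vol`` volumetric flow in mL/s (linear velocity times
    valve area). Total = (1/T) integral p q dt; steady = mean(p) mean(q);
    pulsatile = total - steady. By Parseval the pulsatile term equals the
    harmonic sum (1/2) sum_k |P_k||Q_k| cos(phi_Pk - phi_Qk).
    """
    _check_pair(p, q_vol)
    p_si = p.values * MMHG_TO_PA
    q_si = q_vol.values * 1e-6
    closed = lambda x: np.append(x, x[0])
    total = float(np.trapezoid(closed(p_si * q_si), dx=p.dt) / p.period)
    steady = float(np.mean(p_si) * np.mean(q_si))
    return steady, total - steady, total


def vascular_parameters(
    z: ImpedanceSpectrum, p: Waveform, u: Waveform, aortic_valve_area: float
) -> VascularParameters:
    """Bundle the full metric set for a pressure/velocity pair and its impedance."""
    zc = characteristic_impedance(z)
    wi_f, wi_b = wave_intensity(p, u, zc)
    q_vol = u.with_values(u.values * aortic_valve_area, unit_tag="flow_mL_s")
    steady, pulsatile, total = hydraulic_work(p, q_vol)
    return VascularParameters(
        zc=zc,
        wi_forward_total=wi_f,
        wi_backward_total=wi_b,
        work_steady=steady,
        work_pulsatile=pulsatile,
        work_total=total,
    )
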