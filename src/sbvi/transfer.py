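"""Generalized transfer function between central aortic and brachial pressure.

Peripheral pulse amplification means the brachial waveform is not the central
one: harmonic amplitudes in the 2-6 Hz band are amplified and phases lag. A
generalized transfer function (GTF) captures this as a per-frequency gain and
phase shift, applied multiplicatively in the harmonic domain. Gain at 0 Hz is
pinned to 1 so mean pressure is preserved, which is the physiological
expectation for a conduit artery.

The default curve shipped here (:func:`default_gtf`) is a synthetic stand-in
with the qualitative shape of published radial/brachial GTFs (amplification
peaking ~1.3x around 3-5 Hz, unity at DC, monotonically accumulating phase
lag); device GTFs are proprietary. Any tabulated curve can be loaded from a
``freq_hz,gain,phase_rad`` CSV to replace it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectral import HarmonicSpectrum, wrap_phase

logger = logging.getLogger(__name__)

__all__ = ["TransferFunction", "IllConditionedInverseError", "default_gtf", "apply_gtf", "invert_gtf"]


class IllConditionedInverseError(ValueError):
    """Inverting the transfer function where its gain is (near) zero."""


@dataclass(frozen=True)
class TransferFunction:
    """Tabulated central-to-brachial gain and phase shift on a frequency grid.

    Linear interpolation between grid points; evaluation beyond the last grid
    point clamps to the last tabulated value (logged once per call).
    """

    freq_hz: np.ndarray
    gain: np.ndarray
    phase_rad: np.ndarray
    direction_tag: str = "central_to_brachial"

    def __post_init__(self) -> None:
        f = np.asarray(self.freq_hz, dtype=float)
        g = np.asarray(self.gain, dtype=float)
        p = np.asarray(self.phase_rad, dtype=float)
        if not (f.shape == g.shape == p.shape) or f.ndim != 1 or len(f) < 2:
            raise ValueError("freq_hz, gain, phase_rad must be equal-length 1-D arrays (>= 2 points)")
        if np.any(np.diff(f) <= 0):
            raise ValueError("freq_hz grid must be strictly increasing")
        if f[0] != 0.0:
            raise ValueError("grid must start at 0 Hz")
        if np.any(g <= 0):
            raise ValueError("gain must be strictly positive everywhere")
        if not np.isclose(g[0], 1.0):
            raise ValueError("gain at 0 Hz must be 1 (mean pressure preserved)")
        object.__setattr__(self, "freq_hz", f)
        object.__setattr__(self, "gain", g)
        object.__setattr__(self, "phase_rad", p)

    def gain_at(self, f) -> np.ndarray:
        self._warn_if_clamped(f)
        return np.interp(f, self.freq_hz, self.gain)

    def phase_at(self, f) -> np.ndarray:
        return np.interp(f, self.freq_hz, self.phase_rad)

    def _warn_if_clamped(self, f) -> None:
        fmax = np.max(np.asarray(f, dtype=float), initial=0.0)
        if fmax > self.freq_hz[-1]:
            logger.info(
                "transfer function evaluated at %.2f Hz beyond tabulated %.2f Hz; clamping",
                fmax,
                self.freq_hz[-1],
            )


def default_gtf() -> TransferFunction:
    """Synthetic stand-in central-to-brachial transfer function.

    Qualitatively shaped like published upper-limb GTFs; not fitted to any
    device. Replace via :func:`sbvi.io.load_transfer_function_csv` when
    validated coefficients are available.
    """
    freq = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 16.0, 20.0])
    gain = np.array([1.00, 1.06, 1.16, 1.27, 1.31, 1.29, 1.24, 1.16, 1.11, 1.08, 1.05, 1.03])
    phase = np.array(
        [0.0, -0.16, -0.34, -0.52, -0.68, -0.80, -0.89, -1.00, -1.06, -1.10, -1.14, -1.16]
    )
    return TransferFunction(freq, gain, phase)


def apply_gtf(central: HarmonicSpectrum, tf: TransferFunction) -> HarmonicSpectrum:
    """Map a central pressure spectrum to the corresponding brachial spectrum.

    Per harmonic: amplitude times gain(f_k), phase plus phase_shift(f_k);
    the DC term is left untouched.
    """
    f = central.frequencies_hz
    gain = tf.gain_at(f)
    shift = tf.phase_at(f)
    gain[0] = 1.0
    shift[0] = 0.0
    return central.with_arrays(
        central.amplitudes * gain, wrap_phase(central.phases + shift)
    )


def invert_gtf(
    brachial: HarmonicSpectrum, tf: TransferFunction, min_gain: float = 1e-6
) -> HarmonicSpectrum:
    """Recover the central spectrum from a brachial one (exact algebraic inverse)."""
    f = brachial.frequencies_hz
    gain = tf.gain_at(f)
    shift = tf.phase_at(f)
    gain[0] = 1.0
    shift[0] = 0.0
    if np.any(gain < min_gain):
        raise IllConditionedInverseError(
            f"transfer-function gain below {min_gain} at a used harmonic; inverse ill-conditioned"
        )
    return brachial.with_arrays(
        brachial.amplitudes / gain, wrap_phase(brachial.phases - shift)
    )
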