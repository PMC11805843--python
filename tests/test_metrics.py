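"""Characteristic impedance, wave separation, wave intensity, hydraulic work."""

import numpy as np
import pytest

from sbvi.metrics import (
    EmptyBandError,
    MMHG_TO_PA,
    ZC_CGS_TO_SI,
    characteristic_impedance,
    hydraulic_work,
    separate_waves,
    wave_intensity,
)
from sbvi.spectral import ImpedanceSpectrum, decompose
from sbvi.waveforms import MMHG_TO_DYN_CM2, Waveform


def make_wave(values, period=0.8, unit="pressure_mmHg"):
    values = np.asarray(values, dtype=float)
    return Waveform(values=values, dt=period / len(values), unit_tag=unit)


class TestCharacteristicImpedance:
    def test_flat_band(self):
        # f1 = 1.25 Hz -> harmonics 2..8 lie in [2, 10] Hz
        z = ImpedanceSpectrum(np.full(11, 90.0), np.zeros(11), 1.25)
        assert characteristic_impedance(z) == pytest.approx(90.0)

    def test_outlier_exclusion_matches_enumeration_oracle(self):
        band = np.array([80.0, 82.0, 84.0, 86.0, 88.0, 90.0, 92.0, 94.0, 800.0])
        amps = np.concatenate([[1000.0, 200.0, 150.0], band])  # h3..h11 = band
        f1 = 0.9  # harmonics 3..11 at 2.7..9.9 Hz all in [2, 10] Hz
        z = ImpedanceSpectrum(amps, np.zeros_like(amps), f1)
        freqs = np.arange(len(amps)) * f1
        in_band = amps[(freqs >= 2) & (freqs <= 10)]
        mu, sd = in_band.mean(), in_band.std(ddof=1)
        kept = in_band[in_band <= mu + 2 * sd]
        assert len(kept) == len(in_band) - 1  # the 800 outlier really is dropped
        assert characteristic_impedance(z) == pytest.approx(kept.mean())

    def test_single_pass_not_iterated(self):
        # after one exclusion the remaining values are NOT re-screened
        band = np.array([10.0, 10.0, 10.0, 10.0, 30.0, 1000.0])
        f1 = 1.3  # harmonics 2..7 at 2.6..9.1 Hz
        amps = np.concatenate([[500.0, 100.0], band])
        z = ImpedanceSpectrum(amps, np.zeros_like(amps), f1)
        mu, sd = band.mean(), band.std(ddof=1)
        kept = band[band <= mu + 2 * sd]
        assert characteristic_impedance(z) == pytest.approx(kept.mean())

    def test_empty_band_raises(self):
        z = ImpedanceSpectrum([100.0, 90.0], [0.0, 0.0], fundamental_hz=0.5)
        with pytest.raises(EmptyBandError):
            characteristic_impedance(z)


class TestWaveSeparation:
    def test_matched_load_has_no_backward_wave(self, rng):
        zc = 90.0
        u = make_wave(rng.uniform(0, 200, 256), unit="velocity_cm_s")
        p_vals = zc * (u.values - u.values.mean()) / MMHG_TO_DYN_CM2 + 95.0
        p = make_wave(p_vals)
        pf, pb = separate_waves(p, u, zc)
        np.testing.assert_allclose(pb.values, 0.0, atol=1e-9)
        np.testing.assert_allclose(pf.values, p.values - p.values.mean(), atol=1e-9)

    def test_closed_end_splits_evenly(self):
        p = make_wave(100 + 20 * np.sin(np.linspace(0, 2 * np.pi, 128, endpoint=False)))
        u = make_wave(np.zeros(128), unit="velocity_cm_s")
        pf, pb = separate_waves(p, u, 50.0)
        ptilde = p.values - p.values.mean()
        np.testing.assert_allclose(pf.values, ptilde / 2, atol=1e-12)
        np.testing.assert_allclose(pb.values, ptilde / 2, atol=1e-12)

    def test_reconstruction_identity_and_hand_formula(self, rng):
        zc = 120.0
        p = make_wave(rng.normal(100, 15, 256))
        u = make_wave(rng.normal(80, 40, 256), unit="velocity_cm_s")
        pf, pb = separate_waves(p, u, zc)
        ptilde = p.values - p.values.mean()
        utilde = u.values - u.values.mean()
        np.testing.assert_allclose(pf.values + pb.values, ptilde, atol=1e-9)
        expected_pf = (ptilde * MMHG_TO_DYN_CM2 + zc * utilde) / 2 / MMHG_TO_DYN_CM2
        np.testing.assert_allclose(pf.values, expected_pf, atol=1e-12)

    def test_invalid_zc_rejected(self):
        p = make_wave(np.ones(64) * 100)
        u = make_wave(np.zeros(64), unit="velocity_cm_s")
        with pytest.raises(ValueError):
            separate_waves(p, u, -5.0)


class TestWaveIntensity:
    def test_matched_load_backward_is_zero(self, rng):
        zc = 90.0
        t = np.linspace(0, 1, 256, endpoint=False)
        u_vals = 150 * np.clip(np.sin(2 * np.pi * t), 0, None)
        u = make_wave(u_vals, unit="velocity_cm_s")
        p = make_wave(zc * u_vals / MMHG_TO_DYN_CM2 + 90.0)
        wf, wb = wave_intensity(p, u, zc)
        assert wb == pytest.approx(0.0, abs=1e-9)
        assert wf > 0

    def test_constant_signals_have_no_intensity(self):
        p = make_wave(np.full(128, 100.0))
        u = make_wave(np.full(128, 50.0), unit="velocity_cm_s")
        wf, wb = wave_intensity(p, u, 80.0)
        assert wf == pytest.approx(0.0, abs=1e-12)
        assert wb == pytest.approx(0.0, abs=1e-12)

    def test_sum_identity_and_brute_force_totals(self, rng):
        """dI+ + dI- = (dp/dt)(du/dt) pointwise; totals match direct summation."""
        zc = 110.0
        p = make_wave(rng.normal(100, 10, 256))
        u = make_wave(rng.normal(60, 30, 256), unit="velocity_cm_s")
        wf, wb = wave_intensity(p, u, zc)

        # independent re-computation from first principles
        zc_si = zc * ZC_CGS_TO_SI
        dt = p.dt
        p_si, u_si = p.values * MMHG_TO_PA, u.values * 0.01
        dpdt = (np.roll(p_si, -1) - np.roll(p_si, 1)) / (2 * dt)
        dudt = (np.roll(u_si, -1) - np.roll(u_si, 1)) / (2 * dt)
        di_p = (dpdt + zc_si * dudt) ** 2 / (4 * zc_si)
        di_m = -((dpdt - zc_si * dudt) ** 2) / (4 * zc_si)
        np.testing.assert_allclose(di_p + di_m, dpdt * dudt, rtol=1e-9, atol=1e-6)
        # periodic uniform grid: trapezoid equals the plain Riemann sum
        assert wf == pytest.approx(float(di_p.sum() * dt), rel=1e-9)
        assert wb == pytest.approx(float(di_m.sum() * dt), rel=1e-9)
        assert wf >= 0 >= wb


class TestHydraulicWork:
    def test_dc_only_closed_form(self):
        p = make_wave(np.full(128, 100.0))
        q = make_wave(np.full(128, 83.0), unit="flow_mL_s")
        steady, pulsatile, total = hydraulic_work(p, q)
        assert steady == pytest.approx(100 * MMHG_TO_PA * 83e-6)  # 1.1066 W
        assert pulsatile == pytest.approx(0.0, abs=1e-12)
        assert total == pytest.approx(steady)

    def test_single_harmonic_oscillatory_power(self):
        """Pulsatile power of one harmonic equals (1/2)|P1||Q1|cos(phi)."""
        t = np.linspace(0, 0.8, 512, endpoint=False)
        f1 = 1.25
        amp_p, amp_q, phase_gap = 20.0, 150.0, 0.7
        p = make_wave(95 + amp_p * np.cos(2 * np.pi * f1 * t))
        q = make_wave(
            90 + amp_q * np.cos(2 * np.pi * f1 * t - phase_gap), unit="flow_mL_s"
        )
        steady, pulsatile, total = hydraulic_work(p, q)
        expected = 0.5 * (amp_p * MMHG_TO_PA) * (amp_q * 1e-6) * np.cos(phase_gap)
        assert pulsatile == pytest.approx(expected, rel=1e-9)
        assert total == pytest.approx(steady + pulsatile, abs=1e-9)

    def test_parseval_frequency_domain_agreement(self, rng):
        """Time-domain work equals the harmonic-sum (Parseval) evaluation."""
        p = make_wave(rng.normal(100, 12, 512))
        q = make_wave(rng.normal(90, 35, 512), unit="flow_mL_s")
        steady, pulsatile, total = hydraulic_work(p, q)
        ps, qs = decompose(p, 256), decompose(q, 256)
        dc = (ps.amplitudes[0] * np.cos(ps.phases[0]) * MMHG_TO_PA) * (
            qs.amplitudes[0] * np.cos(qs.phases[0]) * 1e-6
        )
        # the Nyquist bin carries weight 1, every other harmonic 1/2
        weights = np.full(256, 0.5)
        weights[-1] = 1.0
        osc = float(
            np.sum(
                weights
                * (ps.amplitudes[1:] * MMHG_TO_PA)
                * (qs.amplitudes[1:] * 1e-6)
                * np.cos(ps.phases[1:] - qs.phases[1:])
            )
        )
        assert total == pytest.approx(dc + osc, rel=1e-6)
        assert steady == pytest.approx(dc, rel=1e-9)

    def test_work_additivity(self, rng):
        p = make_wave(rng.normal(100, 12, 256))
        q = make_wave(rng.normal(90, 35, 256), unit="flow_mL_s")
        steady, pulsatile, total = hydraulic_work(p, q)
        assert total == pytest.approx(steady + pulsatile, abs=1e-9)
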