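"""Monte-Carlo inverse engine: candidates, bounding criteria, end-to-end runs."""

import numpy as np
import pytest
from scipy import stats

from sbvi.engine import (
    BoundingCriteria,
    ImpedanceBounds,
    bounds_around,
    check_patient_specific,
    check_physiologic_criteria,
    circular_median,
    generate_candidates,
    run_sbvi,
)
from sbvi.metrics import characteristic_impedance
from sbvi.synthetic import make_synthetic_patient
from sbvi.waveforms import EchoInputs, Waveform


from waveshapes import criteria_oracle, make_pressure, simple_flow, textbook_pressure


class TestGenerateCandidates:
    def bounds(self):
        return ImpedanceBounds(
            amplitude_min=[800, 100, 50],
            amplitude_max=[1200, 300, 150],
            phase_min=[0, -1.0, -0.8],
            phase_max=[0, 0.2, 0.3],
            expansion_fraction=0.20,
        )

    def test_degenerate_bounds_yield_boundary_spectrum(self):
        b = ImpedanceBounds([1000.0, 200.0], [1000.0, 200.0], [0, -0.5], [0, -0.5], 0.0)
        cs = generate_candidates(b, 1, seed=0)
        np.testing.assert_allclose(cs.amplitudes[0], [1000.0, 200.0])
        np.testing.assert_allclose(cs.phases[0], [0.0, -0.5])

    def test_within_expanded_bounds_and_uniform(self):
        b = self.bounds()
        cs = generate_candidates(b, 10_000, seed=3)
        alo, ahi, plo, phi = b.expanded()
        assert np.all(cs.amplitudes >= alo) and np.all(cs.amplitudes <= ahi)
        # Kolmogorov-Smirnov against uniform on the expanded range, harmonic 1
        u = (cs.amplitudes[:, 1] - alo[1]) / (ahi[1] - alo[1])
        assert stats.kstest(u, "uniform").pvalue > 0.01
        u_ph = (cs.phases[:, 2] - plo[2]) / (phi[2] - plo[2])
        assert stats.kstest(u_ph, "uniform").pvalue > 0.01

    def test_expansion_widens_by_fraction_of_width(self):
        b = self.bounds()
        alo, ahi, _, _ = b.expanded()
        width = 300 - 100
        assert alo[1] == pytest.approx(100 - 0.1 * width)
        assert ahi[1] == pytest.approx(300 + 0.1 * width)

    def test_same_seed_reproduces(self):
        b = self.bounds()
        a = generate_candidates(b, 500, seed=11)
        c = generate_candidates(b, 500, seed=11)
        np.testing.assert_array_equal(a.amplitudes, c.amplitudes)
        np.testing.assert_array_equal(a.phases, c.phases)


class TestPhysiologicCriteria:
    def test_textbook_shape_passes_all(self):
        ed = 0.35
        flags = check_physiologic_criteria(
            textbook_pressure(ed=ed), simple_flow(ed=ed), ed
        )
        assert flags.as_dict() == {k: True for k in flags.as_dict()}

    def test_late_peak_fails_only_timing_criteria(self):
        ed = 0.35
        p = textbook_pressure(ed=ed)
        shifted = make_pressure(np.roll(p.values, p.n_samples // 2))
        flags = check_physiologic_criteria(shifted, simple_flow(ed=ed), ed)
        assert not flags.peak_in_systole
        # the unshifted waveform's flags are unaffected
        assert check_physiologic_criteria(p, simple_flow(ed=ed), ed).passed

    def test_unbounded_dicrotic_wave_fails(self):
        ed = 0.35
        p = textbook_pressure(ed=ed, dicrotic=8.0)
        flags = check_physiologic_criteria(p, simple_flow(ed=ed), ed)
        assert not (flags.dicrotic_bounded and flags.diastolic_decay)

    def test_flat_waveform_fails_by_convention(self):
        ed = 0.35
        flags = check_physiologic_criteria(
            make_pressure(np.full(512, 100.0)), simple_flow(ed=ed), ed
        )
        assert not flags.first_max_is_global

    def test_dual_implementation_oracle_on_random_candidates(self, rng):
        """Flags agree with an independent loop-based oracle on 1000 waveforms."""
        ed = 0.35
        flow = simple_flow(ed=ed)
        crit = BoundingCriteria()
        n_disagreements = 0
        for _ in range(1000):
            base = textbook_pressure(ed=ed, dicrotic=rng.uniform(0, 6)).values
            noise = rng.normal(0, rng.uniform(0, 2), size=base.size)
            # smooth the noise so waveforms resemble reconstructed candidates
            kernel = np.ones(9) / 9
            p = make_pressure(base + np.convolve(noise, kernel, mode="same"))
            flags = check_physiologic_criteria(p, flow, ed, crit)
            expected = criteria_oracle(p, flow, ed, crit)
            if tuple(flags.as_dict().values()) != expected:
                n_disagreements += 1
        assert n_disagreements == 0


class TestPatientSpecific:
    def echo(self):
        return EchoInputs(75, 425, 0.119, 74, 0.71, systolic_bp=138.0, diastolic_bp=75.0)

    def make_bp_wave(self, sbp, dbp):
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        vals = dbp + (sbp - dbp) * (0.5 - 0.5 * np.cos(t))
        return make_pressure(vals)

    def test_exact_match_passes(self):
        assert check_patient_specific(self.make_bp_wave(138.0, 75.0), self.echo())

    def test_just_outside_tolerance_fails(self):
        assert not check_patient_specific(self.make_bp_wave(140.6, 75.0), self.echo())

    def test_boundary_is_inclusive(self):
        assert check_patient_specific(self.make_bp_wave(140.5, 75.0), self.echo())


class TestCircularMedian:
    def test_odd_set_matches_linear_median_away_from_cut(self):
        assert circular_median(np.array([-0.2, 0.1, 0.3])) == pytest.approx(0.1)

    def test_wraps_across_branch_cut(self):
        angles = np.array([3.0, -3.0, 3.1])  # clustered around +-pi
        med = circular_median(angles)
        assert med in (3.0, -3.0, 3.1)
        # the minimizer must beat the naive linear median (0 would be terrible)
        dev = lambda a: np.abs(
            np.angle(np.exp(1j * (angles - a)))
        ).sum()
        assert dev(med) <= dev(0.0)


class TestRunSBVI:
    def test_forced_unique_candidate_recovers_truth(self):
        """Degenerate bounds pinned at the true spectrum recover it exactly."""
        pat = make_synthetic_patient(seed=3)
        z = pat.true_impedance
        bounds = ImpedanceBounds(
            z.amplitudes, z.amplitudes, z.phases, z.phases, expansion_fraction=0.0
        )
        res = run_sbvi(pat.echo, bounds, n_candidates=1, seed=0)
        assert res.n_passing == 1
        np.testing.assert_allclose(res.median_impedance.amplitudes, z.amplitudes)
        np.testing.assert_allclose(res.median_impedance.phases, z.phases, atol=1e-12)

    def test_recovery_within_tolerance(self):
        """Bounds bracketing truth +-30%: Zc within 15%, mean BP within 2.5 mmHg."""
        pat = make_synthetic_patient(seed=7)
        res = run_sbvi(pat.echo, bounds_around(pat.true_impedance), n_candidates=30_000, seed=1)
        assert res.n_passing > 0
        zc_true = characteristic_impedance(pat.true_impedance)
        assert res.parameters.zc == pytest.approx(zc_true, rel=0.15)
        assert res.median_central_waveform.values.mean() == pytest.approx(
            pat.true_central_pressure.values.mean(), abs=2.5
        )

    def test_determinism_and_chunk_independence(self):
        pat = make_synthetic_patient(seed=5)
        bounds = bounds_around(pat.true_impedance)
        r1 = run_sbvi(pat.echo, bounds, n_candidates=20_000, seed=9, chunk_size=8192)
        r2 = run_sbvi(pat.echo, bounds, n_candidates=20_000, seed=9, chunk_size=1777)
        assert r1.n_passing == r2.n_passing
        np.testing.assert_array_equal(
            r1.median_impedance.amplitudes, r2.median_impedance.amplitudes
        )
        np.testing.assert_array_equal(
            r1.median_central_waveform.values, r2.median_central_waveform.values
        )
        assert r1.parameters.as_dict() == r2.parameters.as_dict()

    def test_survivors_repass_all_checks(self):
        """Every survivor re-passes the seven checks when re-tested one by one."""
        pat = make_synthetic_patient(seed=5)
        res = run_sbvi(pat.echo, bounds_around(pat.true_impedance), n_candidates=20_000, seed=2)
        assert res.n_passing > 0
        from sbvi.spectral import decompose, pressure_from_zq, reconstruct
        from sbvi.transfer import apply_gtf, default_gtf

        q = decompose(res.flow, n_harmonics=res.passing_impedance.amplitudes.shape[1] - 1)
        tf = default_gtf()
        for i in range(res.n_passing):
            z = res.passing_impedance[i]
            p_spec = pressure_from_zq(z, q)
            central = reconstruct(p_spec, res.flow.n_samples)
            brachial = reconstruct(apply_gtf(p_spec, tf), res.flow.n_samples)
            assert check_patient_specific(brachial, pat.echo)
            assert check_physiologic_criteria(
                central, res.flow, res.ejection_duration
            ).passed
            np.testing.assert_allclose(
                central.values, res.passing_central_waveforms[i].values, atol=1e-8
            )

    def test_survivor_count_monotone_in_bp_tolerance(self):
        pat = make_synthetic_patient(seed=8)
        bounds = bounds_around(pat.true_impedance)
        counts = [
            run_sbvi(
                pat.echo,
                bounds,
                crit=BoundingCriteria(bp_tolerance=tol),
                n_candidates=15_000,
                seed=4,
            ).n_passing
            for tol in (1.0, 2.5, 5.0)
        ]
        assert counts[0] <= counts[1] <= counts[2]

    def test_survivor_count_scales_roughly_linearly(self):
        """10x more candidates yield ~10x more survivors (within a factor 3)."""
        pat = make_synthetic_patient(seed=3)
        bounds = bounds_around(pat.true_impedance)
        n_small = run_sbvi(pat.echo, bounds, n_candidates=10_000, seed=6).n_passing
        n_large = run_sbvi(pat.echo, bounds, n_candidates=100_000, seed=6).n_passing
        assert n_small > 0
        ratio = n_large / n_small
        assert 10 / 3 <= ratio <= 10 * 3

    def test_empty_solution_set_reported_not_raised(self):
        pat = make_synthetic_patient(seed=3)
        z = pat.true_impedance
        # bounds far from truth: nothing can match the cuff pressures
        bounds = ImpedanceBounds(
            z.amplitudes * 8, z.amplitudes * 9, z.phases, z.phases, 0.0
        )
        res = run_sbvi(pat.echo, bounds, n_candidates=2_000, seed=0)
        assert res.n_passing == 0
        assert res.median_impedance is None and res.parameters is None
        assert sum(res.rejection_counts.values()) >= 2_000

    def test_central_calibration_mode(self):
        pat = make_synthetic_patient(seed=4)
        res = run_sbvi(
            pat.echo,
            bounds_around(pat.true_impedance),
            n_candidates=20_000,
            seed=3,
            calibration_mode="central",
            central_waveform=pat.true_central_pressure,
        )
        assert res.n_passing > 0
        # central-extrema calibration pins the central waveform even tighter
        assert abs(
            res.median_central_waveform.values.max()
            - pat.true_central_pressure.values.max()
        ) <= 2.5
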