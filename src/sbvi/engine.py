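"""Monte-Carlo inverse search for the aortic input impedance spectrum.

The inverse problem: given a patient's flow waveform (from echo scalars) and
only a brachial cuff pressure, find the impedance spectrum. Candidate
spectra are drawn uniformly within physiologic per-harmonic bounds (widened
by 20% to cover pathophysiology), each is pushed through the forward model
(impedance x flow -> central pressure -> transfer function -> brachial
pressure), and candidates survive only if the implied brachial extrema match
the cuff reading within tolerance and the central waveform looks like a
human pressure waveform (six knowledge-based criteria). Medians over the
survivors give the reported impedance, central waveform, and afterload
metrics.

Candidate evaluation is chunked so memory stays constant in the candidate
count; results are independent of chunk size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import metrics as _metrics
from .spectral import ImpedanceSpectrum, decompose, wrap_phase
from .transfer import TransferFunction, default_gtf
from .waveforms import (
    MMHG_TO_DYN_CM2,
    EchoInputs,
    Waveform,
    optimize_ejection_duration,
    synthesize_flow,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ImpedanceBounds",
    "BoundingCriteria",
    "CandidateSet",
    "PhysiologicFlags",
    "SBVIResult",
    "generate_candidates",
    "check_physiologic_criteria",
    "check_patient_specific",
    "bounds_around",
    "run_sbvi",
    "circular_median",
]

CRITERION_NAMES = (
    "diastolic_decay",
    "peak_in_systole",
    "start_near_minimum",
    "dicrotic_bounded",
    "first_max_is_global",
    "peak_after_peak_flow",
)


@dataclass(frozen=True)
class ImpedanceBounds:
    """Per-harmonic uniform sampling ranges for candidate impedance spectra.

    Each array has one entry per harmonic 0..K. ``expansion_fraction`` widens
    every range symmetrically by that fraction of its width before sampling
    (default 20%), so the search covers states beyond the literature table it
    was built from. Phase ranges for harmonic 0 should be [0, 0].
    """

    amplitude_min: np.ndarray
    amplitude_max: np.ndarray
    phase_min: np.ndarray
    phase_max: np.ndarray
    expansion_fraction: float = 0.20

    def __post_init__(self) -> None:
        for name in ("amplitude_min", "amplitude_max", "phase_min", "phase_max"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        shapes = {
            self.amplitude_min.shape,
            self.amplitude_max.shape,
            self.phase_min.shape,
            self.phase_max.shape,
        }
        if len(shapes) != 1 or self.amplitude_min.ndim != 1:
            raise ValueError("bound arrays must be 1-D and of equal length")
        if self.expansion_fraction < 0:
            raise ValueError("expansion_fraction must be >= 0")
        if np.any(self.amplitude_min > self.amplitude_max) or np.any(
            self.phase_min > self.phase_max
        ):
            raise ValueError("min bound exceeds max bound at some harmonic")

    @property
    def n_harmonics(self) -> int:
        return len(self.amplitude_min) - 1

    def expanded(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Bounds after symmetric widening; amplitude floors clamp at zero."""
        half = 0.5 * self.expansion_fraction
        aw = self.amplitude_max - self.amplitude_min
        pw = self.phase_max - self.phase_min
        alo = np.maximum(self.amplitude_min - half * aw, 0.0)
        ahi = self.amplitude_max + half * aw
        plo = self.phase_min - half * pw
        phi = self.phase_max + half * pw
        return alo, ahi, plo, phi


@dataclass(frozen=True)
class BoundingCriteria:
    """Thresholds for the domain-bounding filters (all mmHg, all > 0)."""

    bp_tolerance: float = 2.5
    start_min_gap: float = 1.0
    dicrotic_gap: float = 3.0

    def __post_init__(self) -> None:
        for name in ("bp_tolerance", "start_min_gap", "dicrotic_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CandidateSet:
    """A batch of candidate impedance spectra as dense arrays (n, K+1)."""

    amplitudes: np.ndarray
    phases: np.ndarray
    fundamental_hz: float

    def __len__(self) -> int:
        return len(self.amplitudes)

    def __getitem__(self, i: int) -> ImpedanceSpectrum:
        return ImpedanceSpectrum(self.amplitudes[i], self.phases[i], self.fundamental_hz)

    def __iter__(self):
        return (self[i] for i in range(len(self)))


def generate_candidates(
    bounds: ImpedanceBounds, n: int, seed: int, fundamental_hz: float = 1.25
) -> CandidateSet:
    """Draw ``n`` candidate spectra uniformly within the expanded bounds.

    Every harmonic's amplitude and phase is drawn independently; the draw is
    reproducible for a fixed seed regardless of how the result is later
    chunked.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    amps, phases = _draw_block(rng, bounds.expanded(), n)
    return CandidateSet(amps, wrap_phase(phases), fundamental_hz)


def _draw_block(
    rng: np.random.Generator, expanded: tuple, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n candidates as one row-contiguous uniform block.

    One (n, 2(K+1)) draw, split into amplitudes and phases, so that consuming
    the stream in chunks of rows yields exactly the same candidates as one
    large draw: survivor sets are independent of chunk size.
    """
    alo, ahi, plo, phi = expanded
    k1 = len(alo)
    u = rng.uniform(size=(n, 2 * k1))
    amps = alo + u[:, :k1] * (ahi - alo)
    phases = plo + u[:, k1:] * (phi - plo)
    phases[:, 0] = 0.0
    return amps, phases


@dataclass(frozen=True)
class PhysiologicFlags:
    """Outcome of the six knowledge-based waveform criteria."""

    diastolic_decay: bool
    peak_in_systole: bool
    start_near_minimum: bool
    dicrotic_bounded: bool
    first_max_is_global: bool
    peak_after_peak_flow: bool

    @property
    def passed(self) -> bool:
        return all(
            getattr(self, name) for name in CRITERION_NAMES
        )

    def as_dict(self) -> dict[str, bool]:
        return {name: bool(getattr(self, name)) for name in CRITERION_NAMES}


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior strict local maxima/minima; plateaus take their first sample."""
    n = len(x)
    maxima, minima = [], []
    i = 1
    while i < n - 1:
        j = i
        while j < n - 1 and x[j + 1] == x[j]:
            j += 1  # skip plateau; candidate extremum is its first sample i
        if j >= n - 1:
            break
        if x[i - 1] < x[i] and x[j + 1] < x[j]:
            maxima.append(i)
        elif x[i - 1] > x[i] and x[j + 1] > x[j]:
            minima.append(i)
        i = j + 1
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def check_physiologic_criteria(
    p: Waveform, flow: Waveform, ejection_duration: float, crit: BoundingCriteria | None = None
) -> PhysiologicFlags:
    """Evaluate the six knowledge-based criteria on a central pressure waveform.

    1. pressure decays after end-systole: non-increasing from the end of
       ejection to the end of the cycle, allowing at most one contiguous
       (dicrotic) rise of no more than ``dicrotic_gap`` mmHg;
    2. peak pressure does not occur after end-systole;
    3. initial pressure exceeds the cycle minimum by less than
       ``start_min_gap`` mmHg;
    4. the first local maximum after peak pressure (if any) is no more than
       ``dicrotic_gap`` mmHg above the first local minimum after the peak;
    5. the first local maximum is the global maximum (flat waveforms with no
       interior local maximum fail by convention);
    6. peak pressure occurs strictly after peak flow.

    End-systole is the flow model's ejection duration. Extrema are strict
    against both neighbours on the sampled grid; plateaus take their first
    sample. The flags are evaluated independently of each other.
    """
    crit = crit or BoundingCriteria()
    if p.n_samples != flow.n_samples or not np.isclose(p.dt, flow.dt, rtol=1e-9):
        raise ValueError("pressure and flow must share the sampling grid")
    x = p.values
    i_es = min(int(round(ejection_duration / p.dt)), p.n_samples - 1)
    i_peak = int(np.argmax(x))

    # 1: diastolic decay with at most one bounded dicrotic excursion
    tail = x[i_es:]
    rises = np.diff(tail) > 0
    if not rises.any():
        c1 = True
    else:
        n_runs = int(rises[0]) + int((np.diff(rises.astype(int)) == 1).sum())
        if n_runs > 1:
            c1 = False
        else:
            total_rise = float(np.sum(np.diff(tail)[rises]))
            c1 = total_rise <= crit.dicrotic_gap

    # 2: peak not after end-systole
    c2 = i_peak <= i_es

    # 3: initial pressure close to the minimum
    c3 = (x[0] - float(x.min())) < crit.start_min_gap

    maxima, minima = _local_extrema(x)

    # 4: dicrotic wave bounded relative to the incisura
    max_after = maxima[maxima > i_peak]
    min_after = minima[minima > i_peak]
    if max_after.size == 0:
        c4 = True
    elif min_after.size == 0:
        c4 = False  # a secondary rise with no preceding trough is non-physiologic
    else:
        c4 = (x[max_after[0]] - x[min_after[0]]) <= crit.dicrotic_gap

    # 5: first local maximum is the global maximum
    c5 = maxima.size > 0 and x[maxima[0]] == x[i_peak]

    # 6: peak pressure after peak flow
    c6 = i_peak > int(np.argmax(flow.values))

    return PhysiologicFlags(c1, c2, c3, c4, c5, c6)


def check_patient_specific(
    brachial: Waveform, echo: EchoInputs, crit: BoundingCriteria | None = None
) -> bool:
    """Do the brachial waveform extrema match the cuff reading within tolerance?

    Inclusive at exactly ``bp_tolerance`` mmHg on both the systolic and the
    diastolic side.
    """
    crit = crit or BoundingCriteria()
    return bool(
        abs(float(brachial.values.max()) - echo.systolic_bp) <= crit.bp_tolerance
        and abs(float(brachial.values.min()) - echo.diastolic_bp) <= crit.bp_tolerance
    )


def circular_median(angles: np.ndarray) -> float:
    """Circular median: the sample minimizing summed absolute angular deviation.

    Ties resolve to the first index in input order.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle set")
    dev = np.abs(wrap_phase(angles[:, None] - angles[None, :])).sum(axis=1)
    return float(angles[int(np.argmin(dev))])


@dataclass(frozen=True)
class SBVIResult:
    """Outcome of one inverse run.

    ``rejection_counts`` records, per filter, how many candidates it rejected
    (patient-specific BP first, then each physiologic criterion evaluated on
    the BP-surviving subset). An empty survivor set is a reportable outcome,
    not an error: medians and parameters are then ``None``.
    """

    n_candidates: int
    n_passing: int
    passing_central_waveforms: list[Waveform]
    passing_impedance: CandidateSet | None
    median_central_waveform: Waveform | None
    median_impedance: ImpedanceSpectrum | None
    parameters: "_metrics.VascularParameters | None"
    flow: Waveform
    ejection_duration: float
    rejection_counts: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        if self.n_passing > self.n_candidates:
            raise ValueError("n_passing cannot exceed n_candidates")


def bounds_around(
    z: ImpedanceSpectrum,
    amplitude_fraction: float = 0.30,
    phase_halfwidth: float = 0.30,
    expansion_fraction: float = 0.20,
) -> ImpedanceBounds:
    """Bounds bracketing a known spectrum: amplitude +-fraction, phase +-radians."""
    amp = z.amplitudes
    return ImpedanceBounds(
        amplitude_min=amp * (1.0 - amplitude_fraction),
        amplitude_max=amp * (1.0 + amplitude_fraction),
        phase_min=np.where(np.arange(len(amp)) == 0, 0.0, z.phases - phase_halfwidth),
        phase_max=np.where(np.arange(len(amp)) == 0, 0.0, z.phases + phase_halfwidth),
        expansion_fraction=expansion_fraction,
    )


def _reconstruct_batch(
    amps: np.ndarray, phases: np.ndarray, n_samples: int, fundamental_hz: float
) -> np.ndarray:
    """Cosine-sum reconstruction of many spectra at once -> (n, n_samples)."""
    k = np.arange(amps.shape[1])
    t = np.arange(n_samples) / (n_samples * fundamental_hz)
    base = 2.0 * np.pi * fundamental_hz * np.outer(k, t)  # (K+1, n_samples)
    cos_b, sin_b = np.cos(base), np.sin(base)
    return (amps * np.cos(phases)) @ cos_b - (amps * np.sin(phases)) @ sin_b


def run_sbvi(
    echo: EchoInputs,
    bounds: ImpedanceBounds,
    crit: BoundingCriteria | None = None,
    tf: TransferFunction | None = None,
    n_candidates: int = 100_000,
    seed: int = 0,
    calibration_mode: str = "brachial",
    central_waveform: Waveform | None = None,
    n_samples: int = 512,
    chunk_size: int = 8192,
) -> SBVIResult:
    """Run the full inverse search for one patient.

    Pipeline: optimize the ejection duration, synthesize the flow waveform,
    decompose it, then for each candidate impedance spectrum solve for the
    central pressure, map it through the transfer function, and keep the
    candidates whose (brachial or central, per ``calibration_mode``) pressure
    extrema match the cuff reading within tolerance and whose central
    waveform passes the six physiologic criteria. Per-harmonic median
    amplitude and circular-median phase over the survivors give the reported
    impedance; the median central waveform is pointwise; afterload metrics
    are computed from the median quantities.

    In ``calibration_mode="central"`` the patient-specific extrema check is
    applied to the central (pre-transfer-function) waveform against the
    extrema of ``central_waveform``, which must be supplied.
    """
    crit = crit or BoundingCriteria()
    tf = tf or default_gtf()
    if calibration_mode not in ("brachial", "central"):
        raise ValueError("calibration_mode must be 'brachial' or 'central'")
    if calibration_mode == "central":
        if central_waveform is None:
            raise ValueError("central calibration requires a central waveform")
        target_sbp = float(central_waveform.values.max())
        target_dbp = float(central_waveform.values.min())
    else:
        target_sbp, target_dbp = echo.systolic_bp, echo.diastolic_bp

    ed = optimize_ejection_duration(echo, n_samples=n_samples)
    flow = synthesize_flow(echo, ed, n_samples=n_samples)
    n_harm = bounds.n_harmonics
    q = decompose(flow, n_harmonics=n_harm)
    f1 = q.fundamental_hz
    freqs = q.frequencies_hz
    gain = tf.gain_at(freqs)
    shift = tf.phase_at(freqs)
    gain[0], shift[0] = 1.0, 0.0

    alo, ahi, plo, phi = bounds.expanded()
    rng = np.random.default_rng(seed)
    i_flow_peak = int(np.argmax(flow.values))

    rejections = {"bp_match": 0, **{name: 0 for name in CRITERION_NAMES}}
    surv_amp, surv_phase, surv_wave = [], [], []

    remaining = n_candidates
    while remaining > 0:
        m = min(chunk_size, remaining)
        remaining -= m
        z_amp, z_phase = _draw_block(rng, (alo, ahi, plo, phi), m)
        # forward model: candidate impedance x flow spectrum -> pressure spectrum
        p_amp = z_amp * q.amplitudes / MMHG_TO_DYN_CM2
        p_phase = wrap_phase(z_phase + q.phases)
        if calibration_mode == "brachial":
            cal_amp = p_amp * gain
            cal_phase = wrap_phase(p_phase + shift)
        else:
            cal_amp, cal_phase = p_amp, p_phase
        cal_wave = _reconstruct_batch(cal_amp, cal_phase, n_samples, f1)
        bp_ok = (np.abs(cal_wave.max(axis=1) - target_sbp) <= crit.bp_tolerance) & (
            np.abs(cal_wave.min(axis=1) - target_dbp) <= crit.bp_tolerance
        )
        rejections["bp_match"] += int(m - bp_ok.sum())
        idx = np.flatnonzero(bp_ok)
        if idx.size == 0:
            continue
        central = _reconstruct_batch(p_amp[idx], p_phase[idx], n_samples, f1)
        for row, i in enumerate(idx):
            pw = Waveform(central[row], dt=flow.dt, unit_tag="pressure_mmHg")
            flags = check_physiologic_criteria(pw, flow, ed, crit)
            for name in CRITERION_NAMES:
                if not getattr(flags, name):
                    rejections[name] += 1
            if flags.passed:
                surv_amp.append(z_amp[i])
                surv_phase.append(z_phase[i])
                surv_wave.append(pw)

    n_passing = len(surv_wave)
    if n_passing == 0:
        worst = max(rejections, key=rejections.get)
        logger.warning(
            "no candidate survived (%d tried); most rejections from '%s' (%d)",
            n_candidates,
            worst,
            rejections[worst],
        )
        return SBVIResult(
            n_candidates=n_candidates,
            n_passing=0,
            passing_central_waveforms=[],
            passing_impedance=None,
            median_central_waveform=None,
            median_impedance=None,
            parameters=None,
            flow=flow,
            ejection_duration=ed,
            rejection_counts=rejections,
            seed=seed,
        )

    amp_arr = np.vstack(surv_amp)
    phase_arr = np.vstack(surv_phase)
    med_amp = np.median(amp_arr, axis=0)
    med_phase = np.array([circular_median(phase_arr[:, k]) for k in range(n_harm + 1)])
    med_phase[0] = 0.0
    median_z = ImpedanceSpectrum(med_amp, med_phase, f1)
    med_wave = Waveform(
        np.median(np.vstack([w.values for w in surv_wave]), axis=0),
        dt=flow.dt,
        unit_tag="pressure_mmHg",
    )
    params = _metrics.vascular_parameters(median_z, med_wave, flow, echo.aortic_valve_area)
    return SBVIResult(
        n_candidates=n_candidates,
        n_passing=n_passing,
        passing_central_waveforms=surv_wave,
        passing_impedance=CandidateSet(amp_arr, phase_arr, f1),
        median_central_waveform=med_wave,
        median_impedance=median_z,
        parameters=params,
        flow=flow,
        ejection_duration=ed,
        rejection_counts=rejections,
        seed=seed,
    )
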