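"""File round-tripping: waveform/spectrum CSVs, echo JSON, bounds YAML, reports.

Plain CSV/JSON/YAML only. Device exports must be converted to the two-column
``time_s,value`` CSV dialect before use; proprietary formats are out of
scope. All writer/reader pairs are numeric inverses to high precision.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import ImpedanceBounds, SBVIResult
from .spectral import HarmonicSpectrum, ImpedanceSpectrum
from .transfer import TransferFunction
from .waveforms import EchoInputs, Waveform

__all__ = [
    "FormatError",
    "load_waveform_csv",
    "save_waveform_csv",
    "load_spectrum_csv",
    "save_spectrum_csv",
    "load_echo_json",
    "save_echo_json",
    "load_transfer_function_csv",
    "save_transfer_function_csv",
    "load_bounds_yaml",
    "default_bounds",
    "run_report",
]

ECHO_KEYS = (
    "heart_rate",
    "peak_velocity",
    "acceleration_time",
    "stroke_volume",
    "aortic_valve_area",
    "systolic_bp",
    "diastolic_bp",
)


class FormatError(ValueError):
    """Malformed input file."""


def load_waveform_csv(path, unit_tag: str = "pressure_mmHg") -> Waveform:
    """Read a one-period waveform from a ``time_s,value`` CSV.

    The time grid must be uniform within 1e-6 s jitter and start at 0; dt and
    period are inferred from the grid (period = n * dt, the sample at the
    period belonging to the next beat).
    """
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "value"]:
        raise FormatError(
            f"{path}: expected header 'time_s,value', got {list(df.columns[:2])}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    steps = np.diff(t)
    dt = float(steps[0])
    bad = np.flatnonzero(np.abs(steps - dt) > 1e-6)
    if bad.size:
        i = int(bad[0]) + 1
        raise FormatError(
            f"{path}: non-uniform time grid at row {i} (t={t[i]!r}, expected {t[0] + i * dt!r})"
        )
    return Waveform(values=v, dt=dt, unit_tag=unit_tag)


def save_waveform_csv(w: Waveform, path) -> None:
    pd.DataFrame({"time_s": w.times, "value": w.values}).to_csv(
        path, index=False, float_format="%.12g"
    )


def load_spectrum_csv(path, impedance: bool = False) -> HarmonicSpectrum:
    """Read a spectrum from a ``harmonic,freq_hz,amplitude,phase_rad`` CSV."""
    df = pd.read_csv(path)
    required = ["harmonic", "freq_hz", "amplitude", "phase_rad"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"{path}: expected header {','.join(required)}")
    k = df["harmonic"].to_numpy(dtype=int)
    if not np.array_equal(k, np.arange(len(k))):
        raise FormatError(f"{path}: harmonics must run 0..N without gaps")
    f = df["freq_hz"].to_numpy(dtype=float)
    fundamental = float(f[1]) if len(f) > 1 else 1.0
    cls = ImpedanceSpectrum if impedance else HarmonicSpectrum
    return cls(
        df["amplitude"].to_numpy(dtype=float),
        df["phase_rad"].to_numpy(dtype=float),
        fundamental,
    )


def save_spectrum_csv(spec: HarmonicSpectrum, path) -> None:
    pd.DataFrame(
        {
            "harmonic": np.arange(len(spec.amplitudes)),
            "freq_hz": spec.frequencies_hz,
            "amplitude": spec.amplitudes,
            "phase_rad": spec.phases,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def load_echo_json(path) -> EchoInputs:
    """Read patient echo scalars + cuff pressures from JSON with exact keys."""
    with open(path) as fh:
        data = json.load(fh)
    missing = [k for k in ECHO_KEYS if k not in data]
    if missing:
        raise FormatError(f"{path}: missing keys {missing}")
    return EchoInputs(**{k: float(data[k]) for k in ECHO_KEYS})


def save_echo_json(echo: EchoInputs, path) -> None:
    with open(path, "w") as fh:
        json.dump({k: getattr(echo, k) for k in ECHO_KEYS}, fh, indent=2)
        fh.write("\n")


def load_transfer_function_csv(path) -> TransferFunction:
    """Read a transfer function from a ``freq_hz,gain,phase_rad`` CSV."""
    df = pd.read_csv(path)
    required = ["freq_hz", "gain", "phase_rad"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"{path}: expected header {','.join(required)}")
    return TransferFunction(
        df["freq_hz"].to_numpy(dtype=float),
        df["gain"].to_numpy(dtype=float),
        df["phase_rad"].to_numpy(dtype=float),
    )


def save_transfer_function_csv(tf: TransferFunction, path) -> None:
    pd.DataFrame(
        {"freq_hz": tf.freq_hz, "gain": tf.gain, "phase_rad": tf.phase_rad}
    ).to_csv(path, index=False, float_format="%.12g")


def _bounds_from_mapping(data: dict) -> ImpedanceBounds:
    rows = sorted(data["harmonics"], key=lambda r: r["harmonic"])
    ks = [r["harmonic"] for r in rows]
    if ks != list(range(len(ks))):
        raise FormatError("bounds harmonics must run 0..K without gaps")
    return ImpedanceBounds(
        amplitude_min=[r["amplitude_min"] for r in rows],
        amplitude_max=[r["amplitude_max"] for r in rows],
        phase_min=[r["phase_min"] for r in rows],
        phase_max=[r["phase_max"] for r in rows],
        expansion_fraction=float(data.get("expansion_fraction", 0.20)),
    )


def load_bounds_yaml(path) -> ImpedanceBounds:
    """Read per-harmonic candidate bounds from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return _bounds_from_mapping(data)
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed bounds file ({exc})") from exc


def default_bounds() -> ImpedanceBounds:
    """The packaged literature-informed candidate bounds (harmonics 0-10)."""
    text = resources.files("sbvi.data").joinpath("default_bounds.yaml").read_text()
    return _bounds_from_mapping(yaml.safe_load(text))


def run_report(result: SBVIResult, out_dir) -> dict:
    """Write the standard result bundle for one inverse run.

    Produces ``parameters.json`` (afterload metrics plus run metadata),
    ``median_central_pressure.csv``, ``median_impedance.csv``,
    ``flow_waveform.csv``, and ``run_log.json`` with per-criterion rejection
    counts. For an empty solution set only the log and flow are written and
    the summary flags it. Returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {
        "n_candidates": result.n_candidates,
        "n_passing": result.n_passing,
        "seed": result.seed,
        "ejection_duration_s": result.ejection_duration,
        "rejection_counts": result.rejection_counts,
        "empty_solution_set": result.n_passing == 0,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
        fh.write("\n")
    save_waveform_csv(result.flow, out / "flow_waveform.csv")
    if result.n_passing > 0:
        save_waveform_csv(result.median_central_waveform, out / "median_central_pressure.csv")
        save_spectrum_csv(result.median_impedance, out / "median_impedance.csv")
        with open(out / "parameters.json", "w") as fh:
            json.dump(result.parameters.as_dict(), fh, indent=2)
            fh.write("\n")
    return log
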