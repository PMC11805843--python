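"""Method-comparison statistics between recorded and simulated quantities.

Bland-Altman bias and 95% limits of agreement (LoA), the maximum LoA
expressed as a percentage of the SD of the simulated metric (a scale-free
severity measure when no third method exists), squared Pearson correlation,
point-by-point waveform differences and RMSE after circular alignment, the
linear-to-volumetric impedance unit conversion, and the blood-pressure input
sensitivity rerun.

Differences are oriented recorded minus simulated throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import BoundingCriteria, ImpedanceBounds, SBVIResult, run_sbvi
from .transfer import TransferFunction
from .waveforms import EchoInputs, Waveform

__all__ = [
    "AgreementStats",
    "bland_altman",
    "loa_pct_sd",
    "waveform_agreement",
    "convert_linear_to_volumetric",
    "bp_sensitivity",
    "cohort_table",
]

#: normal-theory multiplier for 95% limits of agreement
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary for one metric compared across two methods."""

    mean_bias: float
    loa_low: float
    loa_high: float
    loa_pct_sd: float | None
    pearson_r2: float | None
    n: int
    recorded_mean: float = float("nan")
    recorded_sd: float = float("nan")
    simulated_mean: float = float("nan")
    simulated_sd: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.mean_bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


def bland_altman(recorded, simulated) -> AgreementStats:
    """Bland-Altman statistics on paired series (recorded minus simulated).

    Bias is the mean difference; the limits of agreement are
    ``bias +- 1.96 SD(d)`` with the sample SD (n-1 denominator);
    ``loa_pct_sd`` scales the larger absolute limit by the SD of the
    simulated series (None when that SD is zero); ``pearson_r2`` is the
    squared Pearson correlation (None when either series is constant).
    """
    r = np.asarray(recorded, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if r.shape != s.shape or r.ndim != 1:
        raise ValueError("recorded and simulated must be equal-length 1-D series")
    n = len(r)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = r - s
    bias = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    lo, hi = bias - LOA_MULTIPLIER * sd_d, bias + LOA_MULTIPLIER * sd_d
    sd_sim = float(np.std(s, ddof=1))
    pct = loa_pct_sd(lo, hi, sd_sim) if sd_sim > 0 else None
    if np.std(r) == 0 or np.std(s) == 0:
        r2 = None
    else:
        r2 = float(stats.pearsonr(r, s).statistic ** 2)
    return AgreementStats(
        mean_bias=bias,
        loa_low=lo,
        loa_high=hi,
        loa_pct_sd=pct,
        pearson_r2=r2,
        n=n,
        recorded_mean=float(np.mean(r)),
        recorded_sd=float(np.std(r, ddof=1)),
        simulated_mean=float(np.mean(s)),
        simulated_sd=sd_sim,
    )


def loa_pct_sd(loa_low: float, loa_high: float, sd_simulated: float) -> float:
    """Larger absolute limit of agreement as a percentage of the simulated SD."""
    if sd_simulated <= 0:
        raise ValueError("sd_simulated must be positive")
    return 100.0 * max(abs(loa_low), abs(loa_high)) / sd_simulated


def _resample(w: Waveform, n: int) -> np.ndarray:
    """Periodic linear resampling onto an n-point grid over the same period."""
    if w.n_samples == n:
        return w.values
    t_old = np.arange(w.n_samples + 1) * w.dt
    vals = np.append(w.values, w.values[0])
    t_new = np.arange(n) * w.period / n
    return np.interp(t_new, t_old, vals)


def waveform_agreement(
    recorded: Waveform, simulated: Waveform
) -> tuple[float, float, int]:
    """Pointwise agreement between two one-period pressure waveforms.

    The simulated waveform is circularly shifted to the lag maximizing the
    Pearson correlation with the recorded one (first maximum wins ties);
    returns the mean pointwise difference (recorded minus aligned simulated,
    mmHg), the RMSE of the same differences, and the lag in samples of the
    common grid. Waveforms with different sampling are resampled onto the
    finer grid first; the periods must match.
    """
    if not np.isclose(recorded.period, simulated.period, rtol=1e-6):
        raise ValueError(
            f"periods differ: {recorded.period:.4f} vs {simulated.period:.4f} s"
        )
    n = max(recorded.n_samples, simulated.n_samples)
    r = _resample(recorded, n)
    s = _resample(simulated, n)
    rc = r - r.mean()
    sc = s - s.mean()
    # circular cross-correlation via FFT; scale-invariant, so the peak of the
    # correlation coincides with the lag maximizing the Pearson correlation
    xcorr = np.fft.irfft(np.fft.rfft(rc) * np.conj(np.fft.rfft(sc)), n=n)
    lag = int(np.argmax(xcorr))
    s_aligned = np.roll(s, lag)
    d = r - s_aligned
    return float(np.mean(d)), float(np.sqrt(np.mean(d**2))), lag


def convert_linear_to_volumetric(z_linear: float, valve_area: float) -> float:
    """Convert linear-velocity impedance (dyn*s/cm^3) to volumetric (dyn*s/cm^5).

    Volumetric flow is linear velocity times the valve cross-section, so the
    impedance scales by 1/area.
    """
    if valve_area <= 0:
        raise ValueError("valve_area must be positive")
    return z_linear / valve_area


def bp_sensitivity(
    echo: EchoInputs,
    bounds: ImpedanceBounds,
    fraction: float = 0.10,
    crit: BoundingCriteria | None = None,
    tf: TransferFunction | None = None,
    n_candidates: int = 100_000,
    seed: int = 0,
    **run_kwargs,
) -> pd.DataFrame:
    """Percent change in each afterload metric under a BP input perturbation.

    Reruns the inverse search with systolic and diastolic pressure both
    scaled by (1 + fraction) and by (1 - fraction), same seed throughout, and
    reports the per-parameter percent change relative to the unperturbed run.
    A perturbation that inverts the pressure ordering, or a run with no
    survivors, yields a row of NaNs flagged in the ``note`` column.
    """
    if not (0.0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")

    def one(scale: float) -> tuple[SBVIResult | None, str]:
        try:
            e = EchoInputs(
                echo.heart_rate,
                echo.peak_velocity,
                echo.acceleration_time,
                echo.stroke_volume,
                echo.aortic_valve_area,
                systolic_bp=echo.systolic_bp * scale,
                diastolic_bp=echo.diastolic_bp * scale,
            )
        except ValueError:
            return None, "skipped: perturbed pressures not ordered"
        res = run_sbvi(
            e, bounds, crit=crit, tf=tf, n_candidates=n_candidates, seed=seed, **run_kwargs
        )
        if res.n_passing == 0:
            return None, "skipped: no surviving candidates"
        return res, ""

    base, note0 = one(1.0)
    if base is None:
        raise ValueError(f"baseline run failed: {note0}")
    ref = base.parameters.as_dict()
    rows = []
    for label, scale in (("+", 1.0 + fraction), ("-", 1.0 - fraction)):
        res, note = one(scale)
        row = {"perturbation": f"{label}{100 * fraction:.0f}%", "note": note}
        for key, ref_val in ref.items():
            if res is None or ref_val == 0:
                row[key] = float("nan")
            else:
                row[key] = 100.0 * (res.parameters.as_dict()[key] - ref_val) / abs(ref_val)
        rows.append(row)
    return pd.DataFrame(rows).set_index("perturbation")


def cohort_table(
    metric_pairs: dict[str, tuple[np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """Cohort-level comparison table, one row per metric.

    ``metric_pairs`` maps a metric name to its (recorded, simulated) series;
    the table reports mean (SD) of each arm, r^2, bias, the 95% limits of
    agreement, and the maximum limit as a percent of the simulated SD.
    """
    rows = []
    for name, (rec, sim) in metric_pairs.items():
        st = bland_altman(rec, sim)
        rows.append(
            {
                "metric": name,
                "n": st.n,
                "recorded_mean": st.recorded_mean,
                "recorded_sd": st.recorded_sd,
                "simulated_mean": st.simulated_mean,
                "simulated_sd": st.simulated_sd,
                "r2": st.pearson_r2,
                "bias": st.mean_bias,
                "loa_low": st.loa_low,
                "loa_high": st.loa_high,
                "loa_pct_sd": st.loa_pct_sd,
            }
        )
    return pd.DataFrame(rows).set_index("metric")
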