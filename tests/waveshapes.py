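"""Shared test constructions: reference waveform shapes and an independent
re-implementation of the physiologic waveform criteria."""

import numpy as np

from sbvi.waveforms import Waveform


def make_pressure(values, period=0.8):
    values = np.asarray(values, dtype=float)
    return Waveform(values=values, dt=period / len(values), unit_tag="pressure_mmHg")


def textbook_pressure(n=512, period=0.8, ed=0.35, dicrotic=2.0):
    """A central-pressure shape satisfying all six physiologic criteria.

    Systolic rise to a peak between peak flow and end-systole, incisura at
    end-systole, small dicrotic wave, then monotone decay back to the start.
    """
    t = np.arange(n) * period / n
    p = np.empty(n)
    t_peak = 0.55 * ed
    sys_mask = t <= ed
    p[sys_mask] = 80 + 40 * np.sin(np.pi * t[sys_mask] / ed) ** 1.5 * np.exp(
        -((t[sys_mask] - t_peak) ** 2) / (2 * (0.6 * ed) ** 2)
    )
    p_ed = p[sys_mask][-1]
    tail = t[~sys_mask] - ed
    decay = (80.0 - p_ed) / (period - ed)
    p[~sys_mask] = p_ed + decay * tail
    # superpose a small bounded dicrotic wave just after end-systole
    bump_center, bump_width = 0.06, 0.025
    p[~sys_mask] += dicrotic * np.exp(-((tail - bump_center) ** 2) / (2 * bump_width**2))
    return make_pressure(p, period)


def simple_flow(n=512, period=0.8, at=0.12, ed=0.35, vmax=300.0):
    t = np.arange(n) * period / n
    v = np.zeros(n)
    rise = (t >= 0) & (t <= at)
    fall = (t > at) & (t <= ed)
    v[rise] = vmax * np.sin(0.5 * np.pi * t[rise] / at)
    v[fall] = vmax * np.cos(0.5 * np.pi * (t[fall] - at) / (ed - at))
    return Waveform(values=v, dt=period / n, unit_tag="velocity_cm_s")


def criteria_oracle(p, flow, ed, crit):
    """Straight-line, loop-based re-implementation of the six criteria."""
    x = list(p.values)
    n = len(x)
    dt = p.dt
    i_es = min(int(round(ed / dt)), n - 1)
    i_peak = x.index(max(x))

    # local extrema: strict against both neighbours, plateau -> first sample
    maxima, minima = [], []
    i = 1
    while i < n - 1:
        j = i
        while j < n - 1 and x[j + 1] == x[j]:
            j += 1
        if j >= n - 1:
            break
        if x[i - 1] < x[i] and x[j + 1] < x[j]:
            maxima.append(i)
        elif x[i - 1] > x[i] and x[j + 1] > x[j]:
            minima.append(i)
        i = j + 1

    # 1: at most one contiguous rising run after end-systole, bounded rise
    runs, total, in_run = 0, 0.0, False
    for i in range(i_es, n - 1):
        if x[i + 1] > x[i]:
            if not in_run:
                runs += 1
                in_run = True
            total += x[i + 1] - x[i]
        else:
            in_run = False
    c1 = runs == 0 or (runs == 1 and total <= crit.dicrotic_gap)

    c2 = i_peak <= i_es
    c3 = (x[0] - min(x)) < crit.start_min_gap

    max_after = [m for m in maxima if m > i_peak]
    min_after = [m for m in minima if m > i_peak]
    if not max_after:
        c4 = True
    elif not min_after:
        c4 = False
    else:
        c4 = (x[max_after[0]] - x[min_after[0]]) <= crit.dicrotic_gap

    c5 = bool(maxima) and x[maxima[0]] == max(x)
    fv = list(flow.values)
    c6 = i_peak > fv.index(max(fv))
    return (c1, c2, c3, c4, c5, c6)
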