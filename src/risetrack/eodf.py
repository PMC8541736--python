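"""Baseline EODf, Q10 temperature correction, sex assignment.

EODf is temperature sensitive: a fish's fundamental frequency scales as
f(T2) = f(T1) * Q10 ** ((T2 - T1) / 10).  Water temperature drifts by
about a degree over a 6 h trial, so traces are normalized to 25 C
(EODf_25) before individuals are compared.  Baselines are robust to the
upward rise excursions because they are the 5th percentile of
non-overlapping 5 min trace snippets.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from .core import (
    MALE_EODF_CUTOFF_HZ,
    BaselineSeries,
    EodfTrace,
    TemperatureLog,
)

logger = logging.getLogger(__name__)

DEFAULT_Q10 = 1.37


def baseline_series(trace: EodfTrace, window_s: float = 300.0,
                    min_valid_frac: float = 0.1) -> BaselineSeries:
    """5th percentile of non-overlapping window_s-long trace snippets.

    One value per complete window; windows where fewer than
    ``min_valid_frac`` of samples are valid are NaN.  Missing samples are
    excluded, not imputed.  Percentiles interpolate linearly between order
    statistics.
    """
    if trace.times.size == 0:
        raise ValueError("empty trace")
    t0 = trace.times[0]
    n_win = int(np.floor((trace.times[-1] - t0 + trace.dt) / window_s))
    starts = t0 + window_s * np.arange(n_win)
    values = np.full(n_win, np.nan)
    expected = window_s / trace.dt
    idx = np.searchsorted(trace.times, np.append(starts, starts[-1] + window_s)
                          if n_win else starts)
    for w in range(n_win):
        seg = trace.freq[idx[w]:idx[w + 1]]
        seg = seg[np.isfinite(seg)]
        if seg.size >= min_valid_frac * expected:
            values[w] = np.percentile(seg, 5.0)
    return BaselineSeries(starts, values, window_s)


def mask_rise_windows(
    baselines: BaselineSeries,
    rise_peak_times: np.ndarray,
    guard_s: float = 300.0,
) -> BaselineSeries:
    """Blank baseline windows affected by rises (for Q10 estimation).

    A window is dropped when a rise peaks inside it or within ``guard_s``
    before it: the exponential decay back to baseline can outlast a window,
    and residual tails would otherwise masquerade as temperature-driven
    frequency changes.
    """
    t = np.asarray(rise_peak_times, dtype=float)
    vals = baselines.baseline_hz.copy()
    for i, start in enumerate(baselines.window_start):
        if np.any((t >= start - guard_s) & (t < start + baselines.window_s)):
            vals[i] = np.nan
    return BaselineSeries(baselines.window_start.copy(), vals, baselines.window_s)


def estimate_q10(
    baselines: BaselineSeries,
    temperature: TemperatureLog,
    dt_min_c: float = 0.05,
    pairs: str = "all",
) -> tuple[np.ndarray, float]:
    """Per-pair Q10 values from baseline windows and their median.

    For window pairs (f1, T1), (f2, T2) with |T2 - T1| >= ``dt_min_c``:
    Q10 = (f2 / f1) ** (10 / (T2 - T1)).  Window temperatures are the
    interpolated log at window centers.  ``pairs`` selects "all" window
    pairs or only "consecutive" ones; the temperature threshold guards the
    10/dT exponent against blow-up.
    """
    valid = np.isfinite(baselines.baseline_hz)
    f = baselines.baseline_hz[valid]
    temps = temperature.at(baselines.window_centers()[valid])
    if f.size < 2 or np.unique(temps).size < 2:
        raise ValueError("need >= 2 baseline windows with distinct temperatures")
    if pairs == "consecutive":
        idx_pairs = zip(range(f.size - 1), range(1, f.size))
    elif pairs == "all":
        idx_pairs = itertools.combinations(range(f.size), 2)
    else:
        raise ValueError("pairs must be 'all' or 'consecutive'")
    q10s = []
    for i, j in idx_pairs:
        dT = temps[j] - temps[i]
        if abs(dT) < dt_min_c:
            continue
        q10s.append((f[j] / f[i]) ** (10.0 / dT))
    if not q10s:
        raise ValueError(
            f"temperature variation insufficient: no window pair differs by "
            f">= {dt_min_c} C"
        )
    q10s = np.asarray(q10s)
    return q10s, float(np.median(q10s))


def correct_to_25(
    trace: EodfTrace, temperature: TemperatureLog, q10: float = DEFAULT_Q10
) -> EodfTrace:
    """Temperature-correct a trace to 25 C:
    f25(t) = f(t) * q10 ** ((25 - T(t)) / 10), T linearly interpolated."""
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    temp = temperature.at(trace.times)
    f25 = trace.freq * q10 ** ((25.0 - temp) / 10.0)
    return EodfTrace(trace.fish_id, trace.times.copy(), f25,
                     trace.power_profile)


def assign_sex(median_eodf25_hz: float) -> str:
    """Sex from EODf_25: strictly above 740 Hz is male, else female."""
    if not np.isfinite(median_eodf25_hz):
        raise ValueError("median EODf_25 must be finite")
    return "male" if median_eodf25_hz > MALE_EODF_CUTOFF_HZ else "female"


def eodf_difference(
    trace_a: EodfTrace,
    trace_b: EodfTrace,
    light_interval: tuple[float, float],
    window_s: float = 300.0,
) -> float:
    """Median light-phase baseline EODf of a minus that of b.

    Computed on the baseline series restricted to windows starting in the
    light phase, where EODfs are stable (no agonistic activity).
    """
    lo, hi = light_interval
    meds = []
    for tr in (trace_a, trace_b):
        bs = baseline_series(tr, window_s)
        in_light = (bs.window_start >= lo) & (bs.window_start + window_s <= hi)
        vals = bs.baseline_hz[in_light]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(
                f"trace {tr.fish_id!r} has no baseline coverage in the light "
                f"phase [{lo}, {hi}) s"
            )
        meds.append(float(np.median(vals)))
    return meds[0] - meds[1]
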