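"""Rise detection on EODf traces and emission summaries.

A rise is an abrupt EODf increase followed by an exponential decay back to
baseline.  Detection works on the frequency series with an alternating
peak/trough detector using a fixed dynamic threshold: a peak qualifies iff
it exceeds the preceding trough by at least the threshold (default 5 Hz),
and it is committed once the series has fallen that far below the running
maximum again.  The rise onset is placed at the preceding trough.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import RISE_THRESHOLD_HZ, BaselineSeries, EodfTrace, Rise

logger = logging.getLogger(__name__)


def detect_peaks_troughs(
    data: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating peak/trough indices with a fixed detection threshold.

    A peak is committed when the series falls >= threshold below the
    running maximum, a trough when it climbs >= threshold above the running
    minimum; committed extrema therefore alternate and each peak exceeds
    the preceding trough by at least the threshold.
    """
    peaks: list[int] = []
    troughs: list[int] = []
    direction = 0
    min_i = max_i = 0
    min_v = max_v = data[0]
    for i in range(data.size):
        v = data[i]
        if direction > 0:  # searching for a maximum
            if v > max_v:
                max_v = v
                max_i = i
            elif max_v - v >= threshold:
                peaks.append(max_i)
                direction = -1
                min_v = v
                min_i = i
        elif direction < 0:  # searching for a minimum
            if v < min_v:
                min_v = v
                min_i = i
            elif v - min_v >= threshold:
                troughs.append(min_i)
                direction = 1
                max_v = v
                max_i = i
        else:  # undecided start
            if max_v - v >= threshold:
                peaks.append(max_i)
                direction = -1
                min_v = v
                min_i = i
            elif v - min_v >= threshold:
                troughs.append(min_i)
                direction = 1
                max_v = v
                max_i = i
            else:
                if v > max_v:
                    max_v = v
                    max_i = i
                if v < min_v:
                    min_v = v
                    min_i = i
    return np.asarray(peaks, dtype=int), np.asarray(troughs, dtype=int)


def _segments(trace: EodfTrace, gap_split_s: float) -> list[np.ndarray]:
    """Index arrays of valid samples, split where gaps exceed gap_split_s."""
    valid = np.flatnonzero(trace.valid)
    if valid.size == 0:
        return []
    gaps = np.flatnonzero(np.diff(trace.times[valid]) > gap_split_s)
    return np.split(valid, gaps + 1)


def detect_rises(
    trace: EodfTrace,
    threshold_hz: float = RISE_THRESHOLD_HZ,
    baselines: BaselineSeries | None = None,
    gap_split_s: float = 5.0,
) -> list[Rise]:
    """Detect rises on one EODf trace, time-ordered.

    Each committed peak with a preceding trough (or the segment start where
    none precedes it) becomes one Rise.  When a baseline series is given,
    rise size is peak frequency minus the baseline of the window containing
    the onset; otherwise it falls back to peak minus trough frequency.
    Gaps longer than ``gap_split_s`` split the trace into independently
    processed segments; traces with more than half the samples missing are
    flagged with a warning but still processed.
    """
    if threshold_hz <= 0:
        raise ValueError("threshold must be positive")
    missing_frac = 1.0 - trace.valid.mean() if trace.times.size else 0.0
    if missing_frac > 0.5:
        logger.warning(
            "trace %s has %.0f%% missing samples; detecting on valid segments",
            trace.fish_id, 100 * missing_frac,
        )
    rises: list[Rise] = []
    for seg in _segments(trace, gap_split_s):
        f = trace.freq[seg]
        t = trace.times[seg]
        if f.size < 2:
            continue
        peaks, troughs = detect_peaks_troughs(f, threshold_hz)
        for p in peaks:
            prior = troughs[troughs < p]
            tr_i = int(prior[-1]) if prior.size else 0
            if f[p] - f[tr_i] < threshold_hz:
                continue
            peak_time = float(t[p])
            onset_time = float(t[tr_i])
            if baselines is not None:
                try:
                    base = baselines.at_time(onset_time)
                except ValueError:
                    base = np.nan
                size = float(f[p] - base) if np.isfinite(base) else float(f[p] - f[tr_i])
            else:
                size = float(f[p] - f[tr_i])
            rises.append(Rise(trace.fish_id, onset_time, peak_time, float(f[p]), size))
    rises.sort(key=lambda r: r.peak_time)
    return rises


def rise_size(
    trace: EodfTrace,
    peak_time: float,
    baselines: BaselineSeries,
    onset_time: float | None = None,
) -> float:
    """Peak frequency minus the baseline of the window holding the onset.

    Raises if the onset (default: the peak time itself) lies outside
    baseline coverage.
    """
    i = int(np.argmin(np.abs(trace.times - peak_time)))
    base = baselines.at_time(peak_time if onset_time is None else onset_time)
    if not np.isfinite(base):
        raise ValueError("baseline missing for the window containing the rise")
    return float(trace.freq[i] - base)


def counts_by_phase(
    rise_times: np.ndarray,
    dark_interval: tuple[float, float],
    light_interval: tuple[float, float],
) -> tuple[int, int]:
    """(dark count, light count) of rises for one fish.

    Intervals are half-open [start, end) and must not overlap.
    """
    d0, d1 = dark_interval
    l0, l1 = light_interval
    if max(d0, l0) < min(d1, l1):
        raise ValueError("dark and light intervals must be disjoint")
    t = np.asarray(rise_times, dtype=float)
    return int(np.sum((t >= d0) & (t < d1))), int(np.sum((t >= l0) & (t < l1)))


def count_statistics(counts) -> dict:
    """Mean, SD (ddof=1) and coefficient of variation of per-trial counts."""
    c = np.asarray(counts, dtype=float)
    mean = float(c.mean())
    sd = float(c.std(ddof=1)) if c.size > 1 else 0.0
    return {"mean": mean, "sd": sd, "cv": sd / mean if mean else np.nan}


def rise_rate_timecourse(
    trials: list[dict],
    dark_s: float = 10800.0,
    bin_s: float = 900.0,
) -> dict:
    """Normalized loser rise-rate curves and per-bin loser fractions.

    ``trials`` is a list of dicts with keys "loser" and "winner" holding
    rise-time arrays.  For each trial the binned loser rate is divided by
    its trial-mean rate; trials without loser rises are excluded (logged).
    The per-bin loser fraction is loser / (loser + winner) rises, NaN where
    a bin holds no rises at all.
    """
    n_bins = dark_s / bin_s
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_s must divide the dark phase length")
    n_bins = int(round(n_bins))
    edges = np.linspace(0.0, dark_s, n_bins + 1)

    norm_curves = []
    fractions = []
    excluded = 0
    for trial in trials:
        lt = np.asarray(trial["loser"], dtype=float)
        wt = np.asarray(trial["winner"], dtype=float)
        lt = lt[(lt >= 0) & (lt < dark_s)]
        wt = wt[(wt >= 0) & (wt < dark_s)]
        lc, _ = np.histogram(lt, edges)
        wc, _ = np.histogram(wt, edges)
        if lc.sum() == 0:
            excluded += 1
            continue
        norm_curves.append(lc / lc.mean())
        tot = lc + wc
        with np.errstate(invalid="ignore"):
            fractions.append(np.where(tot > 0, lc / np.maximum(tot, 1), np.nan))
    if excluded:
        logger.info("excluded %d trials without loser rises", excluded)
    norm_curves = np.asarray(norm_curves, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        return _timecourse_dict(edges, norm_curves, fractions, excluded, n_bins)


def _timecourse_dict(edges, norm_curves, fractions, excluded, n_bins):
    return {
        "bin_centers": 0.5 * (edges[:-1] + edges[1:]),
        "normalized_curves": norm_curves,
        "mean_curve": norm_curves.mean(axis=0) if norm_curves.size else np.full(n_bins, np.nan),
        "loser_fractions": fractions,
        "mean_loser_fraction": (
            np.nanmean(fractions, axis=0) if fractions.size else np.full(n_bins, np.nan)
        ),
        "n_excluded": excluded,
    }


def rises_table(rises: list[Rise]) -> pd.DataFrame:
    """Rise list as a table (fish_id, onset_s, peak_s, peak_hz, size_hz)."""
    return pd.DataFrame(
        [
            dict(fish_id=r.fish_id, onset_s=r.onset_time, peak_s=r.peak_time,
                 peak_hz=r.peak_freq, size_hz=r.size_hz)
            for r in rises
        ],
        columns=["fish_id", "onset_s", "peak_s", "peak_hz", "size_hz"],
    )
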