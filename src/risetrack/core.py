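"""Core domain types shared across the pipeline.

The experiment these types describe: two wave-type electric fish
(*Apteronotus leptorhynchus*) compete for a superior shelter in a tank for
6 h — a 3 h dark phase (the fish's active period) followed by a 3 h light
phase.  Each fish continuously emits a quasi-sinusoidal electric organ
discharge (EOD) with an individually distinct fundamental frequency (EODf,
~600–1000 Hz).  "Rises" — abrupt EODf increases of >= ~5 Hz followed by a
roughly exponential decay back to baseline — are electrocommunication
signals.  Agonistic behaviors are scored from video as point events
(physical contacts) and interval events (chases).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Default phase boundaries, seconds from trial start. The dark (active)
#: phase is the half-open interval [0, DARK_S); light is [DARK_S, TRIAL_S).
DARK_S = 10800.0
TRIAL_S = 21600.0

#: EODf_25 above this threshold (strictly) is taken to come from a male.
MALE_EODF_CUTOFF_HZ = 740.0

#: Minimum peak-minus-preceding-trough excursion for a rise, Hz.
RISE_THRESHOLD_HZ = 5.0


@dataclass
class EodfTrace:
    """Time-stamped fundamental-frequency series for one fish.

    Missing (untracked) windows are encoded as NaN in ``freq``.
    ``power_profile`` optionally carries, per window, the per-channel signal
    power used by the tracker to separate fish with similar frequencies.
    """

    fish_id: str
    times: np.ndarray
    freq: np.ndarray
    power_profile: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freq = np.asarray(self.freq, dtype=float)
        if self.times.shape != self.freq.shape:
            raise ValueError("times and freq must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        valid = np.isfinite(self.freq)
        if np.any(self.freq[valid] <= 0):
            raise ValueError("EODf values must be positive where present")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.freq)

    @property
    def dt(self) -> float:
        """Median sampling step, seconds."""
        return float(np.median(np.diff(self.times)))


@dataclass
class TemperatureLog:
    """Water temperature readings, nominally one per 5 min."""

    times: np.ndarray
    temp: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        if self.times.shape != self.temp.shape:
            raise ValueError("times and temp must have equal length")
        if np.any((self.temp <= 15) | (self.temp >= 35)):
            raise ValueError("temperatures outside plausible range (15, 35) C")

    def at(self, t: np.ndarray) -> np.ndarray:
        """Linearly interpolated temperature at times ``t``."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.temp)


@dataclass
class BaselineSeries:
    """Per-window baseline EODf: 5th percentile of non-overlapping snippets.

    ``window_start`` marks the left edge of each contiguous window;
    windows with too few valid samples hold NaN.
    """

    window_start: np.ndarray
    baseline_hz: np.ndarray
    window_s: float = 300.0

    def __post_init__(self) -> None:
        self.window_start = np.asarray(self.window_start, dtype=float)
        self.baseline_hz = np.asarray(self.baseline_hz, dtype=float)
        if self.window_start.shape != self.baseline_hz.shape:
            raise ValueError("window_start and baseline_hz must match")

    def window_centers(self) -> np.ndarray:
        return self.window_start + 0.5 * self.window_s

    def at_time(self, t: float) -> float:
        """Baseline of the window containing time ``t`` (NaN if missing)."""
        i = int(np.searchsorted(self.window_start, t, side="right")) - 1
        if i < 0 or i >= self.window_start.size:
            raise ValueError(f"time {t} s outside baseline coverage")
        if t >= self.window_start[i] + self.window_s:
            raise ValueError(f"time {t} s outside baseline coverage")
        return float(self.baseline_hz[i])


@dataclass
class Rise:
    """One detected rise: onset at the preceding trough, peak, and size.

    ``size_hz`` is the peak frequency minus the baseline EODf (or, when no
    baseline series is supplied to the detector, minus the trough frequency).
    """

    fish_id: str
    onset_time: float
    peak_time: float
    peak_freq: float
    size_hz: float

    def __post_init__(self) -> None:
        if self.onset_time > self.peak_time:
            raise ValueError("rise onset must not follow its peak")


@dataclass
class AgonisticEvent:
    """A contact (point event) or chase (interval event).

    In the experiment all agonistic events are initiated by the eventual
    winner; ``initiator`` records that label.  ``triggered_by`` is only set
    by the synthetic generator and indexes the ground-truth rise that evoked
    the event (-1 for background events).
    """

    kind: str  # "contact" | "chase"
    onset_s: float
    end_s: Optional[float] = None
    initiator: str = "winner"
    triggered_by: int = -1

    def __post_init__(self) -> None:
        if self.kind not in ("contact", "chase"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "chase":
            if self.end_s is None or self.end_s < self.onset_s:
                raise ValueError("chase needs end_s >= onset_s")

    @property
    def duration_s(self) -> float:
        return 0.0 if self.end_s is None else self.end_s - self.onset_s


def events_to_frame(events: list[AgonisticEvent]) -> pd.DataFrame:
    rows = [dataclasses.asdict(e) for e in events]
    cols = ["kind", "onset_s", "end_s", "initiator", "triggered_by"]
    return pd.DataFrame(rows, columns=cols)


def rises_to_frame(rises: list[Rise]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in rises]
    cols = ["fish_id", "onset_time", "peak_time", "peak_freq", "size_hz"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class RateCurve:
    """Event-triggered rise rate over lags, with optional uncertainty bands.

    Lags are rise time minus event onset: negative lags mean the rise
    preceded the event.  Rates are rises per second per event (averaged over
    trials when aggregated).
    """

    lags: np.ndarray
    rate: np.ndarray
    jackknife_lo: Optional[np.ndarray] = None
    jackknife_hi: Optional[np.ndarray] = None
    null_lo: Optional[np.ndarray] = None
    null_hi: Optional[np.ndarray] = None
    null_mean: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if np.any(self.rate < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class FishRecord:
    """Per-fish metadata within a trial."""

    fish_id: str
    size_cm: float
    weight_g: float = float("nan")
    sex: str = "female"
    eodf25_hz: float = float("nan")
    dark_rises: int = 0
    experience: int = 0


@dataclass
class TrialRecord:
    """Pair metadata for one competition trial.

    Difference conventions follow the loser-minus-winner orientation:
    dsize = size_loser - size_winner, deodf = EODf_loser - EODf_winner.
    """

    trial_id: str
    fish: tuple[FishRecord, FishRecord]
    winner: str

    def __post_init__(self) -> None:
        ids = {f.fish_id for f in self.fish}
        if len(self.fish) != 2 or len(ids) != 2:
            raise ValueError("a trial needs exactly two distinct fish")
        if self.winner not in ids:
            raise ValueError("winner must be one of the two fish")

    @property
    def winner_record(self) -> FishRecord:
        return next(f for f in self.fish if f.fish_id == self.winner)

    @property
    def loser_record(self) -> FishRecord:
        return next(f for f in self.fish if f.fish_id != self.winner)

    @property
    def dsize(self) -> float:
        return self.loser_record.size_cm - self.winner_record.size_cm

    @property
    def deodf(self) -> float:
        return self.loser_record.eodf25_hz - self.winner_record.eodf25_hz
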