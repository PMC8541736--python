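"""Ground-truthed synthetic competition trials.

Emulates the statistical structure the analysis assumes: two EODf traces
separated in frequency, a slow temperature-driven baseline drift governed by
a Q10 law, rises (abrupt jump + exponential decay, sizes 5-68 Hz, decay
times of roughly a second up to a minute), loser-biased rise emission,
agonistic events partially triggered a fixed lag after rises (0.7 s for
contacts, 1.6 s for chases), chase durations from a truncated normal
(7.4 +/- 6.5 s), and cohorts of trials whose winners follow a logistic
model of between-fish differences.

All randomness flows from a single integer seed; identical configuration
and seed give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .core import (
    DARK_S,
    TRIAL_S,
    AgonisticEvent,
    EodfTrace,
    FishRecord,
    TemperatureLog,
    TrialRecord,
)

logger = logging.getLogger(__name__)


@dataclass
class TrialConfig:
    """Parameters of one synthetic two-fish trial.

    Defaults mirror the study conditions: 6 h trials with a 3 h dark phase,
    EODf traces sampled at the spectrogram hop (~0.33 s), ~1 degree C of
    cooling over the trial, Q10 = 1.37, loser/winner dark-phase rise counts
    of 184 and 18, rise sizes between the 5 Hz detection threshold and
    68 Hz, ~128 background chases and ~36 contacts per dark phase, and
    chase durations of 7.4 +/- 6.5 s (truncated at zero).
    """

    duration_s: float = TRIAL_S
    dark_s: float = DARK_S
    sample_dt_s: float = 0.33
    baseline_hz: tuple[float, float] = (680.0, 720.0)  # (loser, winner) at 25 C
    temp_start_c: float = 26.0
    temp_drop_c: float = 1.0
    q10: float = 1.37
    n_rises: tuple[int, int] = (184, 18)  # (loser, winner), dark phase
    rise_size_range_hz: tuple[float, float] = (5.0, 68.0)
    rise_decay_range_s: tuple[float, float] = (1.0, 60.0)
    min_rise_gap_s: float = 30.0
    trigger_prob: float = 0.3
    trigger_kind: str = "contact"
    contact_lag_s: float = 0.7
    chase_lag_s: float = 1.6
    background_contact_rate: float = 36.0 / DARK_S
    background_chase_rate: float = 128.0 / DARK_S
    chase_dur_mean_s: float = 7.4
    chase_dur_sd_s: float = 6.5
    noise_sd_hz: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_dt_s <= 0:
            raise ValueError("sample_dt_s must be positive")
        if self.dark_s > self.duration_s:
            raise ValueError("dark_s must not exceed duration_s")
        if self.rise_size_range_hz[0] < 5.0:
            raise ValueError(
                "rise sizes below 5 Hz would fall under the detection "
                "threshold and be undetectable by design"
            )
        if not 0.0 <= self.trigger_prob <= 1.0:
            raise ValueError("trigger_prob must lie in [0, 1]")
        if self.background_contact_rate < 0 or self.background_chase_rate < 0:
            raise ValueError("background rates must be >= 0")
        if self.trigger_kind not in ("contact", "chase"):
            raise ValueError("trigger_kind must be 'contact' or 'chase'")
        if self.baseline_hz[0] == self.baseline_hz[1]:
            raise ValueError("the two baselines must differ")


@dataclass
class SyntheticTrial:
    """One generated trial with full ground truth."""

    config: TrialConfig
    traces: tuple[EodfTrace, EodfTrace]
    true_rises: pd.DataFrame
    events: list[AgonisticEvent]
    temperature: TemperatureLog
    meta: TrialRecord
    n_merged_chases: int = 0


def temperature_profile(config: TrialConfig, t: np.ndarray) -> np.ndarray:
    """Linear cooling from temp_start_c by temp_drop_c over the trial."""
    return config.temp_start_c - config.temp_drop_c * np.asarray(t) / config.duration_s


def baseline_at_temperature(f25: float, temp_c: np.ndarray, q10: float) -> np.ndarray:
    """EODf at temperature T for a fish with EODf f25 at 25 C:
    f(T) = f25 * q10 ** ((T - 25) / 10)."""
    return f25 * q10 ** ((np.asarray(temp_c) - 25.0) / 10.0)


def _spaced_times(
    rng: np.random.Generator, n: int, lo: float, hi: float, min_gap: float
) -> np.ndarray:
    """n sorted times uniform on [lo, hi) subject to a minimum spacing.

    Uses the standard order-statistics construction: uniform draws on the
    gap-deflated interval plus a deterministic spacing ramp.
    """
    if n == 0:
        return np.empty(0)
    slack = (hi - lo) - (n - 1) * min_gap
    if slack <= 0:
        raise ValueError(
            f"cannot place {n} rises with {min_gap} s spacing in "
            f"[{lo}, {hi}) s"
        )
    u = np.sort(rng.uniform(0.0, slack, n))
    return lo + u + np.arange(n) * min_gap


def generate_temperature_log(config: TrialConfig) -> TemperatureLog:
    """One reading per 5 min, following the linear cooling profile."""
    times = np.arange(0.0, config.duration_s + 1e-9, 300.0)
    return TemperatureLog(times, temperature_profile(config, times))


def generate_eodf_traces(
    config: TrialConfig,
) -> tuple[tuple[EodfTrace, EodfTrace], pd.DataFrame]:
    """Generate the two EODf traces and the ground-truth rise table.

    Each trace is baseline(T(t)) + sum of rises + Gaussian observation
    noise, where a rise jumps instantaneously by its size at onset and
    decays exponentially back with a per-rise time constant.  Rise onsets
    are placed in the dark phase (fish are active then) with a minimum
    spacing so that individual rises remain resolvable.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration_s, config.sample_dt_s)
    temp = temperature_profile(config, t)

    fish_ids = ("loser", "winner")
    traces: list[EodfTrace] = []
    truth_rows: list[dict] = []
    # keep triggered events (onset + lag) inside the dark phase
    margin = max(config.contact_lag_s, config.chase_lag_s) + 60.0
    for i, fish_id in enumerate(fish_ids):
        freq = baseline_at_temperature(config.baseline_hz[i], temp, config.q10)
        n = config.n_rises[i]
        onsets = _spaced_times(rng, n, 0.0, config.dark_s - margin, config.min_rise_gap_s)
        sizes = rng.uniform(*config.rise_size_range_hz, n)
        taus = rng.uniform(*config.rise_decay_range_s, n)
        for onset, size, tau in zip(onsets, sizes, taus):
            j0 = int(np.searchsorted(t, onset))
            seg = t[j0:] - onset
            freq[j0:] += size * np.exp(-seg / tau)
            truth_rows.append(
                dict(fish_id=fish_id, onset_s=onset, peak_s=onset,
                     size_hz=size, decay_s=tau)
            )
        if config.noise_sd_hz > 0:
            freq = freq + rng.normal(0.0, config.noise_sd_hz, t.size)
        traces.append(EodfTrace(fish_id, t, freq))

    truth = pd.DataFrame(
        truth_rows, columns=["fish_id", "onset_s", "peak_s", "size_hz", "decay_s"]
    )
    return (traces[0], traces[1]), truth


def _truncated_normal_durations(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def merge_chase_intervals(
    intervals: list[tuple[float, float]]
) -> tuple[list[tuple[float, float]], int]:
    """Union-merge overlapping chase intervals; returns (merged, n_merged)."""
    if not intervals:
        return [], 0
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    n_merged = 0
    for on, off in ordered[1:]:
        if on <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], off)
            n_merged += 1
        else:
            merged.append([on, off])
    return [(a, b) for a, b in merged], n_merged


def generate_agonistic_events(
    true_rises: pd.DataFrame,
    config: TrialConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[AgonisticEvent], int]:
    """Agonistic events: rise-triggered plus dark-phase Poisson background.

    For each loser rise, with probability ``trigger_prob`` one event of
    ``trigger_kind`` occurs at the configured lag after the rise onset.
    Background contacts and chases are homogeneous Poisson during the dark
    phase only (agonistic behavior ceases with the lights).  Overlapping
    chase intervals are union-merged; the merge count is logged and
    returned.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rise_times = np.sort(
        true_rises.loc[true_rises["fish_id"] == "loser", "onset_s"].to_numpy()
    )

    events: list[AgonisticEvent] = []
    chase_spans: list[tuple[float, float, int]] = []

    lag = (
        config.contact_lag_s
        if config.trigger_kind == "contact"
        else config.chase_lag_s
    )
    triggered = rng.random(rise_times.size) < config.trigger_prob
    for idx in np.flatnonzero(triggered):
        onset = rise_times[idx] + lag
        if onset >= config.dark_s:
            continue
        if config.trigger_kind == "contact":
            events.append(AgonisticEvent("contact", onset, triggered_by=int(idx)))
        else:
            dur = float(
                _truncated_normal_durations(
                    rng, 1, config.chase_dur_mean_s, config.chase_dur_sd_s
                )[0]
            )
            chase_spans.append((onset, min(onset + dur, config.dark_s), int(idx)))

    for kind, rate in (
        ("contact", config.background_contact_rate),
        ("chase", config.background_chase_rate),
    ):
        n_bg = rng.poisson(rate * config.dark_s)
        onsets = np.sort(rng.uniform(0.0, config.dark_s, n_bg))
        if kind == "contact":
            events.extend(AgonisticEvent("contact", float(o)) for o in onsets)
        else:
            durs = _truncated_normal_durations(
                rng, n_bg, config.chase_dur_mean_s, config.chase_dur_sd_s
            )
            chase_spans.extend(
                (float(o), float(min(o + d, config.dark_s)), -1)
                for o, d in zip(onsets, durs)
            )

    merged, n_merged = merge_chase_intervals([(a, b) for a, b, _ in chase_spans])
    if n_merged:
        logger.info("merged %d overlapping chase intervals", n_merged)
    # re-attach the triggering rise where the merged interval starts at a
    # triggered onset (merging can only ever absorb later-starting chases)
    trigger_lookup = {round(a, 9): tb for a, _, tb in chase_spans if tb >= 0}
    for on, off in merged:
        events.append(
            AgonisticEvent("chase", on, off, triggered_by=trigger_lookup.get(round(on, 9), -1))
        )

    events.sort(key=lambda e: e.onset_s)
    return events, n_merged


@dataclass
class ElectrodeGrid:
    """Rectangular grid of monopolar electrodes on the tank bottom (meters)."""

    positions: np.ndarray  # (n_electrodes, 2)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] < 2:
            raise ValueError("tracking needs spatial profiles: >= 2 electrodes")

    @classmethod
    def regular(cls, nx: int = 5, ny: int = 3, width: float = 0.8, height: float = 0.4):
        """Default 5 x 3 = 15 electrode layout."""
        xs = np.linspace(0.0, width, nx)
        ys = np.linspace(0.0, height, ny)
        gx, gy = np.meshgrid(xs, ys)
        return cls(np.column_stack([gx.ravel(), gy.ravel()]))

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class Recording:
    """Multichannel audio-rate recording: samples x channels."""

    data: np.ndarray
    rate_hz: float
    grid: ElectrodeGrid


def generate_raw_recording(
    traces: tuple[EodfTrace, ...],
    grid: ElectrodeGrid,
    *,
    rate_hz: float = 20000.0,
    n_harmonics: int = 3,
    harmonic_decay: float = 0.4,
    fish_positions: np.ndarray | None = None,
    movement: bool = False,
    movement_step: float = 0.003,
    spread: float = 0.3,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> Recording:
    """Synthesize a multichannel voltage recording from EODf traces.

    Each fish contributes a harmonic series (fundamental + ``n_harmonics-1``
    overtones with geometrically decaying amplitudes) whose instantaneous
    frequency follows its EODf trace.  Per-channel amplitudes fall off with
    distance between the fish and the electrode as 1/(1+(d/spread)^2).
    Fish are stationary by default; ``movement=True`` adds a smooth random
    walk clipped to the tank.  Channels sum contributions plus Gaussian
    noise.
    """
    rng = np.random.default_rng(seed)
    t0 = max(tr.times[0] for tr in traces)
    t1 = min(tr.times[-1] for tr in traces)
    if t1 <= t0:
        raise ValueError("traces do not cover a common time span")
    n_samples = int(np.floor((t1 - t0) * rate_hz))
    t = t0 + np.arange(n_samples) / rate_hz

    lo = grid.positions.min(axis=0)
    hi = grid.positions.max(axis=0)
    if fish_positions is None:
        # spread fish towards opposite corners of the electrode array
        fracs = np.linspace(0.25, 0.75, len(traces))
        fish_positions = np.array([lo + f * (hi - lo) for f in fracs])
    fish_positions = np.asarray(fish_positions, dtype=float)

    data = np.zeros((n_samples, grid.n), dtype=np.float32)
    amps = harmonic_decay ** np.arange(n_harmonics)
    for trace, pos in zip(traces, fish_positions):
        filled = np.array(trace.freq)
        bad = ~np.isfinite(filled)
        if bad.any():
            filled[bad] = np.interp(
                trace.times[bad], trace.times[~bad], filled[~bad]
            )
        finst = np.interp(t, trace.times, filled)
        phase = 2.0 * np.pi * np.cumsum(finst) / rate_hz
        sig = np.zeros(n_samples)
        for h in range(1, n_harmonics + 1):
            sig += amps[h - 1] * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
        if movement:
            steps = rng.normal(0.0, movement_step, (n_samples // int(rate_hz) + 2, 2))
            path = np.clip(pos + np.cumsum(steps, axis=0), lo, hi)
            sec = np.minimum((t - t0).astype(int), path.shape[0] - 1)
            d = np.linalg.norm(
                path[sec][:, None, :] - grid.positions[None, :, :], axis=2
            )  # (n_samples, n_channels)
            gains = 1.0 / (1.0 + (d / spread) ** 2)
            data += (sig[:, None] * gains).astype(np.float32)
        else:
            d = np.linalg.norm(grid.positions - pos, axis=1)
            gains = 1.0 / (1.0 + (d / spread) ** 2)
            data += np.outer(sig, gains).astype(np.float32)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, data.shape).astype(np.float32)
    return Recording(data, rate_hz, grid)


@dataclass
class CohortConfig:
    """Generative model for a cohort of trials.

    Winners follow a logistic model on between-fish differences:
    P(fish A wins) = expit(c0 + c_dsize*(sizeA-sizeB) + c_deodf*(fA-fB)
    + c_dsex*(sexA-sexB)) with sex coded 1 = male.  Loser dark-phase rise
    counts are negative-binomial with mean 184 (winners 18) modulated
    log-linearly by loser-minus-winner size difference with a sign that
    flips with the winner's sex, mirroring the observed opposite
    correlations in male-won versus female-won trials.
    """

    n_trials: int = 37
    size_range_cm: tuple[float, float] = (9.0, 19.0)
    p_male: float = 9.0 / 21.0
    female_eodf_hz: tuple[float, float] = (690.0, 25.0)  # mean, sd; clipped < 740
    male_eodf_hz: tuple[float, float] = (810.0, 55.0)  # clipped > 740
    coef: dict = field(
        default_factory=lambda: {"intercept": 0.0, "dsize": 0.8, "deodf": 0.0, "dsex": 0.0}
    )
    loser_rise_mean: float = 184.0
    winner_rise_mean: float = 18.0
    rise_dispersion: float = 3.1  # NB shape; matches CV ~ 0.6 at mean 184
    rise_dsize_loglinear: float = 0.1  # per cm, sign flipped for female winners
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for k, v in self.coef.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite outcome coefficient {k!r}")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort of trials as one row per trial.

    Columns carry both the raw per-fish attributes (suffix _a/_b), the
    outcome (a_wins), and the loser-minus-winner differences plus rise
    counts used downstream.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    size = rng.uniform(*config.size_range_cm, (n, 2))
    sex = (rng.random((n, 2)) < config.p_male).astype(int)  # 1 = male
    f_mean, f_sd = config.female_eodf_hz
    m_mean, m_sd = config.male_eodf_hz
    eodf = np.where(
        sex == 1,
        np.minimum(np.maximum(rng.normal(m_mean, m_sd, (n, 2)), 741.0), 980.0),
        np.minimum(np.maximum(rng.normal(f_mean, f_sd, (n, 2)), 600.0), 739.0),
    )

    c = config.coef
    eta = (
        c.get("intercept", 0.0)
        + c.get("dsize", 0.0) * (size[:, 0] - size[:, 1])
        + c.get("deodf", 0.0) * (eodf[:, 0] - eodf[:, 1])
        + c.get("dsex", 0.0) * (sex[:, 0] - sex[:, 1])
    )
    a_wins = rng.random(n) < expit(eta)

    win = np.where(a_wins, 0, 1)
    lose = 1 - win
    rows = np.arange(n)
    dsize = size[rows, lose] - size[rows, win]
    deodf = eodf[rows, lose] - eodf[rows, win]
    winner_male = sex[rows, win] == 1

    sign = np.where(winner_male, 1.0, -1.0)
    mu_loser = config.loser_rise_mean * np.exp(
        config.rise_dsize_loglinear * sign * dsize
    )
    r = config.rise_dispersion
    loser_rises = rng.negative_binomial(r, r / (r + mu_loser))
    mu_w = config.winner_rise_mean
    winner_rises = rng.negative_binomial(r, r / (r + mu_w), n)

    return pd.DataFrame(
        dict(
            trial_id=[f"trial{i:03d}" for i in range(n)],
            size_a=size[:, 0], size_b=size[:, 1],
            sex_a=sex[:, 0], sex_b=sex[:, 1],
            eodf_a=eodf[:, 0], eodf_b=eodf[:, 1],
            a_wins=a_wins,
            dsize=dsize, deodf=deodf,
            winner_male=winner_male,
            loser_rises=loser_rises, winner_rises=winner_rises,
            experience_loser=rng.integers(0, 10, n),
            experience_winner=rng.integers(0, 10, n),
        )
    )


def poisson_times(
    rate_hz: float, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Sorted homogeneous Poisson event times on [0, duration)."""
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, n))


def generate_trial(config: TrialConfig) -> SyntheticTrial:
    """Generate one complete trial: traces, truth, events, temperature, meta."""
    (loser_trace, winner_trace), truth = generate_eodf_traces(config)
    events, n_merged = generate_agonistic_events(truth, config)
    temperature = generate_temperature_log(config)
    rng = np.random.default_rng(config.seed + 2)
    sizes = np.sort(rng.uniform(9.0, 19.0, 2))
    meta = TrialRecord(
        trial_id=f"synthetic-{config.seed}",
        fish=(
            FishRecord("loser", size_cm=float(sizes[0]),
                       eodf25_hz=config.baseline_hz[0],
                       dark_rises=config.n_rises[0]),
            FishRecord("winner", size_cm=float(sizes[1]),
                       eodf25_hz=config.baseline_hz[1],
                       dark_rises=config.n_rises[1]),
        ),
        winner="winner",
    )
    return SyntheticTrial(
        config=config,
        traces=(loser_trace, winner_trace),
        true_rises=truth,
        events=events,
        temperature=temperature,
        meta=meta,
        n_merged_chases=n_merged,
    )
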