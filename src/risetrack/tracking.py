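"""From multichannel raw recordings to per-fish EODf traces.

The chain is: short-time Fourier spectrograms per electrode channel
(n_fft = 2**15 samples at 20 kHz, i.e. a 1.6384 s window with 80% overlap),
peak detection on the channel-summed power spectrum of each window,
grouping of peaks into harmonic ladders to obtain candidate fundamental
EODfs, and greedy linking of detections across windows into per-fish traces
using both frequency continuity and the spatial distribution of signal
power over the electrodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import EodfTrace

logger = logging.getLogger(__name__)

DEFAULT_NFFT = 2**15
DEFAULT_OVERLAP = 0.8
DEFAULT_RATE = 20000.0

#: Two fish closer in EODf than this cannot be told apart reliably.
UNRESOLVABLE_DF_HZ = 0.5


@dataclass
class SpectrogramBlock:
    """Per-channel short-time power spectra.

    power has shape (n_channels, n_freqs, n_times), linear power units.
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if self.power.ndim != 3:
            raise ValueError("power must be (channels, freqs, times)")

    def summed(self) -> np.ndarray:
        """Power summed over channels: (n_freqs, n_times)."""
        return self.power.sum(axis=0)


def compute_spectrogram(
    signal: np.ndarray,
    rate_hz: float = DEFAULT_RATE,
    n_fft: int = DEFAULT_NFFT,
    overlap_frac: float = DEFAULT_OVERLAP,
) -> SpectrogramBlock:
    """Spectrogram of a single- or multi-channel signal.

    ``signal`` is (n_samples,) or (n_samples, n_channels).  Window length
    is n_fft / rate (1.6384 s at defaults) and the hop is
    (1 - overlap) * n_fft / rate (0.32768 s).
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must lie in [0, 1)")
    x = np.atleast_2d(np.asarray(signal, dtype=float).T)  # (n_ch, n_samples)
    if x.shape[1] < n_fft:
        raise ValueError(
            f"signal too short: need at least n_fft = {n_fft} samples "
            f"({n_fft / rate_hz:.4f} s at {rate_hz:g} Hz), got {x.shape[1]}"
        )
    freqs, times, power = sps.spectrogram(
        x,
        fs=rate_hz,
        nperseg=n_fft,
        noverlap=int(round(overlap_frac * n_fft)),
        window="hann",
        scaling="spectrum",
        mode="psd",
        detrend=False,
    )
    return SpectrogramBlock(times=times, freqs=freqs, power=power)


@dataclass
class HarmonicGroup:
    """A fundamental candidate with its supporting spectral peaks."""

    fundamental_hz: float
    total_power: float
    peak_freqs: np.ndarray
    harmonics: np.ndarray  # harmonic order of each supporting peak


def _spectral_peaks(
    freqs: np.ndarray, power: np.ndarray, mad_k: float
) -> tuple[np.ndarray, np.ndarray]:
    """Peak frequencies/powers above a median + k*MAD threshold on dB power.

    A parabolic fit through the three bins around each maximum refines the
    peak frequency below bin resolution.
    """
    db = 10.0 * np.log10(np.maximum(power, 1e-300))
    med = np.median(db)
    mad = np.median(np.abs(db - med))
    thresh = med + mad_k * max(mad, 1e-12)
    idx, _ = sps.find_peaks(db, height=thresh)
    if idx.size == 0:
        return np.empty(0), np.empty(0)
    dfreq = freqs[1] - freqs[0]
    pk_freqs = freqs[idx].astype(float)
    inner = (idx > 0) & (idx < freqs.size - 1)
    for k in np.flatnonzero(inner):
        i = idx[k]
        y0, y1, y2 = db[i - 1], db[i], db[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            pk_freqs[k] += 0.5 * (y0 - y2) / denom * dfreq
    return pk_freqs, power[idx]


def detect_harmonic_groups(
    freqs: np.ndarray,
    summed_power: np.ndarray,
    min_freq: float = 400.0,
    max_freq: float = 1200.0,
    max_harmonics: int = 4,
    mad_k: float = 5.0,
    tol_bins: float = 1.0,
    singleton_rel_power: float = 0.05,
) -> list[HarmonicGroup]:
    """Group spectral peaks into harmonic ladders and return fundamentals.

    Candidate fundamentals are every detected peak divided by harmonic
    orders 1..max_harmonics that lands in [min_freq, max_freq]; each
    candidate is scored by the total linear power of peaks lying within
    ``tol_bins`` frequency bins of an integer multiple.  Candidates are
    accepted greedily by score, consuming their peaks, so each peak
    supports at most one group.  A candidate with a missing fundamental
    peak needs at least two supporting harmonics.
    """
    freqs = np.asarray(freqs, dtype=float)
    summed_power = np.asarray(summed_power, dtype=float)
    if freqs.size == 0 or not np.any(summed_power > 0):
        return []
    pk_freqs, pk_pows = _spectral_peaks(freqs, summed_power, mad_k)
    if pk_freqs.size == 0:
        return []
    tol = tol_bins * (freqs[1] - freqs[0])

    groups: list[HarmonicGroup] = []
    available = np.ones(pk_freqs.size, dtype=bool)
    while True:
        best = None  # (score, fund, support_idx, orders)
        cand_funds = []
        for p in pk_freqs[available]:
            for d in range(1, max_harmonics + 1):
                c = p / d
                if min_freq <= c <= max_freq:
                    cand_funds.append(c)
        for c in cand_funds:
            support, orders = [], []
            used = set()
            for h in range(1, max_harmonics + 1):
                target = h * c
                d = np.abs(pk_freqs - target)
                d[~available] = np.inf
                j = int(np.argmin(d))
                if d[j] <= tol * h and j not in used:
                    support.append(j)
                    orders.append(h)
                    used.add(j)
            if not support:
                continue
            if 1 not in orders and len(support) < 2:
                continue
            score = float(pk_pows[support].sum())
            if best is None or score > best[0]:
                # refine fundamental: power-weighted mean of peak/order
                w = pk_pows[support]
                fund = float(np.average(pk_freqs[support] / np.array(orders), weights=w))
                best = (score, fund, support, np.array(orders))
        if best is None:
            break
        score, fund, support, orders = best
        groups.append(
            HarmonicGroup(fund, score, pk_freqs[list(support)].copy(), orders)
        )
        available[list(support)] = False
        if not available.any():
            break
    # a lone in-range peak with no harmonic support is accepted only when
    # its power is comparable to the strongest group: stray noise peaks
    # above the detection threshold must not spawn phantom fish
    if groups:
        strongest = max(g.total_power for g in groups)
        groups = [
            g for g in groups
            if g.peak_freqs.size > 1
            or g.total_power >= singleton_rel_power * strongest
        ]
    groups.sort(key=lambda g: -g.total_power)
    return groups


@dataclass
class TrackingResult:
    traces: list[EodfTrace]
    surplus: list[tuple[float, float]] = field(default_factory=list)
    unresolvable: bool = False
    n_windows: int = 0


def _profile_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Half L1 distance between normalized power profiles, in [0, 1]."""
    pn = p / max(p.sum(), 1e-300)
    qn = q / max(q.sum(), 1e-300)
    return 0.5 * float(np.abs(pn - qn).sum())


def track_traces(
    times: np.ndarray,
    fundamentals: list[np.ndarray],
    profiles: list[np.ndarray] | None = None,
    n_fish: int = 2,
    max_df_hz: float = 30.0,
    weight_freq: float = 0.7,
    max_gap: int = 3,
    rescue_profile_dist: float = 0.35,
    min_coverage: float = 0.1,
) -> TrackingResult:
    """Link per-window fundamental detections into per-fish traces.

    Cost between a trace's last detection and a new one is
    ``weight_freq * |dfreq| / max_df_hz + (1 - weight_freq) * d_profile``
    where d_profile is the half-L1 distance between normalized per-channel
    power profiles.  Links are made greedily from lowest cost; detections
    farther than ``max_df_hz`` from every trace start new traces (up to
    ``n_fish``) or are reported as surplus.  Traces missing for more than
    ``max_gap`` windows are not extended across the gap by frequency alone,
    but a dormant trace can be re-attached by its spatial signature: an
    otherwise-unmatched detection joins the dormant trace with the closest
    power profile when that distance is below ``rescue_profile_dist`` —
    frequency may have moved arbitrarily far (e.g. across a large rise)
    while the fish's position, and hence its per-channel power pattern,
    changed little.
    """
    times = np.asarray(times, dtype=float)
    n_win = times.size
    if len(fundamentals) != n_win:
        raise ValueError("one detection array per window required")
    if profiles is None:
        profiles = [None] * n_win

    class _Trace:
        __slots__ = ("freqs", "last_freq", "last_profile", "last_win")

        def __init__(self, n):
            self.freqs = np.full(n, np.nan)
            self.last_freq = np.nan
            self.last_profile = None
            self.last_win = -1

    tracks: list[_Trace] = []
    surplus: list[tuple[float, float]] = []

    for w in range(n_win):
        dets = np.asarray(fundamentals[w], dtype=float)
        profs = profiles[w]
        order = np.argsort(dets) if dets.size else np.empty(0, int)
        active = [
            k for k, tr in enumerate(tracks) if w - tr.last_win <= max_gap + 1
        ]
        # candidate links (cost, track_idx, det_idx)
        cands = []
        for k in active:
            tr = tracks[k]
            for j in range(dets.size):
                df = abs(dets[j] - tr.last_freq)
                if df > max_df_hz:
                    continue
                cost = weight_freq * df / max_df_hz
                if profs is not None and tr.last_profile is not None:
                    cost += (1 - weight_freq) * _profile_distance(
                        np.asarray(profs[j]), tr.last_profile
                    )
                cands.append((cost, k, j))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for cost, k, j in cands:
            if k in used_tracks or j in used_dets:
                continue
            tr = tracks[k]
            tr.freqs[w] = dets[j]
            tr.last_freq = dets[j]
            if profs is not None:
                tr.last_profile = np.asarray(profs[j], dtype=float)
            tr.last_win = w
            used_tracks.add(k)
            used_dets.add(j)
        # rescue: dormant traces re-identified by spatial power profile
        if profs is not None:
            rescue = []
            for k, tr in enumerate(tracks):
                if k in used_tracks or k in active or tr.last_profile is None:
                    continue
                for j in range(dets.size):
                    if j in used_dets:
                        continue
                    dist = _profile_distance(np.asarray(profs[j]), tr.last_profile)
                    if dist <= rescue_profile_dist:
                        rescue.append((dist, k, j))
            rescue.sort(key=lambda c: (c[0], c[1], c[2]))
            for dist, k, j in rescue:
                if k in used_tracks or j in used_dets:
                    continue
                tr = tracks[k]
                tr.freqs[w] = dets[j]
                tr.last_freq = dets[j]
                tr.last_profile = np.asarray(profs[j], dtype=float)
                tr.last_win = w
                used_tracks.add(k)
                used_dets.add(j)
        for j in order:
            if int(j) in used_dets:
                continue
            if len(tracks) < n_fish:
                tr = _Trace(n_win)
                tr.freqs[w] = dets[j]
                tr.last_freq = dets[j]
                if profs is not None:
                    tr.last_profile = np.asarray(profs[int(j)], dtype=float)
                tr.last_win = w
                tracks.append(tr)
            else:
                surplus.append((float(times[w]), float(dets[j])))

    if surplus:
        logger.warning(
            "%d surplus detections beyond the configured %d fish",
            len(surplus), n_fish,
        )
    traces = [
        EodfTrace(f"fish{k + 1}", times, tr.freqs) for k, tr in enumerate(tracks)
    ]
    # a fish counts as resolved only if its trace covers a meaningful part
    # of the recording; two resolved fish closer than the resolvability
    # limit, or fewer resolved traces than fish, flag the trial
    unresolvable = False
    meds = [
        np.nanmedian(tr.freq)
        for tr in traces
        if np.isfinite(tr.freq).mean() >= min_coverage
    ]
    if n_fish >= 2:
        if len(meds) < n_fish:
            unresolvable = True
        elif len(meds) == 2 and abs(meds[0] - meds[1]) < UNRESOLVABLE_DF_HZ:
            unresolvable = True
    if unresolvable:
        logger.warning(
            "EODf difference below %.1f Hz: traces unresolvable",
            UNRESOLVABLE_DF_HZ,
        )
    return TrackingResult(
        traces=traces, surplus=surplus, unresolvable=unresolvable, n_windows=n_win
    )


def track_recording(
    recording,
    n_fish: int = 2,
    n_fft: int = DEFAULT_NFFT,
    overlap_frac: float = DEFAULT_OVERLAP,
    min_freq: float = 400.0,
    max_freq: float = 1200.0,
    max_harmonics: int = 4,
    mad_k: float = 5.0,
    max_df_hz: float = 30.0,
    weight_freq: float = 0.7,
) -> TrackingResult:
    """Full chain: recording -> spectrogram -> harmonic groups -> traces.

    Power profiles for the tracker are the per-channel power in a small
    band around each detected fundamental.
    """
    spec = compute_spectrogram(
        recording.data, recording.rate_hz, n_fft, overlap_frac
    )
    summed = spec.summed()
    dfreq = spec.freqs[1] - spec.freqs[0]
    fundamentals: list[np.ndarray] = []
    profiles: list[np.ndarray] = []
    for w in range(spec.times.size):
        groups = detect_harmonic_groups(
            spec.freqs, summed[:, w], min_freq, max_freq, max_harmonics, mad_k
        )
        funds = np.array([g.fundamental_hz for g in groups])
        profs = []
        for g in groups:
            i0 = int(np.searchsorted(spec.freqs, g.fundamental_hz - 1.5 * dfreq))
            i1 = int(np.searchsorted(spec.freqs, g.fundamental_hz + 1.5 * dfreq)) + 1
            profs.append(spec.power[:, i0:i1, w].sum(axis=1))
        fundamentals.append(funds)
        profiles.append(np.array(profs) if profs else np.empty((0, spec.power.shape[0])))
    return track_traces(
        spec.times, fundamentals, profiles,
        n_fish=n_fish, max_df_hz=max_df_hz, weight_freq=weight_freq,
    )
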