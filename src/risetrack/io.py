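"""File formats, configuration, and end-to-end orchestration.

Conventions: times are seconds from trial start (0-based, half-open
intervals), delimited files are comma-separated UTF-8 with a header row and
empty fields for missing values.  Raw audio-rate data travel as a flat
binary matrix with a JSON sidecar naming rate and channel layout.  Every
pipeline run writes a manifest recording the configuration hash, seed and
software version so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    DARK_S,
    TRIAL_S,
    AgonisticEvent,
    EodfTrace,
    TemperatureLog,
    events_to_frame,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- tables

def write_traces(traces: list[EodfTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {"fish_id": tr.fish_id, "time_s": tr.times, "freq_hz": tr.freq}
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list[EodfTrace]:
    df = pd.read_csv(path)
    out = []
    for fid, grp in df.groupby("fish_id", sort=False):
        out.append(
            EodfTrace(str(fid), grp["time_s"].to_numpy(), grp["freq_hz"].to_numpy())
        )
    return out


def write_temperature(log: TemperatureLog, path) -> None:
    pd.DataFrame({"time_s": log.times, "temp_c": log.temp}).to_csv(path, index=False)


def read_temperature(path) -> TemperatureLog:
    df = pd.read_csv(path)
    return TemperatureLog(df["time_s"].to_numpy(), df["temp_c"].to_numpy())


def write_rises(rises_df: pd.DataFrame, path) -> None:
    rises_df.to_csv(path, index=False)


def read_rises(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ------------------------------------------------------- BORIS event logs

#: behavior label -> event kind and whether it is a point or state behavior
KNOWN_BEHAVIORS = {"contact": ("contact", "point"), "chase": ("chase", "state")}


def write_event_log(events: list[AgonisticEvent], path) -> None:
    """Write events in the BORIS-style (time, behavior, status) dialect."""
    rows = []
    for e in events:
        if e.kind == "contact":
            rows.append((e.onset_s, "contact", "POINT"))
        else:
            rows.append((e.onset_s, "chase", "START"))
            rows.append((e.end_s, "chase", "STOP"))
    rows.sort()
    pd.DataFrame(rows, columns=["time", "behavior", "status"]).to_csv(
        path, index=False
    )


def read_event_log(path, phase_end_s: float = DARK_S) -> list[AgonisticEvent]:
    """Parse a BORIS-style export into events.

    POINT rows become contacts; START/STOP rows are paired by time order
    into chase intervals.  An unpaired START is closed at ``phase_end_s``
    with a warning; a STOP without a START is an error naming the row.
    Unknown behavior labels are listed and skipped.
    """
    df = pd.read_csv(path)
    required = {"time", "behavior", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"event log needs columns {sorted(required)}")
    unknown = sorted(set(df["behavior"]) - set(KNOWN_BEHAVIORS))
    if unknown:
        logger.warning("skipping unknown behavior labels: %s", unknown)
        df = df[df["behavior"].isin(KNOWN_BEHAVIORS)]
    df = df.sort_values("time", kind="stable").reset_index()

    events: list[AgonisticEvent] = []
    open_start: dict[str, float] = {}
    for _, row in df.iterrows():
        status = str(row["status"]).upper()
        behavior = str(row["behavior"])
        t = float(row["time"])
        if status == "POINT":
            events.append(AgonisticEvent("contact", t))
        elif status == "START":
            if behavior in open_start:
                raise ValueError(
                    f"line {int(row['index']) + 2}: nested START for {behavior!r}"
                )
            open_start[behavior] = t
        elif status == "STOP":
            if behavior not in open_start:
                raise ValueError(
                    f"line {int(row['index']) + 2}: STOP without START for "
                    f"{behavior!r}"
                )
            events.append(AgonisticEvent("chase", open_start.pop(behavior), t))
        else:
            raise ValueError(f"unknown status {status!r}")
    for behavior, t in open_start.items():
        warnings.warn(
            f"unpaired START for {behavior!r} at {t} s closed at phase end",
            stacklevel=2,
        )
        events.append(AgonisticEvent("chase", t, phase_end_s))
    events.sort(key=lambda e: e.onset_s)
    return events


# ---------------------------------------------------------- raw recordings

def write_recording(recording, directory) -> None:
    """Binary float32 matrix + JSON sidecar (rate, channels, layout)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.asarray(recording.data, dtype=np.float32)
    data.tofile(directory / "recording.raw")
    sidecar = {
        "rate_hz": recording.rate_hz,
        "n_channels": int(data.shape[1]),
        "n_samples": int(data.shape[0]),
        "dtype": "float32",
        "order": "samples x channels, C-contiguous",
        "electrode_positions": np.asarray(recording.grid.positions).tolist(),
    }
    (directory / "recording.json").write_text(json.dumps(sidecar, indent=2))


def read_recording(directory):
    from .synthetic import ElectrodeGrid, Recording

    directory = Path(directory)
    sidecar = json.loads((directory / "recording.json").read_text())
    data = np.fromfile(directory / "recording.raw", dtype=np.float32)
    data = data.reshape(sidecar["n_samples"], sidecar["n_channels"])
    grid = ElectrodeGrid(np.array(sidecar["electrode_positions"]))
    return Recording(data, sidecar["rate_hz"], grid)


# ------------------------------------------------------------ run config

@dataclass
class RunConfig:
    """All pipeline parameters with their study defaults."""

    # stages
    simulate: bool = True
    track: bool = False
    detect: bool = True
    couple: bool = True
    # spectral tracking
    n_fft: int = 2**15
    overlap_frac: float = 0.8
    # EODf processing
    baseline_window_s: float = 300.0
    q10: float = 1.37
    estimate_q10: bool = True
    male_cutoff_hz: float = 740.0
    # rise detection
    rise_threshold_hz: float = 5.0
    # coupling
    kernel_sd_s: float = 1.0
    window_s: float = 60.0
    pre_window_s: float = 5.0
    n_perm: int = 1000
    n_boot: int = 1000
    alpha: float = 0.05
    # phases
    dark_s: float = DARK_S
    duration_s: float = TRIAL_S
    # synthetic trial parameters passed through to TrialConfig
    trial: dict = field(default_factory=dict)
    # bookkeeping
    seed: int = 0
    out_dir: str = "risetrack-out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# --------------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute the enabled stages in dependency order.

    simulate -> (track) -> detect (baselines, Q10, correction, rises) ->
    couple (rate curve with permutation and jackknife bands against
    contacts).  Artifacts land in ``out_dir`` together with a manifest;
    identical config + seed reproduce identical outputs.
    """
    from . import coupling, eodf, rises as rises_mod, synthetic

    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    if not config.simulate:
        raise ValueError("pipeline currently requires simulation inputs")
    trial_kwargs = dict(config.trial)
    trial_kwargs.setdefault("seed", config.seed)
    trial_kwargs.setdefault("dark_s", config.dark_s)
    trial_kwargs.setdefault("duration_s", config.duration_s)
    tconf = synthetic.TrialConfig(**trial_kwargs)
    trial = synthetic.generate_trial(tconf)
    write_traces(list(trial.traces), out / "traces.csv")
    write_temperature(trial.temperature, out / "temperature.csv")
    trial.true_rises.to_csv(out / "true_rises.csv", index=False)
    write_event_log(trial.events, out / "events.csv")
    summary["n_true_rises"] = int(len(trial.true_rises))
    summary["n_events"] = len(trial.events)

    detected = {}
    if config.detect:
        q10_used = config.q10
        for tr in trial.traces:
            bs = eodf.baseline_series(tr, config.baseline_window_s)
            rlist_pre = rises_mod.detect_rises(tr, config.rise_threshold_hz, bs)
            if config.estimate_q10:
                masked = eodf.mask_rise_windows(
                    bs, np.array([r.peak_time for r in rlist_pre])
                )
                _, q10_used = eodf.estimate_q10(masked, trial.temperature)
            corrected = eodf.correct_to_25(tr, trial.temperature, q10_used)
            bs25 = eodf.baseline_series(corrected, config.baseline_window_s)
            med25 = float(np.nanmedian(bs25.baseline_hz))
            rlist = rlist_pre  # rises are detected on the uncorrected trace
            detected[tr.fish_id] = rlist
            summary[f"{tr.fish_id}_rises_detected"] = len(rlist)
            summary[f"{tr.fish_id}_median_eodf25"] = med25
            summary[f"{tr.fish_id}_sex"] = eodf.assign_sex(med25)
        summary["q10_used"] = float(q10_used)
        all_rises = rises_mod.rises_table(
            [r for rl in detected.values() for r in rl]
        )
        write_rises(all_rises, out / "rises.csv")
        logger.info("detected %d rises", len(all_rises))

    if config.couple:
        if not config.detect:
            raise ValueError("coupling requires the detection stage")
        rise_times = np.sort(
            [r.peak_time for r in detected.get("loser", [])]
        )
        contacts = coupling.contact_onsets_from_events(trial.events)
        if contacts.size and rise_times.size >= 2:
            curve = coupling.rate_curve_with_bands(
                rise_times, contacts,
                n_perm=config.n_perm, seed=config.seed,
                dark_s=config.dark_s,
                window_s=config.window_s, kernel_sd_s=config.kernel_sd_s,
            )
            pd.DataFrame(
                {
                    "lag_s": curve.lags,
                    "rate": curve.rate,
                    "jk_lo": curve.jackknife_lo,
                    "jk_hi": curve.jackknife_hi,
                    "null_lo": curve.null_lo,
                    "null_hi": curve.null_hi,
                }
            ).to_csv(out / "rate_curve.csv", index=False)
            exceed = curve.rate > curve.null_hi
            summary["coupling_significant_lags"] = int(exceed.sum())
        else:
            logger.warning("coupling skipped: not enough rises or contacts")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
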