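"""On-disk formats: schedule CSV, trace CSV, aligned-tensor HDF5, YAML config.

Column names are fixed:

* schedule CSV — trial_index, onset_s, intensity_db, envelope
* trace CSV   — time_s, value
* track CSV   — t_s, x_cm, y_cm
* pupil CSV   — t_s, area_px2
* aligned HDF5 — datasets z, rel_time, intensity plus a rate attribute
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import PupilSeries, Rect, Track, ZoneLayout
from .preprocess import RawTrace, TrialAlignedTraces
from .synthetic_data import StimulusSchedule

__all__ = [
    "write_schedule_csv",
    "read_schedule_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_aligned_h5",
    "read_aligned_h5",
    "read_track_csv",
    "read_layout_json",
    "read_pupil_csv",
    "load_yaml",
    "dump_yaml",
]


def write_schedule_csv(schedule: StimulusSchedule, path) -> None:
    df = pd.DataFrame(
        dict(
            trial_index=np.arange(schedule.n_trials),
            onset_s=schedule.trial_onsets,
            intensity_db=schedule.trial_intensity,
            envelope=schedule.envelope,
        )
    )
    df.to_csv(path, index=False)
    meta = dict(
        bursts_per_trial=schedule.bursts_per_trial,
        burst_period=schedule.burst_period,
        burst_duration=schedule.burst_duration,
        rise_time=schedule.rise_time,
        fall_time=schedule.fall_time,
    )
    Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_schedule_csv(path) -> StimulusSchedule:
    df = pd.read_csv(path)
    meta_path = Path(path).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    envelope = str(df["envelope"].iloc[0]) if "envelope" in df else "flat"
    return StimulusSchedule(
        trial_onsets=df["onset_s"].to_numpy(),
        trial_intensity=df["intensity_db"].to_numpy(),
        envelope=envelope,
        **meta,
    )


def write_trace_csv(trace: RawTrace, path) -> None:
    pd.DataFrame(dict(time_s=trace.times, value=trace.values)).to_csv(path, index=False)


def read_trace_csv(path) -> RawTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace must contain at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-3, atol=1e-9):
        raise ValueError("trace must be uniformly sampled")
    return RawTrace(values=df["value"].to_numpy(dtype=float), rate=1.0 / dt[0], t0=float(t[0]))


def write_aligned_h5(aligned: TrialAlignedTraces, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("z", data=aligned.z)
        f.create_dataset("rel_time", data=aligned.rel_time)
        f.create_dataset("intensity", data=aligned.intensity)
        f.attrs["rate"] = aligned.rate


def read_aligned_h5(path) -> TrialAlignedTraces:
    with h5py.File(path, "r") as f:
        return TrialAlignedTraces(
            z=f["z"][...],
            rel_time=f["rel_time"][...],
            intensity=f["intensity"][...],
            rate=float(f.attrs["rate"]),
        )


def read_track_csv(path, session_windows=None) -> Track:
    df = pd.read_csv(path)
    return Track(
        timestamps=df["t_s"].to_numpy(dtype=float),
        x=df["x_cm"].to_numpy(dtype=float),
        y=df["y_cm"].to_numpy(dtype=float),
        session_windows=session_windows or {},
    )


def read_layout_json(path) -> ZoneLayout:
    spec = json.loads(Path(path).read_text())
    return ZoneLayout(
        zone_a=Rect(*spec["zone_a"]),
        zone_b=Rect(*spec["zone_b"]),
    )


def read_pupil_csv(path, onsets, stimulus_dur: float = 10.0) -> PupilSeries:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-3, atol=1e-9):
        raise ValueError("pupil series must be uniformly sampled")
    return PupilSeries(
        area=df["area_px2"].to_numpy(dtype=float),
        rate=1.0 / dt[0],
        onsets=np.asarray(onsets, dtype=float),
        stimulus_dur=stimulus_dur,
        t0=float(t[0]),
    )


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def dump_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
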