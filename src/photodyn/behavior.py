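"""Two-compartment occupancy and pupil response metrics.

Occupancy weights each inter-sample interval by its duration and assigns it
to the zone of the earlier sample; Zone A and Zone B percentages therefore
sum to exactly 100 within a session. Pupil responses reuse the per-trial
baseline z-scoring convention of :mod:`photodyn.preprocess`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import RawTrace, zscore_by_trial

__all__ = [
    "Rect",
    "ZoneLayout",
    "Track",
    "PupilSeries",
    "zone_occupancy",
    "pupil_response",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x, y):
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)


@dataclass(frozen=True)
class ZoneLayout:
    """Two rectangles partitioning the arena; anything not in A is B."""

    zone_a: Rect
    zone_b: Rect

    def zone_of(self, x, y):
        """Vectorised zone membership: True for Zone A, False for Zone B."""
        return self.zone_a.contains(np.asarray(x), np.asarray(y))


@dataclass(frozen=True)
class Track:
    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    session_windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        x = np.asarray(self.x, dtype=float)
        yy = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", yy)
        if not (ts.shape == x.shape == yy.shape):
            raise ValueError("timestamps, x and y must have equal length")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(yy))):
            raise ValueError("positions must be finite")


@dataclass(frozen=True)
class PupilSeries:
    """Pupil area per frame plus the stimulus schedule used to evoke it."""

    area: np.ndarray
    rate: float = 30.0
    onsets: np.ndarray = field(default_factory=lambda: np.array([]))
    stimulus_dur: float = 10.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.area, dtype=float)
        o = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "area", a)
        object.__setattr__(self, "onsets", o)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")


def zone_occupancy(track: Track, layout: ZoneLayout, session: str) -> dict[str, float]:
    """Percent time in each zone during one session window.

    Each inter-sample interval contributes its duration to the zone of its
    earlier sample; the final partial interval runs to the window end.
    """
    if session not in track.session_windows:
        raise KeyError(f"unknown session {session!r}")
    start, end = track.session_windows[session]
    if end <= start:
        raise ValueError("empty session window")
    ts = track.timestamps
    mask = (ts >= start) & (ts < end)
    if not mask.any():
        raise ValueError(f"session {session!r} contains no track samples")
    idx = np.flatnonzero(mask)
    t = ts[idx]
    in_a = layout.zone_of(track.x[idx], track.y[idx])
    bounds = np.append(t, end)
    dt = np.diff(bounds)
    total = dt.sum()
    time_a = dt[in_a].sum()
    pct_a = 100.0 * time_a / total
    return {"A": pct_a, "B": 100.0 - pct_a}


def pupil_response(
    series: PupilSeries,
    baseline_dur: float = 5.0,
    normalize: bool = True,
) -> np.ndarray:
    """Mean response per stimulus over [onset, onset + stimulus_dur).

    With ``normalize=True`` each trial is baseline z-scored (5-s pre-onset
    mean/sd) before averaging; with ``normalize=False`` the response is the
    raw mean minus the baseline mean (useful for noiseless calibration,
    where the baseline sd is zero and z-scoring is undefined).
    """
    if series.onsets.size == 0:
        raise ValueError("series has no stimulus onsets")
    raw = RawTrace(values=series.area, rate=series.rate, t0=series.t0)
    if normalize:
        aligned = zscore_by_trial(
            raw,
            series.onsets,
            baseline_dur=baseline_dur,
            segment=(0.0, series.stimulus_dur),
        )
        return aligned.z.mean(axis=1)
    out = np.empty(series.onsets.size)
    nb = int(round(baseline_dur * series.rate))
    nwin = int(round(series.stimulus_dur * series.rate))
    for k, onset in enumerate(series.onsets):
        i0 = int(round((onset - series.t0) * series.rate))
        if i0 - nb < 0 or i0 + nwin > raw.n:
            raise ValueError(f"stimulus {k}: window outside the series")
        base = series.area[i0 - nb : i0].mean()
        out[k] = series.area[i0 : i0 + nwin].mean() - base
    return out
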