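"""Raw trace conditioning: downsampling, trial z-scoring, smoothing, averaging.

Conventions used throughout:

* sample ``i`` of a trace starting at ``t0`` covers ``[t0 + i/rate,
  t0 + (i+1)/rate)`` — all windows are half-open;
* each trial is z-scored against the mean and standard deviation (ddof=1)
  of the 5 s immediately preceding its onset;
* the moving median is centred with an odd window; edges use the truncated
  window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RawTrace",
    "TrialAlignedTraces",
    "DegenerateBaselineError",
    "resample_uniform",
    "zscore_by_trial",
    "moving_median",
    "average_trials",
    "segment_bursts",
]


class DegenerateBaselineError(ValueError):
    """Raised when a trial's pre-onset baseline has zero standard deviation."""


@dataclass(frozen=True)
class RawTrace:
    """Uniformly sampled single-channel signal."""

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if v.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    @property
    def duration(self) -> float:
        return self.n / self.rate


@dataclass(frozen=True)
class TrialAlignedTraces:
    """Per-trial baseline-z-scored segments on a common relative time axis."""

    z: np.ndarray  # trials x samples
    rel_time: np.ndarray  # seconds relative to trial onset
    intensity: np.ndarray  # dB per trial
    rate: float

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        rel = np.asarray(self.rel_time, dtype=float)
        intens = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "rel_time", rel)
        object.__setattr__(self, "intensity", intens)
        if z.ndim != 2 or z.shape[1] != rel.size or z.shape[0] != intens.size:
            raise ValueError("inconsistent aligned-trace shapes")

    @property
    def n_trials(self) -> int:
        return int(self.z.shape[0])

    def select(self, intensity: float) -> np.ndarray:
        mask = self.intensity == intensity
        if not mask.any():
            raise KeyError(f"no trials at intensity {intensity}")
        return self.z[mask]


def resample_uniform(raw: RawTrace, target_rate: float) -> RawTrace:
    """Downsample to ``target_rate`` (low-pass at the target Nyquist, then
    linear interpolation onto the uniform output grid).

    Upsampling is refused: ``target_rate`` must not exceed ``raw.rate``.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    if target_rate > raw.rate:
        raise ValueError("target_rate must not exceed the input rate (no upsampling)")
    if target_rate == raw.rate:
        return RawTrace(values=raw.values.copy(), rate=raw.rate, t0=raw.t0)

    x = raw.values
    # Zero-phase Butterworth at the output Nyquist; skipped when the input
    # is too short for filtfilt's edge padding or the band edge is ~1.
    wn = target_rate / raw.rate  # = (target_rate/2) / (raw.rate/2)
    if wn < 0.95:
        sos = signal.butter(4, wn, btype="low", output="sos")
        # pad generously (one output-sample period) to keep edge transients
        # below the interpolation error
        padlen = min(x.size - 1, max(27, int(round(3 * raw.rate / target_rate))))
        if padlen >= 1:
            x = signal.sosfiltfilt(sos, x, padlen=padlen)

    n_out = int(round(raw.n * target_rate / raw.rate))
    t_out = np.arange(n_out) / target_rate
    t_in = np.arange(raw.n) / raw.rate
    return RawTrace(values=np.interp(t_out, t_in, x), rate=target_rate, t0=raw.t0)


def zscore_by_trial(
    raw: RawTrace,
    trial_onsets,
    baseline_dur: float = 5.0,
    segment: tuple[float, float] = (5.0, 10.0),
    intensities=None,
) -> TrialAlignedTraces:
    """Per-trial baseline z-scoring and segment extraction.

    For each onset, z = (x - mean) / sd with mean/sd taken over the
    ``baseline_dur`` seconds before the onset (sd with ddof=1), and the
    segment covering ``[-segment[0], +segment[1])`` relative to onset.
    """
    onsets = np.asarray(trial_onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("trial_onsets must be non-empty")
    pre, post = float(segment[0]), float(segment[1])
    if pre < 0 or post <= 0:
        raise ValueError("segment must satisfy pre >= 0 and post > 0")

    rate = raw.rate
    nb = int(round(baseline_dur * rate))
    npre = int(round(pre * rate))
    npost = int(round(post * rate))
    if nb < 2:
        raise ValueError("baseline window must contain at least 2 samples")

    z = np.empty((onsets.size, npre + npost))
    for k, onset in enumerate(onsets):
        i0 = int(round((onset - raw.t0) * rate))
        if i0 - nb < 0 or i0 - npre < 0:
            raise ValueError(f"trial {k}: insufficient samples before onset")
        if i0 + npost > raw.n:
            raise ValueError(f"trial {k}: segment extends past the end of the trace")
        baseline = raw.values[i0 - nb : i0]
        mu = baseline.mean()
        sd = baseline.std(ddof=1)
        if sd == 0:
            raise DegenerateBaselineError(f"trial {k}: baseline standard deviation is zero")
        z[k] = (raw.values[i0 - npre : i0 + npost] - mu) / sd

    rel_time = (np.arange(npre + npost) - npre) / rate
    if intensities is None:
        intens = np.full(onsets.size, np.nan)
    else:
        intens = np.asarray(intensities, dtype=float)
        if intens.shape != onsets.shape:
            raise ValueError("intensities must match trial_onsets in length")
    return TrialAlignedTraces(z=z, rel_time=rel_time, intensity=intens, rate=rate)


def moving_median(series, window: float = 0.2, rate: float = 120.0) -> np.ndarray:
    """Centred moving-median smoothing with an odd window (truncated edges).

    ``window`` is in seconds; the window length in samples is rounded and,
    if even, incremented to the next odd number (0.2 s at 120 Hz -> 25).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    n_win = int(round(window * rate))
    if n_win < 1:
        raise ValueError("window must span at least one sample")
    if n_win % 2 == 0:
        n_win += 1
    return (
        pd.Series(x).rolling(n_win, center=True, min_periods=1).median().to_numpy()
    )


def average_trials(aligned: TrialAlignedTraces, intensities=None) -> dict[float, np.ndarray]:
    """Pointwise mean trace per intensity.

    Raises ``KeyError`` if a requested intensity has no trials.
    """
    if intensities is None:
        intensities = np.unique(aligned.intensity)
    out: dict[float, np.ndarray] = {}
    for db in intensities:
        out[float(db)] = aligned.select(float(db)).mean(axis=0)
    return out


def segment_bursts(
    trace,
    burst_onsets,
    rate: float,
    window: float = 1.0,
    t0: float = 0.0,
) -> np.ndarray:
    """Cut half-open windows ``[onset, onset + window)`` from a trace.

    ``t0`` is the time of the first sample of ``trace`` (e.g. -5.0 for a
    trial-aligned segment starting 5 s before onset). Returns a
    (bursts x samples) matrix in burst order.
    """
    x = np.asarray(trace, dtype=float)
    if window <= 0:
        raise ValueError("window must be > 0")
    onsets = np.asarray(burst_onsets, dtype=float)
    nwin = int(round(window * rate))
    segs = np.empty((onsets.size, nwin))
    for k, onset in enumerate(onsets):
        i0 = int(round((onset - t0) * rate))
        if i0 < 0 or i0 + nwin > x.size:
            raise ValueError(f"burst {k}: window [{onset}, {onset + window}) overruns the trace")
        segs[k] = x[i0 : i0 + nwin]
    return segs
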