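"""Per-burst response metrics and increase/decrease phenotype classification.

Amplitudes follow the onset-referenced convention: each burst's positive and
negative amplitudes are absolute differences between the z value at the
burst-onset sample and the extrema within the burst window. A subject is
classified "increase" when the maximum of its trial-averaged trace over the
stimulus window strictly exceeds the threshold (default 2.58) at any tested
intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import TrialAlignedTraces, average_trials, segment_bursts
from .synthetic_data import StimulusSchedule

__all__ = [
    "Extrema",
    "BurstMetrics",
    "IntensityResponse",
    "SubjectSummary",
    "extrema_in_window",
    "burst_metrics",
    "peak_ratio",
    "classify_subject",
    "summarize_subject",
    "summaries_to_table",
    "CLASSIFIER_THRESHOLD",
]

CLASSIFIER_THRESHOLD = 2.58


@dataclass(frozen=True)
class Extrema:
    min_z: float
    min_latency: float
    max_z: float
    max_latency: float


@dataclass(frozen=True)
class BurstMetrics:
    burst_index: int  # 1-based
    onset_z: float
    min_z: float
    max_z: float
    neg_latency: float
    pos_latency: float
    neg_amplitude: float
    pos_amplitude: float


@dataclass(frozen=True)
class IntensityResponse:
    """Extrema of the first-burst window and of the across-burst average."""

    intensity: float
    first: Extrema
    average: Extrema
    trial_window_max: float  # classifier statistic for this intensity


@dataclass(frozen=True)
class SubjectSummary:
    subject_id: str
    responses: dict[float, IntensityResponse] = field(default_factory=dict)
    phenotype: str = "decrease"
    max_z: float = float("-inf")  # max of trial_window_max over intensities

    @property
    def intensities(self) -> list[float]:
        return sorted(self.responses)


def extrema_in_window(series, rate: float, window: tuple[float, float], t0: float = 0.0) -> Extrema:
    """Min/max and first-occurrence latencies over the half-open window.

    Latencies are measured from the window start.
    """
    x = np.asarray(series, dtype=float)
    a, b = float(window[0]), float(window[1])
    i0 = int(round((a - t0) * rate))
    i1 = int(round((b - t0) * rate))
    if i1 <= i0:
        raise ValueError("window must be non-empty")
    if i0 < 0 or i1 > x.size:
        raise ValueError("window outside the series")
    seg = x[i0:i1]
    imin = int(np.argmin(seg))
    imax = int(np.argmax(seg))
    return Extrema(
        min_z=float(seg[imin]),
        min_latency=imin / rate,
        max_z=float(seg[imax]),
        max_latency=imax / rate,
    )


def burst_metrics(
    avg_trace,
    burst_onsets,
    rate: float,
    window: float = 1.0,
    t0: float = 0.0,
) -> list[BurstMetrics]:
    """Onset-referenced amplitude/latency metrics for each burst window."""
    x = np.asarray(avg_trace, dtype=float)
    segs = segment_bursts(x, burst_onsets, rate, window=window, t0=t0)
    out = []
    for k, seg in enumerate(segs):
        onset_z = float(seg[0])
        imin = int(np.argmin(seg))
        imax = int(np.argmax(seg))
        out.append(
            BurstMetrics(
                burst_index=k + 1,
                onset_z=onset_z,
                min_z=float(seg[imin]),
                max_z=float(seg[imax]),
                neg_latency=imin / rate,
                pos_latency=imax / rate,
                neg_amplitude=abs(onset_z - float(seg[imin])),
                pos_amplitude=abs(float(seg[imax]) - onset_z),
            )
        )
    return out


def peak_ratio(second_peak: float, first_peak: float, eps: float = 1e-6) -> float:
    """second/first on signed onset-referenced peaks; NaN when |first| < eps."""
    if abs(first_peak) < eps:
        return float("nan")
    return second_peak / first_peak


def classify_subject(summary, threshold: float = CLASSIFIER_THRESHOLD) -> str:
    """'increase' iff the trial-averaged maximum strictly exceeds the threshold
    at any intensity; ties and everything else are 'decrease'."""
    if isinstance(summary, SubjectSummary):
        maxes = [r.trial_window_max for r in summary.responses.values()]
    else:
        maxes = list(np.atleast_1d(np.asarray(summary, dtype=float)))
    if len(maxes) == 0:
        raise ValueError("summary must cover at least one intensity")
    return "increase" if max(maxes) > threshold else "decrease"


def summarize_subject(
    aligned: TrialAlignedTraces,
    schedule: StimulusSchedule,
    burst_window: float = 1.0,
    threshold: float = CLASSIFIER_THRESHOLD,
    subject_id: str = "",
) -> SubjectSummary:
    """Per-intensity first/average extrema and the phenotype label.

    For each intensity the trials are averaged pointwise; "first" extrema
    come from the burst-1 window of that average, "average" extrema from the
    pointwise mean of the per-burst windows. The classifier statistic is the
    maximum of the averaged trace over the stimulus window [0, 10).
    """
    rel0 = float(aligned.rel_time[0])
    rate = aligned.rate
    burst_onsets = schedule.relative_burst_onsets()
    means = average_trials(aligned)
    responses: dict[float, IntensityResponse] = {}
    for db, trace in means.items():
        segs = segment_bursts(trace, burst_onsets, rate, window=burst_window, t0=rel0)
        first = _extrema_of(segs[0], rate)
        average = _extrema_of(segs.mean(axis=0), rate)
        trial_max = extrema_in_window(
            trace, rate, (0.0, schedule.trial_duration), t0=rel0
        ).max_z
        responses[db] = IntensityResponse(
            intensity=db, first=first, average=average, trial_window_max=trial_max
        )
    max_z = max(r.trial_window_max for r in responses.values())
    phenotype = classify_subject([r.trial_window_max for r in responses.values()], threshold)
    return SubjectSummary(
        subject_id=subject_id, responses=responses, phenotype=phenotype, max_z=max_z
    )


def _extrema_of(seg: np.ndarray, rate: float) -> Extrema:
    imin = int(np.argmin(seg))
    imax = int(np.argmax(seg))
    return Extrema(float(seg[imin]), imin / rate, float(seg[imax]), imax / rate)


def summaries_to_table(summaries) -> pd.DataFrame:
    """Tidy table: one row per (subject, intensity, response_type, measure)."""
    rows = []
    for s in summaries:
        for db, r in sorted(s.responses.items()):
            for response_type, ext in (("first", r.first), ("average", r.average)):
                rows.append(
                    dict(
                        subject_id=s.subject_id,
                        intensity=db,
                        response_type=response_type,
                        measure="min",
                        value=ext.min_z,
                        latency=ext.min_latency,
                    )
                )
                rows.append(
                    dict(
                        subject_id=s.subject_id,
                        intensity=db,
                        response_type=response_type,
                        measure="max",
                        value=ext.max_z,
                        latency=ext.max_latency,
                    )
                )
    return pd.DataFrame(rows)
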