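"""Synthetic stimulus schedules and photometry-like recordings.

Generates burst-train stimulus schedules (10 x 500 ms on / 500 ms off bursts
per 10-s trial, intensities in dB SPL, inter-trial intervals drawn from a
small set) together with surrogate single-channel recordings built from
phenomenological response kernels:

* a negative "dip" locked to each burst whose depth scales linearly with
  intensity above a 45 dB anchor,
* a positive rebound following each burst,
* an optional large positive onset transient on the first burst of each
  trial ("increase"-phenotype subjects), habituating across trials,
* slow sinusoidal drift plus i.i.d. Gaussian sensor noise.

All kernels are difference-of-exponential (alpha-like) shapes normalised to
unit peak, so the extremum of a noiseless response has a closed form that
tests can check independently. For ramped/damped burst envelopes the dip
kernel is driven by the envelope itself so that ramped responses peak later
than damped ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "StimulusSchedule",
    "ResponseKernelParams",
    "SubjectParams",
    "CohortConfig",
    "make_schedule",
    "burst_envelope",
    "simulate_subject",
    "simulate_cohort",
    "simulate_pupil",
    "pupil_gain_for_mean",
    "alpha_peak_time",
    "alpha_kernel",
    "default_kernel",
    "DEFAULT_INTENSITIES",
    "DEFAULT_ISI_CHOICES",
    "DB_ANCHOR",
    "TRIAL_DURATION",
]

TRIAL_DURATION = 10.0
DEFAULT_INTENSITIES = (45.0, 65.0, 85.0, 105.0)
DEFAULT_ISI_CHOICES = (25.0, 30.0, 35.0)
#: Lowest tested level; kernel amplitudes scale with (dB - DB_ANCHOR).
DB_ANCHOR = 45.0
#: Lead-in before the first trial so a 5-s baseline always exists.
SCHEDULE_LEAD_IN = 20.0

_ENVELOPE_KINDS = ("flat", "ramped", "damped")

# (rise, fall) seconds for each envelope kind, 500-ms bursts
_ENVELOPE_DEFAULTS = {
    "flat": (0.005, 0.005),
    "ramped": (0.495, 0.005),
    "damped": (0.005, 0.495),
}


@dataclass(frozen=True)
class StimulusSchedule:
    """Trial onsets, per-trial intensities and within-trial burst layout."""

    trial_onsets: np.ndarray
    trial_intensity: np.ndarray
    bursts_per_trial: int = 10
    burst_period: float = 1.0
    burst_duration: float = 0.5
    envelope: str = "flat"
    rise_time: float = 0.005
    fall_time: float = 0.005

    def __post_init__(self) -> None:
        onsets = np.asarray(self.trial_onsets, dtype=float)
        intens = np.asarray(self.trial_intensity, dtype=float)
        object.__setattr__(self, "trial_onsets", onsets)
        object.__setattr__(self, "trial_intensity", intens)
        if onsets.ndim != 1 or intens.shape != onsets.shape:
            raise ValueError("trial_onsets and trial_intensity must be 1-D and equal length")
        if onsets.size == 0:
            raise ValueError("schedule must contain at least one trial")
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("trial_onsets must be strictly increasing")
        if self.envelope not in _ENVELOPE_KINDS:
            raise ValueError(f"unknown envelope kind {self.envelope!r}")
        if self.rise_time + self.fall_time > self.burst_duration + 1e-12:
            raise ValueError("rise_time + fall_time must not exceed burst_duration")
        if self.bursts_per_trial < 1 or self.burst_period <= 0:
            raise ValueError("bursts_per_trial must be >= 1 and burst_period > 0")

    @property
    def n_trials(self) -> int:
        return int(self.trial_onsets.size)

    @property
    def trial_duration(self) -> float:
        return self.bursts_per_trial * self.burst_period

    def burst_onsets(self, trial: int) -> np.ndarray:
        """Absolute onset times of the bursts of one trial."""
        base = float(self.trial_onsets[trial])
        return base + np.arange(self.bursts_per_trial) * self.burst_period

    def relative_burst_onsets(self) -> np.ndarray:
        """Burst onsets relative to trial onset (same for every trial)."""
        return np.arange(self.bursts_per_trial) * self.burst_period

    @property
    def end_time(self) -> float:
        return float(self.trial_onsets[-1]) + self.trial_duration


@dataclass(frozen=True)
class ResponseKernelParams:
    """Population-level response kernel parameters."""

    dip_slope: float = -0.020  # z-units per dB above the 45 dB anchor
    dip_latency: float = 0.03
    dip_rise_tau: float = 0.05
    dip_decay_tau: float = 0.20
    rebound_amplitude: float = 0.3
    rebound_delay: float = 0.55
    onset_transient_amplitude: float = 3.6  # first burst of each trial only
    onset_transient_tau: float = 0.15
    habituation_factor: float = 1.0  # per-trial multiplier on the transient

    def __post_init__(self) -> None:
        for name in ("dip_rise_tau", "dip_decay_tau", "onset_transient_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.habituation_factor <= 1.0:
            raise ValueError("habituation_factor must lie in [0, 1]")
        if self.dip_latency < 0 or self.rebound_delay < 0:
            raise ValueError("latencies must be >= 0")


def default_kernel(**overrides) -> ResponseKernelParams:
    """Kernel defaults used throughout the test-bench simulations."""
    return replace(ResponseKernelParams(), **overrides)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject parameters.

    ``noise_sd`` is the white sensor-noise level in z units. When it is
    positive, a slow band-limited fluctuation (cutoff ``slow_cutoff_hz``)
    is added with complementary variance so the 5-s pre-trial baseline has
    unit standard deviation — this is what defines the z unit, so kernel
    amplitudes configured in z survive the pipeline's baseline z-scoring.
    With ``noise_sd = 0`` the trace is fully deterministic.
    """

    subject_id: str
    phenotype: str = "decrease"  # "increase" or "decrease"
    slope_deviation: float = 0.0  # z per dB, added to the population dip_slope
    noise_sd: float = 0.2
    drift_amplitude: float = 0.15
    drift_period: float = 90.0
    slow_cutoff_hz: float = 2.5

    def __post_init__(self) -> None:
        if self.phenotype not in ("increase", "decrease"):
            raise ValueError("phenotype must be 'increase' or 'decrease'")
        if not 0.0 <= self.noise_sd <= 1.0:
            raise ValueError("noise_sd must lie in [0, 1] (z units)")
        if self.drift_period <= 0 or self.slow_cutoff_hz <= 0:
            raise ValueError("drift_period and slow_cutoff_hz must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 9
    p_increase: float = 0.0
    kernel: ResponseKernelParams = field(default_factory=ResponseKernelParams)
    between_subject_slope_sd: float = 0.003
    sample_rate: float = 120.0
    seed: int = 0
    noise_sd: float = 0.2
    drift_amplitude: float = 0.15
    drift_period: float = 90.0
    slow_cutoff_hz: float = 2.5

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.p_increase <= 1.0:
            raise ValueError("p_increase must lie in [0, 1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


# ---------------------------------------------------------------------------
# Schedules and envelopes
# ---------------------------------------------------------------------------

def make_schedule(
    intensities: Sequence[float],
    envelope: str = "flat",
    isi_choices: Sequence[float] = DEFAULT_ISI_CHOICES,
    seed: int = 0,
    bursts_per_trial: int = 10,
    burst_period: float = 1.0,
    burst_duration: float = 0.5,
    lead_in: float = SCHEDULE_LEAD_IN,
) -> StimulusSchedule:
    """Build a trial schedule, one trial per requested intensity, in order.

    Inter-trial gaps are i.i.d. draws from ``isi_choices`` (seconds of
    silence between trial end and the next trial onset).
    """
    intensities = list(intensities)
    if len(intensities) == 0:
        raise ValueError("intensities must be non-empty")
    isi_choices = np.asarray(list(isi_choices), dtype=float)
    if isi_choices.size == 0 or np.any(isi_choices <= 0):
        raise ValueError("isi_choices must be non-empty and positive")
    if envelope not in _ENVELOPE_KINDS:
        raise ValueError(f"unknown envelope kind {envelope!r}")

    rng = np.random.default_rng(seed)
    trial_len = bursts_per_trial * burst_period
    onsets = np.empty(len(intensities))
    t = float(lead_in)
    for i in range(len(intensities)):
        onsets[i] = t
        gap = float(rng.choice(isi_choices))
        t += trial_len + gap
    rise, fall = _ENVELOPE_DEFAULTS[envelope]
    return StimulusSchedule(
        trial_onsets=onsets,
        trial_intensity=np.asarray(intensities, dtype=float),
        bursts_per_trial=bursts_per_trial,
        burst_period=burst_period,
        burst_duration=burst_duration,
        envelope=envelope,
        rise_time=rise,
        fall_time=fall,
    )


def burst_envelope(
    kind: str,
    duration: float = 0.5,
    rise: float | None = None,
    fall: float | None = None,
    rate: float = 120.0,
) -> np.ndarray:
    """Piecewise-linear intensity envelope sampled at ``rate``.

    0 -> 1 over ``rise`` seconds, flat at 1, then 1 -> 0 over ``fall``
    seconds; length is ``round(duration * rate)`` samples at times i/rate.
    """
    if kind not in _ENVELOPE_KINDS:
        raise ValueError(f"unknown envelope kind {kind!r}")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if rise is None or fall is None:
        d_rise, d_fall = _ENVELOPE_DEFAULTS[kind]
        rise = d_rise if rise is None else rise
        fall = d_fall if fall is None else fall
    if rise < 0 or fall < 0:
        raise ValueError("rise and fall must be >= 0")
    if rise + fall > duration + 1e-12:
        raise ValueError("rise + fall must not exceed duration")

    n = int(round(duration * rate))
    t = np.arange(n) / rate
    env = np.ones(n)
    if rise > 0:
        m = t < rise
        env[m] = t[m] / rise
    if fall > 0:
        m = t > duration - fall
        env[m] = np.minimum(env[m], (duration - t[m]) / fall)
    return np.clip(env, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Response kernels
# ---------------------------------------------------------------------------

def alpha_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time of the extremum of exp(-t/decay) - exp(-t/rise)."""
    if rise_tau == decay_tau:
        return rise_tau  # limit of the difference form (t * exp(-t/tau))
    return (rise_tau * decay_tau / (decay_tau - rise_tau)) * math.log(decay_tau / rise_tau)


def alpha_kernel(rate: float, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalised to unit peak.

    Support is truncated where the decaying tail drops below 1e-5 of the
    peak, so additions at 1-s burst spacing carry negligible wrap-around.
    """
    tpk = alpha_peak_time(rise_tau, decay_tau)
    t_end = tpk + decay_tau * math.log(1e5)
    t = np.arange(int(round(t_end * rate)) + 1) / rate
    if rise_tau == decay_tau:
        k = t * np.exp(-t / decay_tau)
        peak = tpk * math.exp(-1.0)
    else:
        k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
        peak = math.exp(-tpk / decay_tau) - math.exp(-tpk / rise_tau)
    return k / peak


def _dip_kernel(kernel: ResponseKernelParams, schedule: StimulusSchedule, rate: float) -> np.ndarray:
    """Unit-peak dip kernel; envelope-driven for ramped/damped schedules."""
    base = alpha_kernel(rate, kernel.dip_rise_tau, kernel.dip_decay_tau)
    if schedule.envelope == "flat":
        return base
    env = burst_envelope(
        schedule.envelope,
        schedule.burst_duration,
        schedule.rise_time,
        schedule.fall_time,
        rate,
    )
    drive = env / env.sum()
    k = np.convolve(base, drive)
    return k / np.max(np.abs(k))


def _add_at(trace: np.ndarray, start: int, kern: np.ndarray) -> None:
    stop = min(start + kern.size, trace.size)
    if stop > start >= 0:
        trace[start:stop] += kern[: stop - start]


# ---------------------------------------------------------------------------
# Trace simulation
# ---------------------------------------------------------------------------

def simulate_subject(
    subject: SubjectParams,
    kernel: ResponseKernelParams,
    schedule: StimulusSchedule,
    rate: float = 120.0,
    seed: int = 0,
    tail: float = 15.0,
):
    """Simulate one subject's recording over the full schedule.

    Returns a :class:`photodyn.preprocess.RawTrace` starting at t = 0.
    """
    from .preprocess import RawTrace  # local import to avoid a cycle

    if rate <= 0:
        raise ValueError("rate must be > 0")
    duration = schedule.end_time + tail
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    trace = subject.drift_amplitude * np.sin(2.0 * np.pi * t / subject.drift_period)

    slope = kernel.dip_slope + subject.slope_deviation
    dip = _dip_kernel(kernel, schedule, rate)
    reb = alpha_kernel(rate, kernel.dip_rise_tau, kernel.dip_decay_tau)
    trans = alpha_kernel(rate, kernel.onset_transient_tau / 5.0, kernel.onset_transient_tau)

    dip_off = int(round(kernel.dip_latency * rate))
    reb_off = int(round(kernel.rebound_delay * rate))

    for j in range(schedule.n_trials):
        amp = slope * (schedule.trial_intensity[j] - DB_ANCHOR)
        for onset in schedule.burst_onsets(j):
            i0 = int(round(onset * rate))
            if amp != 0.0:
                _add_at(trace, i0 + dip_off, amp * dip)
            if kernel.rebound_amplitude != 0.0:
                _add_at(trace, i0 + reb_off, kernel.rebound_amplitude * reb)
        if subject.phenotype == "increase" and kernel.onset_transient_amplitude != 0.0:
            a = kernel.onset_transient_amplitude * kernel.habituation_factor**j
            if a != 0.0:
                i0 = int(round(schedule.trial_onsets[j] * rate))
                _add_at(trace, i0, a * trans)

    if subject.noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, subject.noise_sd, n)
        slow_sd = math.sqrt(max(0.0, 1.0 - subject.noise_sd**2))
        if slow_sd > 0:
            trace = trace + _slow_fluctuation(rng, n, rate, subject.slow_cutoff_hz, slow_sd)
    return RawTrace(values=trace, rate=rate, t0=0.0)


def _slow_fluctuation(
    rng: np.random.Generator, n: int, rate: float, cutoff_hz: float, sd: float
) -> np.ndarray:
    """Band-limited Gaussian baseline fluctuation rescaled to ``sd``."""
    from scipy import signal

    w = rng.normal(0.0, 1.0, n)
    wn = min(cutoff_hz / (rate / 2.0), 0.99)
    sos = signal.butter(4, wn, btype="low", output="sos")
    slow = signal.sosfiltfilt(sos, w)
    s = slow.std()
    if s == 0:
        return np.zeros(n)
    return slow * (sd / s)


def simulate_cohort(config: CohortConfig, schedule: StimulusSchedule):
    """Simulate ``config.n_subjects`` subjects; returns [(params, trace), ...].

    Phenotypes are Bernoulli(p_increase) and slope deviations are
    Normal(0, between_subject_slope_sd^2), all reproducible from the seed.
    """
    ss = np.random.SeedSequence(config.seed)
    assign_seed, *trace_seeds = ss.spawn(config.n_subjects + 1)
    rng = np.random.default_rng(assign_seed)
    phenotypes = np.where(rng.random(config.n_subjects) < config.p_increase, "increase", "decrease")
    devs = (
        rng.normal(0.0, config.between_subject_slope_sd, config.n_subjects)
        if config.between_subject_slope_sd > 0
        else np.zeros(config.n_subjects)
    )
    out = []
    for i in range(config.n_subjects):
        params = SubjectParams(
            subject_id=f"s{i:02d}",
            phenotype=str(phenotypes[i]),
            slope_deviation=float(devs[i]),
            noise_sd=config.noise_sd,
            drift_amplitude=config.drift_amplitude,
            drift_period=config.drift_period,
            slow_cutoff_hz=config.slow_cutoff_hz,
        )
        trace = simulate_subject(params, config.kernel, schedule, config.sample_rate, trace_seeds[i])
        out.append((params, trace))
    return out


# ---------------------------------------------------------------------------
# Pupil
# ---------------------------------------------------------------------------

#: dB level at which the simulated pupil response vanishes. Chosen so the
#: noiseless 45:105 dB response ratio matches a ~0.36 ratio of means.
PUPIL_DB_ANCHOR = 10.0
_PUPIL_TAU_ON = 2.0
_PUPIL_TAU_OFF = 3.0


def _pupil_kernel(rate: float, stimulus_dur: float) -> np.ndarray:
    n_on = int(round(stimulus_dur * rate))
    t_on = np.arange(n_on) / rate
    on = 1.0 - np.exp(-t_on / _PUPIL_TAU_ON)
    n_off = int(round(5.0 * _PUPIL_TAU_OFF * rate))
    t_off = (np.arange(n_off) + 1) / rate
    off = on[-1] * np.exp(-t_off / _PUPIL_TAU_OFF)
    return np.concatenate([on, off])


def pupil_kernel_mean(stimulus_dur: float = 10.0) -> float:
    """Closed-form mean of the dilation kernel over the stimulus window."""
    tau = _PUPIL_TAU_ON
    return 1.0 - tau * (1.0 - math.exp(-stimulus_dur / tau)) / stimulus_dur


def pupil_gain_for_mean(target_mean: float, intensity: float, stimulus_dur: float = 10.0) -> float:
    """Gain giving a noiseless mean response of ``target_mean`` at ``intensity``."""
    return target_mean / ((intensity - PUPIL_DB_ANCHOR) * pupil_kernel_mean(stimulus_dur))


def simulate_pupil(
    onsets: Sequence[float],
    intensities: Sequence[float],
    rate: float = 30.0,
    gain: float = 0.005,
    seed: int = 0,
    noise_sd: float = 0.0,
    stimulus_dur: float = 10.0,
    baseline_level: float = 0.0,
    tail: float = 15.0,
):
    """Simulate a pupil-area-like series with intensity-scaled dilations."""
    from .behavior import PupilSeries

    onsets = np.asarray(list(onsets), dtype=float)
    intensities = np.asarray(list(intensities), dtype=float)
    if onsets.shape != intensities.shape:
        raise ValueError("onsets and intensities must have equal length")
    n = int(round((onsets.max(initial=0.0) + stimulus_dur + tail) * rate))
    series = np.full(n, baseline_level)
    kern = _pupil_kernel(rate, stimulus_dur)
    for onset, db in zip(onsets, intensities):
        _add_at(series, int(round(onset * rate)), gain * (db - PUPIL_DB_ANCHOR) * kern)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        series = series + rng.normal(0.0, noise_sd, n)
    return PupilSeries(area=series, rate=rate, onsets=onsets, stimulus_dur=stimulus_dur)
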