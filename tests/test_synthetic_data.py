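import math

import numpy as np
import pytest

from photodyn.behavior import pupil_response
from photodyn.synthetic_data import (
    CohortConfig,
    SubjectParams,
    alpha_peak_time,
    burst_envelope,
    default_kernel,
    make_schedule,
    pupil_gain_for_mean,
    simulate_cohort,
    simulate_pupil,
    simulate_subject,
)


class TestMakeSchedule:
    def test_four_trials_burst_onsets(self):
        s = make_schedule([45, 65, 85, 105], seed=0)
        assert s.n_trials == 4
        for j in range(4):
            rel = s.burst_onsets(j) - s.trial_onsets[j]
            np.testing.assert_allclose(rel, np.arange(10.0))

    def test_empty_intensities_rejected(self):
        with pytest.raises(ValueError):
            make_schedule([])

    def test_nonpositive_isi_rejected(self):
        with pytest.raises(ValueError):
            make_schedule([85], isi_choices=[0.0, 30.0])

    def test_gaps_drawn_from_choices_and_deterministic(self):
        a = make_schedule([45] * 20, isi_choices=[25, 30, 35], seed=7)
        b = make_schedule([45] * 20, isi_choices=[25, 30, 35], seed=7)
        np.testing.assert_array_equal(a.trial_onsets, b.trial_onsets)
        gaps = np.diff(a.trial_onsets) - a.trial_duration
        assert set(np.round(gaps, 9)) <= {25.0, 30.0, 35.0}
        c = make_schedule([45] * 20, isi_choices=[25, 30, 35], seed=8)
        assert not np.array_equal(a.trial_onsets, c.trial_onsets)

    def test_fixed_intensity_order_preserved(self):
        levels = [db for db in (45, 65, 85, 105) for _ in range(10)]
        s = make_schedule(levels, seed=3)
        np.testing.assert_array_equal(s.trial_intensity, np.asarray(levels, float))
        assert np.all(np.diff(s.trial_onsets) >= s.trial_duration + 25.0)


class TestBurstEnvelope:
    def test_ramped_peaks_at_rise_end(self):
        rate = 1000.0
        env = burst_envelope("ramped", 0.5, 0.495, 0.005, rate)
        t = np.arange(env.size) / rate
        assert env[np.argmin(np.abs(t - 0.495))] == pytest.approx(1.0)
        assert env.max() <= 1.0 and env.min() >= 0.0

    def test_flat_zero_ramp_is_constant_one(self):
        env = burst_envelope("flat", 0.5, 0.0, 0.0, 120.0)
        np.testing.assert_array_equal(env, np.ones(60))

    def test_ramped_integral_quarter_second(self):
        rate = 2000.0
        env = burst_envelope("ramped", 0.5, 0.495, 0.005, rate)
        area = np.trapezoid(env, dx=1.0 / rate)
        assert area == pytest.approx(0.250, abs=1.5 / rate)

    def test_flat_envelope_mass(self):
        # trapezoid with 5 ms linear edges: area = dur - (rise+fall)/2
        rate = 2000.0
        env = burst_envelope("flat", 0.5, 0.005, 0.005, rate)
        area = np.trapezoid(env, dx=1.0 / rate)
        assert area == pytest.approx(0.5 - 0.005, abs=1.5 / rate)

    def test_rise_fall_overrun_rejected(self):
        with pytest.raises(ValueError):
            burst_envelope("ramped", 0.4, 0.3, 0.2, 120.0)

    def test_length(self):
        assert burst_envelope("damped", 0.5, rate=120.0).size == 60


def _noiseless_subject(**kw):
    defaults = dict(
        subject_id="s00",
        phenotype="decrease",
        noise_sd=0.0,
        drift_amplitude=0.0,
    )
    defaults.update(kw)
    return SubjectParams(**defaults)


class TestSimulateSubject:
    def test_null_kernel_gives_drift_exactly(self):
        subject = _noiseless_subject(drift_amplitude=0.2, drift_period=60.0)
        kernel = default_kernel(
            dip_slope=0.0, rebound_amplitude=0.0, onset_transient_amplitude=0.0
        )
        schedule = make_schedule([45, 105], seed=0)
        trace = simulate_subject(subject, kernel, schedule, rate=120.0, seed=0)
        t = np.arange(trace.n) / 120.0
        np.testing.assert_allclose(
            trace.values, 0.2 * np.sin(2 * np.pi * t / 60.0), atol=1e-12
        )

    def test_dip_minimum_matches_closed_form_single_burst(self):
        # single burst so no tail overlap; oracle evaluates the
        # difference-of-exponentials on the sample grid independently
        rate = 120.0
        kernel = default_kernel(rebound_amplitude=0.0, onset_transient_amplitude=0.0)
        schedule = make_schedule([105], seed=0, bursts_per_trial=1)
        trace = simulate_subject(_noiseless_subject(), kernel, schedule, rate, seed=0)

        amp = kernel.dip_slope * (105.0 - 45.0)  # -1.2 z
        tpk = alpha_peak_time(kernel.dip_rise_tau, kernel.dip_decay_tau)
        peak = math.exp(-tpk / kernel.dip_decay_tau) - math.exp(-tpk / kernel.dip_rise_tau)
        i0 = int(round(schedule.trial_onsets[0] * rate)) + int(
            round(kernel.dip_latency * rate)
        )
        t_grid = np.arange(600) / rate
        oracle = amp * (
            np.exp(-t_grid / kernel.dip_decay_tau) - np.exp(-t_grid / kernel.dip_rise_tau)
        ) / peak
        assert trace.values.min() == pytest.approx(oracle.min(), abs=1e-12)
        assert np.argmin(trace.values) == i0 + np.argmin(oracle)

    def test_trial_average_minimum_close_to_closed_form_ten_bursts(self):
        rate = 120.0
        kernel = default_kernel(rebound_amplitude=0.0, onset_transient_amplitude=0.0)
        schedule = make_schedule([105], seed=0)
        trace = simulate_subject(_noiseless_subject(), kernel, schedule, rate, seed=0)
        i0 = int(round(schedule.trial_onsets[0] * rate))
        segs = trace.values[i0 : i0 + 1200].reshape(10, 120)
        amp = kernel.dip_slope * 60.0
        # inter-burst tails perturb the minimum by < 2.5%
        assert segs.mean(axis=0).min() == pytest.approx(amp, rel=0.025)

    def test_increase_type_transient_and_habituation_zero(self):
        rate = 120.0
        kernel = default_kernel(
            dip_slope=0.0,
            rebound_amplitude=0.0,
            onset_transient_amplitude=3.6,
            habituation_factor=0.0,
        )
        schedule = make_schedule([105, 105], seed=0)
        subject = _noiseless_subject(phenotype="increase")
        trace = simulate_subject(subject, kernel, schedule, rate, seed=0)
        i0 = int(round(schedule.trial_onsets[0] * rate))
        i1 = int(round(schedule.trial_onsets[1] * rate))
        burst1 = trace.values[i0 : i0 + 120]
        burst2 = trace.values[i0 + 120 : i0 + 240]
        trial2 = trace.values[i1 : i1 + 1200]
        assert burst1.max() == pytest.approx(3.6, rel=0.01)
        # P2/P1 ~ 0: no transient on burst 2 and none on trial 2
        assert abs(burst2).max() < 0.05
        assert abs(trial2).max() < 1e-9

    def test_deterministic_given_seed(self):
        schedule = make_schedule([65], seed=0)
        subject = SubjectParams(subject_id="s", noise_sd=0.3)
        kernel = default_kernel()
        a = simulate_subject(subject, kernel, schedule, 120.0, seed=11)
        b = simulate_subject(subject, kernel, schedule, 120.0, seed=11)
        c = simulate_subject(subject, kernel, schedule, 120.0, seed=12)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_ramped_dip_later_than_damped(self):
        kernel = default_kernel(rebound_amplitude=0.0, onset_transient_amplitude=0.0)
        latencies = {}
        for env in ("ramped", "damped"):
            schedule = make_schedule([85], seed=0, envelope=env)
            trace = simulate_subject(_noiseless_subject(), kernel, schedule, 120.0, 0)
            i0 = int(round(schedule.trial_onsets[0] * 120.0))
            latencies[env] = np.argmin(trace.values[i0 : i0 + 120]) / 120.0
        assert latencies["ramped"] > latencies["damped"]


class TestSimulateCohort:
    def test_all_decrease_when_p_zero(self):
        cfg = CohortConfig(n_subjects=9, p_increase=0.0, seed=5)
        schedule = make_schedule([45, 105], seed=0)
        cohort = simulate_cohort(cfg, schedule)
        assert len(cohort) == 9
        assert all(p.phenotype == "decrease" for p, _ in cohort)

    def test_no_heterogeneity_identical_traces(self):
        cfg = CohortConfig(
            n_subjects=3, between_subject_slope_sd=0.0, noise_sd=0.0,
            drift_amplitude=0.0, seed=5,
        )
        schedule = make_schedule([85], seed=0)
        cohort = simulate_cohort(cfg, schedule)
        ref = cohort[0][1].values
        for _, trace in cohort[1:]:
            np.testing.assert_array_equal(trace.values, ref)

    def test_seed_reproducibility(self):
        schedule = make_schedule([85], seed=0)
        a = simulate_cohort(CohortConfig(n_subjects=2, seed=9), schedule)
        b = simulate_cohort(CohortConfig(n_subjects=2, seed=9), schedule)
        c = simulate_cohort(CohortConfig(n_subjects=2, seed=10), schedule)
        for (pa, ta), (pb, tb) in zip(a, b):
            assert pa == pb
            np.testing.assert_array_equal(ta.values, tb.values)
        assert not np.array_equal(a[0][1].values, c[0][1].values)

    def test_ground_truth_returned(self):
        cfg = CohortConfig(n_subjects=4, p_increase=1.0, seed=2)
        cohort = simulate_cohort(cfg, make_schedule([85], seed=0))
        assert all(p.phenotype == "increase" for p, _ in cohort)


class TestSimulatePupil:
    def test_zero_gain_flat(self):
        series = simulate_pupil([20.0], [105.0], gain=0.0, baseline_level=5.0)
        np.testing.assert_array_equal(series.area, np.full(series.area.size, 5.0))

    def test_calibrated_mean_recovered(self):
        gain = pupil_gain_for_mean(0.33, 105.0)
        series = simulate_pupil([20.0], [105.0], gain=gain)
        resp = pupil_response(series, normalize=False)
        assert resp[0] == pytest.approx(0.33, abs=2e-3)

    def test_intensity_ordering(self):
        series = simulate_pupil([20.0, 60.0], [45.0, 105.0], gain=0.005)
        lo, hi = pupil_response(series, normalize=False)
        assert hi > lo


class TestClusteringProperty:
    def test_slope_variance_decomposes(self):
        # var(estimated subject slopes) ~ between-subject variance +
        # sampling variance (estimated from a no-heterogeneity run)
        from photodyn.inference import per_subject_slopes
        from photodyn.metrics import summaries_to_table
        from photodyn.pipeline import RunConfig, _schedule_for, _subject_summaries

        def slopes(between_sd, n_cohorts, seed0):
            out = []
            for s in range(n_cohorts):
                cfg = RunConfig(
                    seed=seed0 + s, n_subjects=2, trials_per_intensity=3,
                    between_subject_slope_sd=between_sd, noise_sd=0.3,
                )
                sch = _schedule_for(cfg)
                cohort = simulate_cohort(cfg.cohort_config(), sch)
                summ = _subject_summaries(cfg, sch, cohort)
                tbl = summaries_to_table(summ)
                sub = tbl[(tbl.response_type == "average") & (tbl.measure == "min")]
                out.extend(per_subject_slopes(sub)["beta"].tolist())
            return np.asarray(out)

        base = slopes(0.0, 100, 10_000)
        hetero = slopes(0.006, 100, 20_000)
        sampling_var = base.var(ddof=1)
        total_var = hetero.var(ddof=1)
        expected = 0.006**2 + sampling_var
        assert total_var == pytest.approx(expected, rel=0.35)
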