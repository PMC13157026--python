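"""Self-validation harness: end-to-end property checks on synthetic data.

Each function recomputes one quantitative property of the toolchain from
scratch — simulating inputs, running the production code path, and measuring
the result — and returns plain numbers. They back both the acceptance test
suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import inference, metrics
from .pipeline import RunConfig, _schedule_for, _subject_summaries, run_ramp_damp_experiment
from .preprocess import RawTrace, zscore_by_trial
from .synthetic_data import default_kernel, simulate_cohort

__all__ = [
    "sim_long_table",
    "sandwich_vs_loop_oracle",
    "bootstrap_null_pvalues",
    "ci_coverage",
    "slope_recovery",
    "classifier_accuracy",
    "zscore_baseline_deviation",
    "printed_paired_t_pvalue",
    "ramp_damp_ordering",
]


def sim_long_table(
    rng: np.random.Generator,
    n_clusters: int = 9,
    slope: float = 0.0,
    icept_sd: float = 0.5,
    noise_sd: float = 0.3,
    intensities=(45.0, 65.0, 85.0, 105.0),
) -> pd.DataFrame:
    """Clustered regression data with subject random intercepts."""
    x = np.tile(np.asarray(intensities, dtype=float), n_clusters)
    g = np.repeat(np.arange(n_clusters), len(intensities))
    y = rng.normal(0.0, icept_sd, n_clusters)[g] + slope * x + rng.normal(
        0.0, noise_sd, x.size
    )
    return pd.DataFrame(
        dict(subject_id=[f"s{i:03d}" for i in g], intensity=x, value=y)
    )


def _loop_sandwich(data: pd.DataFrame) -> tuple[float, float]:
    """Explicit-loop CR1 cluster sandwich (reference implementation)."""
    X = np.column_stack([np.ones(len(data)), data["intensity"].to_numpy(float)])
    y = data["value"].to_numpy(float)
    A = np.linalg.inv(X.T @ X)
    coef = A @ (X.T @ y)
    meat = np.zeros((2, 2))
    for _, grp in data.groupby("subject_id"):
        score = np.zeros(2)
        for _, row in grp.iterrows():
            xi = np.array([1.0, row["intensity"]])
            score += xi * (row["value"] - xi @ coef)
        meat += np.outer(score, score)
    G = data["subject_id"].nunique()
    N = len(data)
    c = (G / (G - 1.0)) * ((N - 1.0) / (N - 2.0))
    V = c * (A @ meat @ A)
    return float(coef[1]), math.sqrt(V[1, 1])


def sandwich_vs_loop_oracle(seed: int, n_instances: int = 100) -> float:
    """Max |difference| between the production cluster SE and an explicit
    per-cluster loop, over random small instances (<=6 clusters, <=5 points
    per cluster)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        G = int(rng.integers(3, 7))
        rows = []
        for g in range(G):
            n_pts = int(rng.integers(2, 6))
            x = rng.choice([45.0, 65.0, 85.0, 105.0], size=n_pts)
            while np.unique(np.concatenate([x, [45.0, 105.0]])).size < 2:
                x = rng.choice([45.0, 65.0, 85.0, 105.0], size=n_pts)
            a = rng.normal(0, 0.5)
            for xi in x:
                rows.append((f"s{g}", xi, a - 0.02 * xi + rng.normal(0, 0.3)))
        data = pd.DataFrame(rows, columns=["subject_id", "intensity", "value"])
        fit = inference.fit_cluster_ols(data)
        beta_ref, se_ref = _loop_sandwich(data)
        worst = max(worst, abs(fit.beta - beta_ref), abs(fit.cr_se - se_ref))
    return worst


def bootstrap_null_pvalues(
    seed: int, n_sims: int = 1000, B: int = 399, n_clusters: int = 9
) -> np.ndarray:
    """Wild cluster bootstrap p-values under a true null (slope = 0)."""
    rng = np.random.default_rng(seed)
    ps = np.empty(n_sims)
    for i in range(n_sims):
        data = sim_long_table(rng, n_clusters=n_clusters, slope=0.0)
        ps[i] = inference.wild_cluster_boot_p(
            data, 0.0, B=B, seed=int(rng.integers(2**31))
        )
    return ps


def ci_coverage(
    seed: int, n_sims: int = 500, B: int = 399, slope: float = -0.020
) -> float:
    """Fraction of 95% test-inversion CIs covering the true slope.

    Membership in the inversion CI is evaluated directly as
    p(beta0 = truth) >= alpha with the same common-random-number weights the
    endpoint search uses, which is the defining property of the interval.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        data = sim_long_table(rng, slope=slope)
        hits += inference.ci_contains(
            data, slope, level=0.95, B=B, seed=int(rng.integers(2**31))
        )
    return hits / n_sims


def slope_recovery(seed: int, n_cohorts: int = 200) -> float:
    """Mean pooled average-min slope over full-pipeline decrease cohorts.

    Generator truth is the default dip slope (-0.020 z/dB); each cohort is
    simulated, z-scored, summarised and fit with the cluster OLS estimator.
    """
    betas = np.empty(n_cohorts)
    for i in range(n_cohorts):
        cfg = RunConfig(seed=seed * 1_000_003 + i, n_subjects=9, p_increase=0.0)
        schedule = _schedule_for(cfg)
        cohort = simulate_cohort(cfg.cohort_config(), schedule)
        summaries = _subject_summaries(cfg, schedule, cohort)
        table = metrics.summaries_to_table(summaries)
        sub = table[(table.response_type == "average") & (table.measure == "min")]
        betas[i] = inference.fit_cluster_ols(sub).beta
    return float(betas.mean())


def classifier_accuracy(seed: int, n_cohorts: int = 200, n_subjects: int = 6) -> float:
    """Phenotype classification accuracy on mixed cohorts (transient 3.6 z,
    white-noise level 0.3)."""
    kernel = default_kernel(onset_transient_amplitude=3.6)
    correct = total = 0
    for i in range(n_cohorts):
        cfg = RunConfig(
            seed=seed * 2_000_003 + i,
            n_subjects=n_subjects,
            p_increase=0.5,
            noise_sd=0.3,
            kernel=kernel,
        )
        schedule = _schedule_for(cfg)
        cohort = simulate_cohort(cfg.cohort_config(), schedule)
        summaries = _subject_summaries(cfg, schedule, cohort)
        for (params, _), s in zip(cohort, summaries):
            correct += params.phenotype == s.phenotype
            total += 1
    return correct / total


def zscore_baseline_deviation(seed: int, n_traces: int = 20) -> tuple[float, float]:
    """(max |baseline mean|, max |baseline sd - 1|) after trial z-scoring."""
    rng = np.random.default_rng(seed)
    worst_mean = worst_sd = 0.0
    for _ in range(n_traces):
        raw = RawTrace(values=rng.normal(2.0, 0.7, 12000), rate=120.0)
        aligned = zscore_by_trial(raw, [20.0, 55.0, 90.0], segment=(5.0, 10.0))
        base = aligned.z[:, aligned.rel_time < 0]
        worst_mean = max(worst_mean, np.abs(base.mean(axis=1)).max())
        worst_sd = max(worst_sd, np.abs(base.std(axis=1, ddof=1) - 1.0).max())
    return worst_mean, worst_sd


def printed_paired_t_pvalue() -> float:
    """Two-sided p recomputed from t = -4.40 with df = 9."""
    from scipy import stats

    return float(2.0 * stats.t.sf(4.40, 9))


def ramp_damp_ordering(seed: int, n_runs: int = 100, n_subjects: int = 8):
    """(noiseless per-subject ordering fraction, noisy per-run fraction,
    noisy significant-paired-t fraction) for ramped > damped neg-peak
    latency."""
    cfg0 = RunConfig(
        seed=seed, n_subjects=n_subjects, noise_sd=0.0,
        between_subject_slope_sd=0.002, trials_per_intensity=10,
    )
    bundle = run_ramp_damp_experiment(cfg0)
    pe = bundle["per_envelope"].pivot(
        index="subject_id", columns="envelope", values="neg_latency"
    )
    noiseless_frac = float((pe["ramped"] > pe["damped"]).mean())

    ordered = significant = 0
    for i in range(n_runs):
        cfg = RunConfig(seed=seed * 3_000_017 + i, n_subjects=n_subjects,
                        trials_per_intensity=10)
        bundle = run_ramp_damp_experiment(cfg)
        res = bundle["tests"]["neg_latency"]
        ordered += res.t > 0
        significant += res.t > 0 and res.p < 0.05
    return noiseless_frac, ordered / n_runs, significant / n_runs
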