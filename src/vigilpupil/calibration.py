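"""Statistical calibration utilities: type-I error, coverage, recovery.

These routines exercise the inference machinery under known truth — null
cohorts for the cluster permutation test's family-wise error, Gaussian
cohorts for bootstrap CI coverage, and simulated observer cohorts (with or
without injected time-on-task decay of the evoked pupil amplitude) for
end-to-end parameter recovery.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal

from . import groupstats
from .clusterstats import permutation_test
from .pipeline import RunConfig, run_experiment1

__all__ = [
    "smoothed_null_traces",
    "cluster_test_fwer",
    "bootstrap_coverage",
    "recovery_cohorts",
    "scaled_exp1_config",
    "simulate_block_durations",
]


def simulate_block_durations(
    n_blocks: int = 1000,
    trials_per_block: int = 90,
    rt_nonlapse_ms: float = 420.0,
    rt_lapse_ms: float = 960.0,
    lapse_prob: float = 27.6 / 270.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulated PVT block durations in minutes.

    Each block sums 90 draws of (ISI + RT): the ISI comes from the
    tertile-balanced schedule generator (2 s fixed + 2-10 s random) and the
    RT is the two-point lapse mixture (response-initiated ISIs make the
    block length the plain sum of the per-trial times).
    """
    from .schedule import generate_pvt_schedule

    rng = np.random.default_rng(seed)
    durations = np.empty(n_blocks)
    for b in range(n_blocks):
        sched = generate_pvt_schedule(
            1, trials_per_block, seed=int(rng.integers(0, 2**31 - 1))
        )
        isis = sched.all_isis_ms
        rts = np.where(
            rng.random(trials_per_block) < lapse_prob, rt_lapse_ms, rt_nonlapse_ms
        )
        durations[b] = (isis.sum() + rts.sum()) / 60_000.0
    return durations


def smoothed_null_traces(
    rng: np.random.Generator,
    n_subjects: int = 28,
    n_times: int = 126,
    rate_hz: float = 50.0,
    cutoff_hz: float = 4.0,
    order: int = 3,
) -> np.ndarray:
    """i.i.d. Gaussian noise per participant, low-passed like the pipeline.

    Smoothing introduces the within-trace autocorrelation that makes cluster
    correction necessary; across participants the traces stay exchangeable,
    so any significant cluster is a false positive.
    """
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    noise = rng.normal(size=(n_subjects, n_times + 80))
    smooth = signal.sosfiltfilt(sos, noise, axis=1)[:, 40:-40]
    return smooth / smooth.std(axis=1, keepdims=True)


def cluster_test_fwer(
    n_cohorts: int = 2000,
    n_subjects: int = 28,
    n_times: int = 126,
    n_perm: int = 1024,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null cohorts with at least one significant cluster."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        traces = smoothed_null_traces(rng, n_subjects, n_times)
        res = permutation_test(
            traces, n_perm=n_perm, alpha=alpha,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if res.significant:
            hits += 1
    return hits / n_cohorts


def bootstrap_coverage(
    n_cohorts: int = 1000,
    n_subjects: int = 28,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> float:
    """Fraction of Gaussian cohorts whose bootstrap CI covers the true mean."""
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_cohorts):
        values = rng.normal(loc=0.3, scale=1.0, size=n_subjects)
        lo, hi = groupstats.bootstrap_interval(
            values, n_boot=n_boot, level=level, seed=int(rng.integers(0, 2**31 - 1))
        )
        covered += lo <= 0.3 <= hi
    return covered / n_cohorts


def scaled_exp1_config(
    seed: int,
    n_subjects: int = 28,
    duration_min: int = 12,
    amp_decay_per_min: float | None = None,
    n_perm: int = 256,
) -> RunConfig:
    """Shortened vigilance-cohort configuration for repeated simulation.

    Twelve-minute sessions (three 4-min watch periods) keep the full chain —
    schedule, 250 Hz stream, preprocessing, epoching, ANOVA — while fitting
    many cohorts in a modest compute budget.  ``amp_decay_per_min`` None
    keeps the generator default; 0 yields a no-decline null cohort.
    """
    cfg = RunConfig(experiment=1, seed=seed, n_subjects=n_subjects,
                    duration_min=duration_min, n_permutations=n_perm)
    if amp_decay_per_min is not None:
        cfg.pupil = dataclasses.replace(cfg.pupil, amp_decay_per_min=amp_decay_per_min)
    return cfg


def recovery_cohorts(
    n_cohorts: int,
    seed: int,
    amp_decay_per_min: float | None = None,
    n_subjects: int = 28,
    duration_min: int = 12,
) -> pd.DataFrame:
    """Per-cohort recovery of the evoked-amplitude decline.

    For each cohort: simulate, run the pipeline, average the button-locked
    evoked scalar per watch period, and record (a) whether the three period
    means decrease monotonically and (b) whether the one-way RM-ANOVA on the
    per-subject period means rejects at alpha.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cohorts):
        cfg = scaled_exp1_config(
            int(rng.integers(0, 2**31 - 1)), n_subjects, duration_min,
            amp_decay_per_min,
        )
        res = run_experiment1(cfg)
        valid = res["epochs"]
        btn = valid[(valid.lock == "button") & valid.valid]
        cells = (
            btn.groupby(["subject", "period"], observed=True)["evoked_pct"]
            .mean().reset_index()
        )
        period_means = cells.groupby("period", observed=True)["evoked_pct"].mean()
        monotone = bool(np.all(np.diff(period_means.values) < 0))
        aov = groupstats.rm_anova(cells, dv="evoked_pct", within="period",
                                  subject="subject")[0]
        rows.append(dict(cohort=c, monotone=monotone, F=aov.F, p=aov.p,
                         rejected=aov.p < cfg.alpha,
                         **{f"period_{int(k)}": float(v)
                            for k, v in period_means.items()}))
    return pd.DataFrame(rows)
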