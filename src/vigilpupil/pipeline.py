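"""End-to-end cohort pipelines for both experiments.

``run_experiment`` simulates a cohort of observers, preprocesses each pupil
stream, classifies behaviour, extracts epochs, and produces the group-level
statistics: per-period SDT summaries and RM-ANOVAs for the continuous
vigilance task; 1/RT, lapse and pupil-scalar ANOVAs, the fastest/slowest
quintile contrast, cluster permutation tests and trial-level correlations
for the PVT.  All randomness derives from one integer seed; rerunning with
the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, clusterstats, epochs, groupstats, preprocess, schedule, sdt
from .synthetic import (
    ObserverParams,
    PupilParams,
    ResponseLog,
    simulate_behavior,
    simulate_pvt_behavior,
    simulate_pupil,
)

__all__ = ["RunConfig", "run_experiment", "simulate_subject_exp1", "simulate_subject_exp2"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters, with the task-design values as defaults."""

    experiment: int = 1
    seed: int = 0
    n_subjects: int = 28            # Exp 2 analysed cohort: 23

    # vigilance schedule
    duration_min: int = 30
    targets_per_min: int = 6
    min_gap_s: float = 6.0
    max_gap_s: float = 30.0
    edge_buffer_s: float = 2.0
    n_locations: int = 4

    # PVT schedule
    n_blocks: int = 3
    trials_per_block: int = 90
    isi_fixed_ms: int = 2000
    isi_random_low_ms: int = 2000
    isi_random_high_ms: int = 10_000

    observer: ObserverParams = field(default_factory=ObserverParams)
    pupil: PupilParams = field(default_factory=PupilParams)

    # preprocessing
    rate_hz: int = 250
    target_hz: int = 50
    blink_pad_ms: float = 100.0
    filter_order: int = 3
    filter_cutoff_hz: float = 4.0

    # classification / epoching / stats
    mad_k: float = 2.0
    min_gap_for_fa_ms: float = 6000.0
    max_interp_fraction: float = 0.25
    n_periods: int = 3
    trials_per_group: int = 18
    n_permutations: int = 1024
    alpha: float = 0.05

    def subject_seeds(self, n_streams: int = 3) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        return rng.integers(0, 2**31 - 1, size=(self.n_subjects, n_streams))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# per-subject simulation + preprocessing
# ---------------------------------------------------------------------------

def _preprocess(cfg: RunConfig, t, pupil, gx, gy):
    raw = preprocess.SampleSeries(cfg.rate_hz, float(t[0]), pupil, gx, gy)
    return preprocess.preprocess_session(
        raw,
        pad_ms=cfg.blink_pad_ms,
        order=cfg.filter_order,
        cutoff_hz=cfg.filter_cutoff_hz,
        target_hz=cfg.target_hz,
    )


def simulate_subject_exp1(cfg: RunConfig, seeds) -> dict:
    """One vigilance session: schedule, behaviour, pupil, preprocessed series."""
    sched = schedule.generate_vigilance_schedule(
        cfg.duration_min, cfg.targets_per_min, cfg.min_gap_s, cfg.max_gap_s,
        cfg.edge_buffer_s, cfg.n_locations, seed=int(seeds[0]),
    )
    responses, truth = simulate_behavior(sched, cfg.observer, seed=int(seeds[1]))
    t, pupil, gx, gy = simulate_pupil(
        sched, responses, truth, cfg.pupil, cfg.rate_hz, seed=int(seeds[2])
    )
    low, z = _preprocess(cfg, t, pupil, gx, gy)
    return dict(schedule=sched, responses=responses, truth=truth, series_au=low,
                series_z=z)


def simulate_subject_exp2(cfg: RunConfig, seeds) -> dict:
    """One PVT session (3 blocks of 90 trials by default)."""
    sched = schedule.generate_pvt_schedule(
        cfg.n_blocks, cfg.trials_per_block, cfg.isi_fixed_ms,
        cfg.isi_random_low_ms, cfg.isi_random_high_ms, seed=int(seeds[0]),
    )
    responses, truth = simulate_pvt_behavior(sched, cfg.observer, seed=int(seeds[1]))
    t, pupil, gx, gy = simulate_pupil(
        sched, responses, truth, cfg.pupil, cfg.rate_hz, seed=int(seeds[2])
    )
    low, z = _preprocess(cfg, t, pupil, gx, gy)
    return dict(schedule=sched, responses=responses, truth=truth, series_au=low,
                series_z=z)


# ---------------------------------------------------------------------------
# Experiment 1
# ---------------------------------------------------------------------------

def _epoch_exp1(cfg: RunConfig, subj: dict, outcome_table: classify.OutcomeTable,
                subject_id: int) -> pd.DataFrame:
    """Epoch every event of one subject; returns the scalar long table."""
    rows = []
    duration_ms = subj["schedule"].duration_ms
    for rec in outcome_table.records.itertuples():
        if rec.outcome in ("HIT", "FA"):
            spec = epochs.EXP1_BUTTON
            lock = rec.assigned_press_ms
        else:
            spec = epochs.EXP1_STIMULUS
            lock = rec.event_time_ms
        try:
            ep = epochs.extract_epoch(
                subj["series_au"], subj["series_z"], lock, spec,
                outcome=rec.outcome,
            )
        except epochs.EpochError:
            continue  # too close to the session edge
        epochs.apply_exclusions(ep, cfg.max_interp_fraction)
        sm = epochs.scalar_measures(ep)
        rows.append(dict(
            subject=subject_id,
            event_time_ms=rec.event_time_ms,
            outcome=rec.outcome,
            period=epochs.watch_period(rec.event_time_ms, duration_ms, cfg.n_periods),
            lock=spec.lock,
            valid=ep.valid,
            baseline_z=sm.baseline_z,
            evoked_pct=sm.evoked_pct,
            peak_pct=sm.peak_pct,
            peak_latency_ms=sm.peak_latency_ms,
            rt_ms=rec.rt_ms,
            trace=ep.trace_pct,
        ))
    return pd.DataFrame(rows)


def _mean_traces(epoch_df: pd.DataFrame, by: str = "outcome") -> dict[str, np.ndarray]:
    """Per-subject mean %-modulation trace for each group level."""
    out: dict[str, list[np.ndarray]] = {}
    valid = epoch_df[epoch_df.valid]
    for (lvl, _subj), grp in valid.groupby([by, "subject"], observed=True):
        out.setdefault(lvl, []).append(np.mean(np.stack(grp.trace.to_list()), axis=0))
    return {k: np.stack(v) for k, v in out.items()}


def run_experiment1(cfg: RunConfig) -> dict:
    seeds = cfg.subject_seeds()
    subjects = [simulate_subject_exp1(cfg, seeds[i]) for i in range(cfg.n_subjects)]

    # pooled (group-level) permissible hit range
    pooled_rts = []
    for subj in subjects:
        rts, _, cand = classify.press_rts(
            subj["schedule"], subj["responses"], cfg.min_gap_for_fa_ms
        )
        pooled_rts.append(rts[cand])
    pooled = np.concatenate(pooled_rts) if pooled_rts else np.array([])
    hit_window = classify.hit_window_from_rts(pooled, cfg.mad_k)

    behaviour_rows, epoch_frames, minute_bin_rows = [], [], []
    duration_ms = cfg.duration_min * 60_000.0
    for i, subj in enumerate(subjects):
        table = classify.assign_outcomes(
            subj["schedule"], subj["responses"], cfg.min_gap_for_fa_ms,
            cfg.mad_k, hit_window_ms=hit_window,
        )
        summary = sdt.summarize_periods(table, duration_ms, cfg.n_periods)
        summary.insert(0, "subject", i)
        behaviour_rows.append(summary)
        epoch_frames.append(_epoch_exp1(cfg, subj, table, i))
        minute_bin_rows.append(preprocess.minute_bins(subj["series_z"]))

    behaviour = pd.concat(behaviour_rows, ignore_index=True)
    epoch_df = pd.concat(epoch_frames, ignore_index=True)
    minute_bin_traces = np.stack(minute_bin_rows)

    # cluster permutation tests on per-subject mean traces
    traces = _mean_traces(epoch_df)
    cluster_results = {
        name: clusterstats.permutation_test(
            tr, n_perm=cfg.n_permutations, alpha=cfg.alpha, seed=cfg.seed + 17,
        )
        for name, tr in traces.items() if tr.shape[0] >= 2
    }
    for pair in (("HIT", "FA"), ("MISS", "CR")):
        a, b = pair
        if a in traces and b in traces:
            # pairwise-complete participants
            na, nb = traces[a].shape[0], traces[b].shape[0]
            n = min(na, nb)
            if n >= 2 and na == nb:
                cluster_results[f"{a}_vs_{b}"] = clusterstats.permutation_test(
                    traces[a], traces[b], n_perm=cfg.n_permutations,
                    alpha=cfg.alpha, seed=cfg.seed + 19,
                )
    cluster_results["minute_bins"] = clusterstats.permutation_test(
        minute_bin_traces, n_perm=cfg.n_permutations, alpha=cfg.alpha,
        seed=cfg.seed + 23,
    )

    # time-on-task ANOVAs on behaviour
    per = behaviour[behaviour.period > 0].copy()
    anovas = {}
    for dv in ("hit_rate", "fa_rate", "rt_mean_ms", "d_prime", "criterion_c"):
        anovas[dv] = groupstats.rm_anova(per, dv=dv, within="period", subject="subject")
    # pupil scalar ANOVAs (outcome x watch period), per lock type
    valid = epoch_df[epoch_df.valid]
    scalar_cells = (
        valid.groupby(["subject", "lock", "outcome", "period"], observed=True)
        [["baseline_z", "evoked_pct"]].mean().reset_index()
    )
    for lock in ("stimulus", "button"):
        sub = scalar_cells[scalar_cells.lock == lock]
        for dv in ("baseline_z", "evoked_pct"):
            try:
                anovas[f"{lock}_{dv}"] = groupstats.rm_anova(
                    sub, dv=dv, within=["outcome", "period"], subject="subject"
                )
            except ValueError as exc:
                log.warning("ANOVA %s_%s skipped: %s", lock, dv, exc)

    # trial-level correlations over valid button-locked epochs
    btn = valid[valid.lock == "button"].dropna(subset=["rt_ms"])
    correlations = {}
    if len(btn) >= 3:
        for name, (x, y) in {
            "rt_vs_baseline": (btn.rt_ms, btn.baseline_z),
            "rt_vs_evoked": (btn.rt_ms, btn.evoked_pct),
            "baseline_vs_evoked": (btn.baseline_z, btn.evoked_pct),
        }.items():
            r, df, p = groupstats.pearson_r(x, y)
            correlations[name] = dict(r=r, df=df, p=p)

    return dict(
        config=cfg,
        hit_window_ms=hit_window,
        behaviour=behaviour,
        epochs=epoch_df.drop(columns=["trace"]),
        traces=traces,
        minute_bins=minute_bin_traces,
        clusters=cluster_results,
        anovas=anovas,
        correlations=correlations,
    )


# ---------------------------------------------------------------------------
# Experiment 2
# ---------------------------------------------------------------------------

def _epoch_exp2(cfg: RunConfig, subj: dict, trial_table: pd.DataFrame,
                subject_id: int) -> pd.DataFrame:
    rows = []
    truth = subj["truth"]
    presses = subj["responses"].presses
    for rec in trial_table.itertuples():
        press = presses[rec.trial_index]
        flip = truth.flip_times_ms[rec.trial_index]
        try:
            ep = epochs.extract_epoch(
                subj["series_au"], subj["series_z"], press, epochs.EXP2_BUTTON,
                stim_time_ms=flip, outcome="PVT",
            )
        except epochs.EpochError:
            continue
        epochs.apply_exclusions(ep, cfg.max_interp_fraction)
        sm = epochs.scalar_measures(ep)
        rows.append(dict(
            subject=subject_id,
            trial_index=rec.trial_index,
            block=rec.block,
            trial_group=rec.trial_group,
            rt_ms=rec.rt_ms,
            recip_rt_per_s=rec.recip_rt_per_s,
            lapse=rec.lapse,
            valid=ep.valid,
            baseline_z=sm.baseline_z,
            evoked_pct=sm.evoked_pct,
            peak_pct=sm.peak_pct,
            peak_latency_ms=sm.peak_latency_ms,
            trace=ep.trace_pct,
        ))
    return pd.DataFrame(rows)


def run_experiment2(cfg: RunConfig) -> dict:
    seeds = cfg.subject_seeds()
    subjects = [simulate_subject_exp2(cfg, seeds[i]) for i in range(cfg.n_subjects)]

    trial_frames, thresholds, block_durations = [], [], []
    for i, subj in enumerate(subjects):
        table, threshold = classify.pvt_trial_table(
            subj["truth"].rt_ms, cfg.trials_per_block, cfg.trials_per_group, cfg.mad_k
        )
        thresholds.append(threshold)
        table = _epoch_exp2(cfg, subj, table, i)
        trial_frames.append(table)
        flips = subj["truth"].flip_times_ms
        presses = subj["responses"].presses
        for b in range(cfg.n_blocks):
            i0, i1 = b * cfg.trials_per_block, (b + 1) * cfg.trials_per_block
            start = flips[i0] - subj["schedule"].blocks[b][0].isi_ms
            block_durations.append(
                dict(subject=i, block=b + 1,
                     duration_min=(presses[i1 - 1] - start) / 60_000.0)
            )
    trials = pd.concat(trial_frames, ignore_index=True)
    block_durations = pd.DataFrame(block_durations)

    # trial group x block ANOVAs
    anovas, simple_effects = {}, {}
    perf_cells = (
        trials.groupby(["subject", "block", "trial_group"], observed=True)
        .agg(recip_rt_per_s=("recip_rt_per_s", "mean"), n_lapses=("lapse", "sum"))
        .reset_index()
    )
    pupil_valid = trials[trials.valid]
    pupil_cells = (
        pupil_valid.groupby(["subject", "block", "trial_group"], observed=True)
        [["baseline_z", "evoked_pct"]].mean().reset_index()
    )
    for dv, cells in (
        ("recip_rt_per_s", perf_cells),
        ("n_lapses", perf_cells),
        ("baseline_z", pupil_cells),
        ("evoked_pct", pupil_cells),
    ):
        try:
            anovas[dv] = groupstats.rm_anova(
                cells, dv=dv, within=["trial_group", "block"], subject="subject"
            )
            simple_effects[dv] = groupstats.simple_main_effects(
                cells, dv=dv, free="trial_group", fix="block", subject="subject"
            )
        except ValueError as exc:
            log.warning("ANOVA %s skipped: %s", dv, exc)

    # fastest / slowest 20% contrast (per participant)
    fast_rows, slow_rows, fast_traces, slow_traces = [], [], [], []
    post_button_ms = 2000.0
    for sid, sub in trials.groupby("subject", observed=True):
        sub_valid = sub[sub.valid]
        if len(sub_valid) < 5:
            log.warning("subject %s: too few valid trials for quintile split", sid)
            continue
        fastest, slowest = epochs.quintile_split(sub_valid)
        f, s = sub_valid.loc[fastest], sub_valid.loc[slowest]
        fast_rows.append(dict(subject=sid, rt_ms=f.rt_ms.mean(),
                              baseline_z=f.baseline_z.mean()))
        slow_rows.append(dict(subject=sid, rt_ms=s.rt_ms.mean(),
                              baseline_z=s.baseline_z.mean()))
        fast_traces.append(np.mean(np.stack(f.trace.to_list()), axis=0))
        slow_traces.append(np.mean(np.stack(s.trace.to_list()), axis=0))
    quintiles = dict(
        fastest=pd.DataFrame(fast_rows), slowest=pd.DataFrame(slow_rows)
    )
    clusters = {}
    if len(fast_traces) >= 2:
        fast_traces = np.stack(fast_traces)
        slow_traces = np.stack(slow_traces)
        clusters["fastest"] = clusterstats.permutation_test(
            fast_traces, n_perm=cfg.n_permutations, alpha=cfg.alpha,
            seed=cfg.seed + 29,
        )
        clusters["slowest"] = clusterstats.permutation_test(
            slow_traces, n_perm=cfg.n_permutations, alpha=cfg.alpha,
            seed=cfg.seed + 29,
        )
        clusters["slowest_vs_fastest"] = clusterstats.permutation_test(
            slow_traces, fast_traces, n_perm=cfg.n_permutations,
            alpha=cfg.alpha, seed=cfg.seed + 31,
        )
        # post-button modulation means over the final stretch of the trace
        t_rel = epochs.EXP2_BUTTON.window_ms[0] + np.arange(
            fast_traces.shape[1]
        ) * (1000.0 / cfg.target_hz)
        sel = (t_rel >= 0) & (t_rel <= post_button_ms)
        quintiles["fastest"]["post_button_pct"] = fast_traces[:, sel].mean(axis=1)
        quintiles["slowest"]["post_button_pct"] = slow_traces[:, sel].mean(axis=1)

    # block-wise grand traces
    block_traces = _mean_traces(trials, by="block")
    for b, tr in block_traces.items():
        if tr.shape[0] >= 2:
            clusters[f"block_{b}"] = clusterstats.permutation_test(
                tr, n_perm=cfg.n_permutations, alpha=cfg.alpha, seed=cfg.seed + 37
            )

    valid = trials[trials.valid]
    correlations = {}
    if len(valid) >= 3:
        for name, (x, y) in {
            "rt_vs_baseline": (valid.rt_ms, valid.baseline_z),
            "rt_vs_evoked": (valid.rt_ms, valid.evoked_pct),
            "baseline_vs_evoked": (valid.baseline_z, valid.evoked_pct),
        }.items():
            r, df, p = groupstats.pearson_r(x, y)
            correlations[name] = dict(r=r, df=df, p=p)

    return dict(
        config=cfg,
        trials=trials.drop(columns=["trace"]),
        lapse_thresholds_ms=np.array(thresholds),
        block_durations=block_durations,
        anovas=anovas,
        simple_effects=simple_effects,
        quintiles=quintiles,
        clusters=clusters,
        correlations=correlations,
    )


# ---------------------------------------------------------------------------

def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _anova_frame(anovas: dict) -> pd.DataFrame:
    rows = []
    for dv, results in anovas.items():
        for res in results:
            rows.append(dict(measure=dv, **dataclasses.asdict(res)))
    return pd.DataFrame(rows)


def _cluster_frame(clusters: dict) -> pd.DataFrame:
    rows = []
    for name, res in clusters.items():
        for c in res.clusters:
            rows.append(dict(test=name, start_index=c.start_index,
                             end_index=c.end_index, mass=c.mass, sign=c.sign,
                             p_corrected=c.p_corrected,
                             n_permutations=res.n_permutations,
                             t_threshold=res.t_threshold))
        if not res.clusters:
            rows.append(dict(test=name, start_index=np.nan, end_index=np.nan,
                             mass=np.nan, sign=np.nan, p_corrected=np.nan,
                             n_permutations=res.n_permutations,
                             t_threshold=res.t_threshold))
    return pd.DataFrame(rows)


def run_experiment(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the configured experiment; optionally write tables + manifest."""
    if cfg.experiment == 1:
        result = run_experiment1(cfg)
    elif cfg.experiment == 2:
        result = run_experiment2(cfg)
    else:
        raise ValueError(f"unknown experiment {cfg.experiment}")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key in ("behaviour", "epochs", "trials", "block_durations"):
            if key in result:
                result[key].to_csv(out / f"{key}.csv", index=False)
        _anova_frame(result["anovas"]).to_csv(out / "anovas.csv", index=False)
        _cluster_frame(result["clusters"]).to_csv(out / "clusters.csv", index=False)
        if result.get("correlations"):
            pd.DataFrame(result["correlations"]).T.to_csv(out / "correlations.csv")
        if "traces" in result:
            for name, tr in result["traces"].items():
                np.savetxt(out / f"trace_{name}.tsv", tr, delimiter="\t")
        manifest = dict(
            experiment=cfg.experiment, seed=cfg.seed,
            n_subjects=cfg.n_subjects, config_hash=_config_hash(cfg),
            config=cfg.to_dict(),
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result
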