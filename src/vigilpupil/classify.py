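"""Response classification: SDT outcome assignment and PVT lapse labelling.

The continuous-vigilance assignment is iterative.  Pass 1: a press whose RT
to the most recent target exceeds the minimum inter-target time (6 s), or
that precedes any target, is a false alarm bound to the nearest elapsed
neutral event.  Pass 2: the remaining presses are pooled, a permissible hit
range is set at the group median RT +/- 2 scaled MADs, and presses inside it
become hits (first press per target); presses outside become false alarms.
Pass 3: unanswered targets are misses, untouched neutral events correct
rejections.

PVT lapses are one-sided per participant: RT above median + 2 scaled MADs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedule import StimulusSchedule
from .synthetic import ResponseLog

__all__ = [
    "ClassifyError",
    "OutcomeTable",
    "mad",
    "press_rts",
    "hit_window_from_rts",
    "assign_outcomes",
    "label_lapses",
    "reciprocal_rt",
    "pvt_trial_table",
]

log = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # normal-consistency constant


class ClassifyError(ValueError):
    pass


@dataclass
class OutcomeTable:
    """Per-event SDT labels with assigned presses and RTs."""

    records: pd.DataFrame  # event_time_ms, outcome, rt_ms, assigned_press_ms
    hit_window_ms: tuple[float, float]

    def counts(self) -> dict[str, int]:
        return self.records["outcome"].value_counts().to_dict()

    def subset(self, t0_ms: float, t1_ms: float) -> pd.DataFrame:
        r = self.records
        return r[(r.event_time_ms >= t0_ms) & (r.event_time_ms < t1_ms)]


def mad(values, scale_constant: float = MAD_SCALE) -> float:
    """Median absolute deviation, scaled (1.4826 for normal consistency)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ClassifyError("MAD of empty sequence")
    med = np.median(values)
    return float(scale_constant * np.median(np.abs(values - med)))


def press_rts(
    schedule: StimulusSchedule,
    responses: ResponseLog,
    min_gap_ms: float = 6000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pass 1: RT of each press to the most recent target.

    Returns (rt_ms with nan for immediate FAs, index of preceding target or
    -1, is_candidate), where a candidate press has a preceding target and
    RT <= min_gap_ms and goes on to the pooled hit-window stage.
    """
    targets = schedule.target_times_ms.astype(float)
    presses = responses.presses
    rts = np.full(presses.size, np.nan)
    t_idx = np.full(presses.size, -1, dtype=int)
    candidate = np.zeros(presses.size, dtype=bool)
    for i, p in enumerate(presses):
        j = int(np.searchsorted(targets, p, side="right")) - 1
        if j < 0:
            continue  # no target yet presented -> FA
        rt = p - targets[j]
        rts[i] = rt
        t_idx[i] = j
        if rt <= min_gap_ms:
            candidate[i] = True
    return rts, t_idx, candidate


def hit_window_from_rts(
    candidate_rts: np.ndarray, k: float = 2.0, scale_constant: float = MAD_SCALE
) -> tuple[float, float]:
    """Permissible hit range: median +/- k scaled MADs of the pooled RTs.

    A degenerate (zero-MAD) pool widens to +/-1 ms so the window is never
    empty.
    """
    candidate_rts = np.asarray(candidate_rts, dtype=float)
    if candidate_rts.size == 0:
        return (np.nan, np.nan)
    med = float(np.median(candidate_rts))
    spread = mad(candidate_rts, scale_constant)
    if spread == 0.0:
        log.warning("degenerate RT pool (MAD 0); widening hit window to +/-1 ms")
        return (med - 1.0, med + 1.0)
    return (med - k * spread, med + k * spread)


def _nearest_elapsed_neutral(neutrals: np.ndarray, press: float, used: set[int]) -> int:
    """Latest unused neutral event at or before the press.

    A press preceding every neutral binds to the earliest one; if every
    elapsed neutral already carries a false alarm, the nearest later unused
    neutral is taken so every press keeps exactly one event.
    """
    j = int(np.searchsorted(neutrals, press, side="right")) - 1
    if j < 0:
        log.warning("press at %.0f ms precedes every neutral event", press)
        j = 0
    while j >= 0 and j in used:
        j -= 1
    if j < 0:
        j = int(np.searchsorted(neutrals, press, side="right"))
        while j < neutrals.size and j in used:
            j += 1
        if j >= neutrals.size:
            raise ClassifyError("more false-alarm presses than neutral events")
    return j


def assign_outcomes(
    schedule: StimulusSchedule,
    responses: ResponseLog,
    min_gap_ms: float = 6000.0,
    k: float = 2.0,
    hit_window_ms: tuple[float, float] | None = None,
    scale_constant: float = MAD_SCALE,
) -> OutcomeTable:
    """Label every event HIT/MISS/FA/CR and bind every press to one event.

    ``hit_window_ms`` may be supplied (e.g., pooled across a cohort); when
    absent it is derived from this session's candidate RTs.  Within a
    target's window the first qualifying press is the hit; surplus presses
    become false alarms on the nearest elapsed neutral event.
    """
    targets = schedule.target_times_ms.astype(float)
    neutrals = schedule.neutral_times_ms.astype(float)
    presses = responses.presses
    rts, t_idx, candidate = press_rts(schedule, responses, min_gap_ms)

    if hit_window_ms is None:
        hit_window_ms = hit_window_from_rts(rts[candidate], k, scale_constant)
    lo, hi = hit_window_ms

    target_outcome = np.full(targets.size, "MISS", dtype=object)
    target_rt = np.full(targets.size, np.nan)
    target_press = np.full(targets.size, np.nan)
    neutral_fa_press: dict[int, float] = {}

    for i, p in enumerate(presses):
        is_hit = (
            candidate[i]
            and np.isfinite(lo)
            and lo <= rts[i] <= hi
            and target_outcome[t_idx[i]] == "MISS"
        )
        if is_hit:
            target_outcome[t_idx[i]] = "HIT"
            target_rt[t_idx[i]] = rts[i]
            target_press[t_idx[i]] = p
        else:
            j = _nearest_elapsed_neutral(neutrals, p, set(neutral_fa_press))
            neutral_fa_press[j] = p

    rows = []
    for j, t in enumerate(targets):
        rows.append(
            dict(event_time_ms=t, event_kind="target", outcome=target_outcome[j],
                 rt_ms=target_rt[j], assigned_press_ms=target_press[j])
        )
    for j, t in enumerate(neutrals):
        if j in neutral_fa_press:
            p = neutral_fa_press[j]
            rows.append(dict(event_time_ms=t, event_kind="neutral", outcome="FA",
                             rt_ms=p - t, assigned_press_ms=p))
        else:
            rows.append(dict(event_time_ms=t, event_kind="neutral", outcome="CR",
                             rt_ms=np.nan, assigned_press_ms=np.nan))
    records = pd.DataFrame(rows).sort_values("event_time_ms").reset_index(drop=True)
    return OutcomeTable(records=records, hit_window_ms=(float(lo), float(hi)))


def label_lapses(
    rts, k: float = 2.0, scale_constant: float = MAD_SCALE
) -> tuple[np.ndarray, float]:
    """One-sided lapse labels: RT above the participant median + k scaled MADs."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < 3:
        raise ClassifyError("need at least 3 trials to label lapses")
    threshold = float(np.median(rts) + k * mad(rts, scale_constant))
    return rts > threshold, threshold


def reciprocal_rt(rt_ms):
    """Response speed in 1/s: 1000 / RT(ms)."""
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt <= 0):
        raise ClassifyError("RT must be positive")
    out = 1000.0 / rt
    return float(out) if out.ndim == 0 else out


def pvt_trial_table(
    rts_ms,
    trials_per_block: int = 90,
    trials_per_group: int = 18,
    k: float = 2.0,
) -> tuple[pd.DataFrame, float]:
    """Per-trial PVT records: block, 18-trial trial group, 1/RT, lapse flag."""
    rts = np.asarray(rts_ms, dtype=float)
    lapse, threshold = label_lapses(rts, k)
    idx = np.arange(rts.size)
    block = idx // trials_per_block + 1
    group = (idx % trials_per_block) // trials_per_group + 1
    table = pd.DataFrame(
        dict(trial_index=idx, block=block, trial_group=group, rt_ms=rts,
             recip_rt_per_s=reciprocal_rt(rts), lapse=lapse)
    )
    return table, threshold
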