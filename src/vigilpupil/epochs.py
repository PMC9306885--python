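"""Event-locked epoching, baselines, exclusion rules, and scalar measures.

Continuous vigilance task: misses and correct rejections are stimulus-locked
([-500, +2000] ms, baseline [-500, 0) ms); hits and false alarms are
button-locked ([-1000, +1500] ms, baseline [-1000, -500) ms, offset to avoid
motor-preparation contamination).  PVT: traces are button-locked
([-1000, +1500] ms) with the baseline taken in the 500 ms before the
RT-initiating flip; the evoked scalar averages [-500, +1500] ms.

An epoch is discarded if the observer blinked in the baseline window or more
than 25% of its samples are interpolated.  Baseline scalars are session
z-units; evoked scalars are the mean percent modulation,
100 * (x - baseline) / baseline, over the peristimulus window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import SampleSeries

__all__ = [
    "EpochError",
    "EpochSpec",
    "Epoch",
    "ScalarMeasures",
    "EXP1_STIMULUS",
    "EXP1_BUTTON",
    "EXP2_BUTTON",
    "extract_epoch",
    "apply_exclusions",
    "scalar_measures",
    "quintile_split",
    "watch_period",
]

log = logging.getLogger(__name__)


class EpochError(ValueError):
    pass


@dataclass(frozen=True)
class EpochSpec:
    """Epoch geometry, all relative to the lock event (ms)."""

    lock: str                 # "stimulus" or "button"
    window_ms: tuple[float, float]
    baseline_ms: tuple[float, float]   # relative to the lock event
    evoked_ms: tuple[float, float]     # peristimulus averaging window
    baseline_lock: str = "self"        # "self" or "stimulus" (PVT: pre-flip)


EXP1_STIMULUS = EpochSpec("stimulus", (-500.0, 2000.0), (-500.0, 0.0), (0.0, 2000.0))
EXP1_BUTTON = EpochSpec("button", (-1000.0, 1500.0), (-1000.0, -500.0), (-500.0, 1500.0))
EXP2_BUTTON = EpochSpec(
    "button", (-1000.0, 1500.0), (-500.0, 0.0), (-500.0, 1500.0),
    baseline_lock="stimulus",
)


@dataclass
class Epoch:
    spec: EpochSpec
    lock_time_ms: float
    t_rel_ms: np.ndarray
    trace_z: np.ndarray          # session z-units
    trace_pct: np.ndarray        # percent modulation from the trial baseline
    baseline_au: float
    baseline_z: float
    interp_fraction: float
    blink_in_baseline: bool
    session_minute: float
    outcome: str = ""
    valid: bool = True


@dataclass(frozen=True)
class ScalarMeasures:
    baseline_z: float
    evoked_pct: float
    peak_pct: float
    peak_latency_ms: float


def _slice(series: SampleSeries, t0: float, t1: float, inclusive: bool = False) -> slice:
    """Sample slice covering [t0, t1) — or [t0, t1] when ``inclusive``.

    An inclusive 2,500 ms window at 50 Hz spans 126 samples.
    """
    i0 = int(np.ceil(round((t0 - series.t0_ms) / series.dt_ms, 9)))
    if inclusive:
        i1 = int(np.floor(round((t1 - series.t0_ms) / series.dt_ms, 9))) + 1
    else:
        i1 = int(np.ceil(round((t1 - series.t0_ms) / series.dt_ms, 9)))
    if i0 < 0 or i1 > series.pupil.size:
        raise EpochError("window outside session bounds")
    return slice(i0, i1)


def extract_epoch(
    series_au: SampleSeries,
    series_z: SampleSeries,
    lock_time_ms: float,
    spec: EpochSpec,
    stim_time_ms: float | None = None,
    outcome: str = "",
) -> Epoch:
    """Cut one epoch from the paired (a.u., z) 50 Hz series.

    ``stim_time_ms`` anchors the baseline when ``spec.baseline_lock`` is
    "stimulus" (the PVT pre-flip baseline).  Raises ``EpochError`` when any
    required window leaves the session; callers drop and log such events.
    """
    w0, w1 = spec.window_ms
    # fixed sample count (endpoints inclusive: 2,500 ms at 50 Hz = 126
    # samples) so traces stack regardless of lock-time grid alignment
    n_samples = int(round((w1 - w0) / series_au.dt_ms)) + 1
    i0 = int(np.ceil(round((lock_time_ms + w0 - series_au.t0_ms) / series_au.dt_ms, 9)))
    if i0 < 0 or i0 + n_samples > series_au.pupil.size:
        raise EpochError("window outside session bounds")
    sl = slice(i0, i0 + n_samples)
    if spec.baseline_lock == "stimulus":
        if stim_time_ms is None:
            raise EpochError("stimulus-locked baseline requires stim_time_ms")
        b_anchor = stim_time_ms
    else:
        b_anchor = lock_time_ms
    b0, b1 = spec.baseline_ms
    bsl = _slice(series_au, b_anchor + b0, b_anchor + b1)

    baseline_au = float(series_au.pupil[bsl].mean())
    baseline_z = float(series_z.pupil[bsl].mean())
    raw = series_au.pupil[sl]
    if baseline_au == 0:
        raise EpochError("zero baseline; percent modulation undefined")
    trace_pct = 100.0 * (raw - baseline_au) / baseline_au
    trace_z = series_z.pupil[sl].copy()
    n = sl.stop - sl.start
    t_rel = w0 + np.arange(n) * series_au.dt_ms

    mask_epoch = series_au.interp_mask[sl]
    mask_base = series_au.interp_mask[bsl]
    return Epoch(
        spec=spec,
        lock_time_ms=float(lock_time_ms),
        t_rel_ms=t_rel,
        trace_z=trace_z,
        trace_pct=trace_pct,
        baseline_au=baseline_au,
        baseline_z=baseline_z,
        interp_fraction=float(mask_epoch.mean()) if n else 0.0,
        blink_in_baseline=bool(mask_base.any()),
        session_minute=float(lock_time_ms) / 60_000.0,
        outcome=outcome,
    )


def apply_exclusions(epoch: Epoch, max_interp_fraction: float = 0.25) -> Epoch:
    """Mark the epoch invalid on a baseline blink or >25% interpolated data."""
    epoch.valid = (not epoch.blink_in_baseline) and (
        epoch.interp_fraction <= max_interp_fraction
    )
    return epoch


def scalar_measures(epoch: Epoch) -> ScalarMeasures:
    """Baseline-z and evoked-percent scalars plus peak and its latency."""
    e0, e1 = epoch.spec.evoked_ms
    sel = (epoch.t_rel_ms >= e0) & (epoch.t_rel_ms < e1)
    if not sel.any():
        raise EpochError("empty evoked window")
    evoked = float(epoch.trace_pct[sel].mean())
    i_peak = int(np.argmax(epoch.trace_pct[sel]))
    return ScalarMeasures(
        baseline_z=epoch.baseline_z,
        evoked_pct=evoked,
        peak_pct=float(epoch.trace_pct[sel][i_peak]),
        peak_latency_ms=float(epoch.t_rel_ms[sel][i_peak]),
    )


def watch_period(time_ms: float, duration_ms: float, n_periods: int = 3) -> int:
    """1-based watch period of an event; each epoch falls in exactly one."""
    period = int(time_ms // (duration_ms / n_periods)) + 1
    return min(max(period, 1), n_periods)


def quintile_split(trials: pd.DataFrame, rt_col: str = "rt_ms"):
    """Fastest and slowest 20% of trials by RT (floor(n/5) each side).

    Ties are broken by trial order.  Requires at least 5 trials.
    Returns (fastest_index, slowest_index) as row indices into ``trials``.
    """
    n = len(trials)
    if n < 5:
        raise EpochError("need at least 5 trials for a quintile split")
    k = n // 5
    order = trials[rt_col].reset_index(drop=True).sort_values(kind="stable").index
    fastest = trials.index[order[:k]]
    slowest = trials.index[order[n - k:]]
    return fastest, slowest
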