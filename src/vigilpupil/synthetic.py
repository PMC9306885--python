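"""Synthetic observers and 250 Hz pupil/gaze streams.

The generator emulates the statistical structure of an eye-tracked vigilance
session: event-locked pupil dilations riding on a slowly drifting baseline,
whose amplitude declines with time-on-task; log-normal reaction times with a
lapse mixture; rare false alarms; and blink artefacts (missing samples) that
cluster after button presses.  Ground truth (true outcome labels, injected
amplitudes, baseline trajectory) is retained so downstream recovery can be
checked against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .schedule import PvtSchedule, StimulusSchedule

__all__ = [
    "ObserverParams",
    "PupilParams",
    "SessionTruth",
    "ResponseLog",
    "simulate_behavior",
    "simulate_pvt_behavior",
    "pupil_kernel",
    "simulate_pupil",
    "write_samples",
    "read_samples",
    "MISSING_CODE",
]

MISSING_CODE = 0.0


@dataclass(frozen=True)
class ObserverParams:
    """Behavioural parameters of a simulated observer.

    Defaults reproduce the vigilance-task phenomenology: hit probability
    declining across the three 10-min watch periods, a ~1% false-alarm rate
    per neutral event, and log-normal hit RTs slowing with time-on-task.
    PVT fields give a 420 ms non-lapse / 960 ms lapse RT mixture with a
    lapse probability of 27.6 per 270 trials.
    """

    hit_prob_by_period: tuple[float, ...] = (0.692, 0.625, 0.596)
    fa_rate_per_neutral: float = 0.0109
    rt_median_ms_by_period: tuple[float, ...] = (640.0, 676.0, 693.0)
    rt_log_sd: float = 0.16
    lapse_prob: float = 27.6 / 270.0
    lapse_rt_mean_ms: float = 960.0
    lapse_rt_log_sd: float = 0.6
    pvt_rt_mean_ms: float = 420.0
    pvt_rt_sd_ms: float = 79.0

    def __post_init__(self) -> None:
        for p in (*self.hit_prob_by_period, self.fa_rate_per_neutral, self.lapse_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if min(self.rt_median_ms_by_period) <= 0 or self.rt_log_sd < 0:
            raise ValueError("RT parameters must be positive")


@dataclass(frozen=True)
class PupilParams:
    """Generative parameters of the pupil stream (arbitrary units, a.u.)."""

    baseline_mean_au: float = 4000.0
    baseline_drift_sd: float = 0.2      # random-walk step sd per sample
    noise_sd: float = 20.0
    kernel_n: float = 10.1
    kernel_tmax_ms: float = 930.0
    evoked_amp_by_outcome: dict = field(
        default_factory=lambda: {
            "hit": 5.6,        # % of baseline, button-locked
            "fa": 7.0,
            "miss": 2.7,       # stimulus-locked dilation without a response
            "neutral": 0.0,
            "pvt": 6.0,
        }
    )
    amp_decay_per_min: float = 0.025
    blink_rate_hz: float = 0.15
    blink_dur_range_ms: tuple[float, float] = (100.0, 400.0)
    post_button_blink_boost: float = 0.5   # P(extra blink in the 1 s after a press)

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.evoked_amp_by_outcome.values()):
            raise ValueError("evoked amplitudes must be non-negative")
        if self.kernel_tmax_ms <= 0:
            raise ValueError("kernel_tmax_ms must be positive")
        lo, hi = self.blink_dur_range_ms
        if lo <= 0 or hi < lo:
            raise ValueError("blink durations must be positive")


@dataclass
class ResponseLog:
    """Strictly increasing button-press times, ms from session start."""

    presses: np.ndarray

    def __post_init__(self) -> None:
        self.presses = np.asarray(self.presses, dtype=float)
        if self.presses.size and np.any(np.diff(self.presses) <= 0):
            raise ValueError("press times must be strictly increasing")


@dataclass
class SessionTruth:
    """Ground truth retained by the simulator for recovery tests."""

    event_times_ms: np.ndarray
    event_kinds: list[str]          # per stimulus event: hit/miss/fa/neutral/pvt
    true_amplitudes_pct: np.ndarray  # injected evoked amplitude per event
    rt_ms: np.ndarray               # nan where no response
    lapse: np.ndarray | None = None  # PVT only
    flip_times_ms: np.ndarray | None = None  # PVT stimulus (flip) times
    baseline_trajectory: np.ndarray | None = None


def simulate_behavior(
    schedule: StimulusSchedule,
    params: ObserverParams,
    seed: int,
) -> tuple[ResponseLog, SessionTruth]:
    """Simulate detection behaviour on a continuous vigilance schedule.

    Each target is answered with the period's hit probability (RT log-normal
    around the period median); each neutral tick triggers a false-alarm press
    with the per-neutral rate.  Simultaneous or out-of-order presses are
    dropped to keep the log strictly increasing.
    """
    rng = np.random.default_rng(seed)
    n_periods = len(params.hit_prob_by_period)
    period_ms = schedule.duration_ms / n_periods

    times: list[float] = []
    kinds: list[str] = []
    rts: list[float] = []

    for ev in schedule.events:
        period = min(int(ev.time_ms // period_ms), n_periods - 1)
        if ev.kind == "target":
            if rng.random() < params.hit_prob_by_period[period]:
                median = params.rt_median_ms_by_period[
                    min(period, len(params.rt_median_ms_by_period) - 1)
                ]
                rt = float(rng.lognormal(np.log(median), params.rt_log_sd))
                times.append(ev.time_ms + rt)
                kinds.append("hit")
                rts.append(rt)
            else:
                kinds.append("miss")
                rts.append(np.nan)
                times.append(np.nan)
        else:
            if rng.random() < params.fa_rate_per_neutral:
                rt = float(rng.uniform(200.0, 2000.0))
                times.append(ev.time_ms + rt)
                kinds.append("fa")
                rts.append(rt)
            else:
                kinds.append("neutral")
                rts.append(np.nan)
                times.append(np.nan)

    event_times = np.array([e.time_ms for e in schedule.events], dtype=float)
    press_times = np.array([t for t in times if np.isfinite(t)])
    order = np.argsort(press_times, kind="stable")
    press_times = press_times[order]
    keep = np.ones(press_times.size, dtype=bool)
    if press_times.size > 1:
        keep[1:] = np.diff(press_times) > 0
    truth = SessionTruth(
        event_times_ms=event_times,
        event_kinds=kinds,
        true_amplitudes_pct=np.zeros(event_times.size),
        rt_ms=np.array(rts),
    )
    return ResponseLog(press_times[keep]), truth


def simulate_pvt_behavior(
    schedule: PvtSchedule,
    params: ObserverParams,
    seed: int,
    block_gap_ms: float = 60_000.0,
) -> tuple[ResponseLog, SessionTruth]:
    """Simulate PVT responding: the ISI clock restarts at each button press.

    Trial n's flip occurs ``isi_ms`` after the previous press (block start for
    the first trial); RT is a non-lapse/lapse log-normal mixture.  Returns the
    press log plus truth with flip times, RTs and lapse flags.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + (params.pvt_rt_sd_ms / params.pvt_rt_mean_ms) ** 2))
    mu = np.log(params.pvt_rt_mean_ms) - sigma**2 / 2
    lapse_sigma = params.lapse_rt_log_sd
    lapse_mu = np.log(params.lapse_rt_mean_ms) - lapse_sigma**2 / 2

    presses: list[float] = []
    flips: list[float] = []
    rts: list[float] = []
    lapses: list[bool] = []
    clock = 0.0
    for block in schedule.blocks:
        for trial in block:
            flip = clock + trial.isi_ms
            is_lapse = rng.random() < params.lapse_prob
            if is_lapse:
                rt = float(rng.lognormal(lapse_mu, lapse_sigma))
            else:
                rt = float(rng.lognormal(mu, sigma))
            rt = max(rt, 100.0)  # physiological floor
            press = flip + rt
            flips.append(flip)
            presses.append(press)
            rts.append(rt)
            lapses.append(is_lapse)
            clock = press
        clock += block_gap_ms
    truth = SessionTruth(
        event_times_ms=np.array(flips),
        event_kinds=["pvt"] * len(flips),
        true_amplitudes_pct=np.zeros(len(flips)),
        rt_ms=np.array(rts),
        lapse=np.array(lapses),
        flip_times_ms=np.array(flips),
    )
    return ResponseLog(np.array(presses)), truth


def pupil_kernel(t_ms, n: float = 10.1, tmax_ms: float = 930.0):
    """Gamma-family pupil impulse response, normalized to peak 1 at ``tmax_ms``.

    h(t) = (t/tmax)^n * exp(n * (1 - t/tmax)); zero for t < 0.
    """
    if tmax_ms <= 0:
        raise ValueError("tmax_ms must be positive")
    t = np.asarray(t_ms, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / tmax_ms
    out[pos] = x**n * np.exp(n * (1.0 - x))
    return float(out[0]) if scalar else out


def _press_event_amplitudes(
    truth: SessionTruth, params: PupilParams, responses: ResponseLog
) -> tuple[np.ndarray, np.ndarray]:
    """Times and undecayed amplitudes of every dilation-evoking event."""
    times: list[float] = []
    amps: list[float] = []
    amp = params.evoked_amp_by_outcome
    if truth.flip_times_ms is not None:  # PVT: dilation locked to the press
        for press in responses.presses:
            times.append(press)
            amps.append(amp.get("pvt", 0.0))
        return np.array(times), np.array(amps)
    press_iter = list(responses.presses)
    k = 0
    for t_ev, kind in zip(truth.event_times_ms, truth.event_kinds):
        if kind in ("hit", "fa"):
            # dilation locked to the press that the behaviour sim emitted
            while k < len(press_iter) and press_iter[k] < t_ev:
                k += 1
            if k < len(press_iter):
                times.append(press_iter[k])
                amps.append(amp.get(kind, 0.0))
        elif kind == "miss":
            times.append(t_ev)
            amps.append(amp.get("miss", 0.0))
        elif amp.get("neutral", 0.0) > 0:
            times.append(t_ev)
            amps.append(amp["neutral"])
    return np.array(times), np.array(amps)


def simulate_pupil(
    schedule: StimulusSchedule | PvtSchedule,
    responses: ResponseLog,
    truth: SessionTruth,
    params: PupilParams,
    rate_hz: int = 250,
    seed: int = 0,
    duration_ms: float | None = None,
    gaze_center: tuple[float, float] = (527.0, 379.0),
    gaze_sd: tuple[float, float] = (20.0, 26.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render the 250 Hz sample stream.

    pupil(t) = baseline random walk + sum of event kernels + Gaussian noise,
    with the evoked amplitude of an event at minute m scaled by
    (1 - amp_decay_per_min)^m.  Blink intervals (a renewal process, with an
    extra blink probability in the 1 s after each press) set samples to the
    missing code 0.  Returns (t_ms, pupil, gaze_x, gaze_y); the baseline
    trajectory is stored on ``truth``.
    """
    rng = np.random.default_rng(seed)
    if duration_ms is None:
        if isinstance(schedule, StimulusSchedule):
            duration_ms = float(schedule.duration_ms)
        else:
            last = max(
                responses.presses[-1] if responses.presses.size else 0.0,
                truth.event_times_ms[-1] if truth.event_times_ms.size else 0.0,
            )
            duration_ms = last + 3000.0
    dt_ms = 1000.0 / rate_hz
    n = int(round(duration_ms / dt_ms))
    t = np.arange(n) * dt_ms

    baseline = params.baseline_mean_au + np.cumsum(
        rng.normal(0.0, params.baseline_drift_sd, size=n)
    )
    pupil = baseline + rng.normal(0.0, params.noise_sd, size=n)

    ev_times, ev_amps = _press_event_amplitudes(truth, params, responses)
    decay = params.amp_decay_per_min
    kernel_len = int(round(4 * params.kernel_tmax_ms / dt_ms))
    kernel = pupil_kernel(
        np.arange(kernel_len) * dt_ms, params.kernel_n, params.kernel_tmax_ms
    )
    true_amps = np.zeros(ev_times.size)
    for j, (t_ev, amp_pct) in enumerate(zip(ev_times, ev_amps)):
        minute = t_ev / 60_000.0
        eff = amp_pct * (1.0 - decay) ** minute
        true_amps[j] = eff
        i0 = int(np.ceil(t_ev / dt_ms))
        if i0 >= n or eff == 0.0:
            continue
        i1 = min(i0 + kernel_len, n)
        seg = kernel[: i1 - i0]
        b0 = baseline[min(i0, n - 1)]
        pupil[i0:i1] += eff / 100.0 * b0 * seg

    # blink artefacts: renewal process + press-locked extras, merged
    intervals: list[tuple[float, float]] = []
    lo_d, hi_d = params.blink_dur_range_ms
    if params.blink_rate_hz > 0:
        t_blink = float(rng.exponential(1000.0 / params.blink_rate_hz))
        while t_blink < duration_ms:
            dur = float(rng.uniform(lo_d, hi_d))
            intervals.append((t_blink, t_blink + dur))
            t_blink += dur + float(rng.exponential(1000.0 / params.blink_rate_hz))
    if params.post_button_blink_boost > 0:
        for press in responses.presses:
            if rng.random() < params.post_button_blink_boost:
                onset = press + float(rng.uniform(100.0, 700.0))
                dur = float(rng.uniform(lo_d, hi_d))
                intervals.append((onset, onset + dur))
    for start, end in _merge_intervals(intervals):
        i0 = max(int(np.floor(start / dt_ms)), 0)
        i1 = min(int(np.ceil(end / dt_ms)), n)
        pupil[i0:i1] = MISSING_CODE

    gaze_x = rng.normal(gaze_center[0], gaze_sd[0], size=n)
    gaze_y = rng.normal(gaze_center[1], gaze_sd[1], size=n)
    truth.baseline_trajectory = baseline
    truth.true_amplitudes_pct = true_amps
    return t, pupil, gaze_x, gaze_y


def _merge_intervals(
    intervals: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    if not intervals:
        return []
    merged: list[tuple[float, float]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


# --- sample-stream serialization -------------------------------------------

def write_samples(
    path: str | Path,
    t_ms: np.ndarray,
    pupil: np.ndarray,
    gaze_x: np.ndarray,
    gaze_y: np.ndarray,
) -> None:
    """Tab-separated sample stream: ``time_ms  gaze_x  gaze_y  pupil_au``."""
    with open(path, "w") as fh:
        fh.write("time_ms\tgaze_x\tgaze_y\tpupil_au\n")
        for row in zip(t_ms, gaze_x, gaze_y, pupil):
            fh.write(f"{row[0]:.1f}\t{row[1]:.1f}\t{row[2]:.1f}\t{row[3]:.2f}\n")


def read_samples(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    return data[:, 0], data[:, 3], data[:, 1], data[:, 2]
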