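"""Stimulus timelines for the two vigilance experiments.

The continuous vigilance task presents four gratings ticking in synchrony at
120 ticks per minute; a target is a tick where one grating falls out of sync.
Targets are therefore constrained to lie on the tick grid, occur at
pseudorandom intervals bounded below and above, respect an edge buffer, and
are balanced exactly across the four locations.

The psychomotor vigilance task (PVT) presents a single central grating that
flips on its side after a response-initiated interstimulus interval (ISI):
a fixed 2 s component plus a random 2-10 s component whose distribution is
balanced across short/medium/long tertiles within each block.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "ScheduleError",
    "StimulusEvent",
    "StimulusSchedule",
    "PvtTrial",
    "PvtSchedule",
    "generate_vigilance_schedule",
    "generate_pvt_schedule",
    "write_events",
    "read_events",
]

TERTILES = ("short", "medium", "long")


class ScheduleError(ValueError):
    """Raised when a requested schedule cannot satisfy its constraints."""


@dataclass(frozen=True)
class StimulusEvent:
    time_ms: int
    kind: str            # "target" or "neutral"
    location: int | None = None


@dataclass
class StimulusSchedule:
    """Tick-aligned event timeline of the continuous vigilance task."""

    events: list[StimulusEvent]
    duration_ms: int
    tick_period_ms: int = 500

    @property
    def target_times_ms(self) -> np.ndarray:
        return np.array([e.time_ms for e in self.events if e.kind == "target"], dtype=int)

    @property
    def neutral_times_ms(self) -> np.ndarray:
        return np.array([e.time_ms for e in self.events if e.kind == "neutral"], dtype=int)

    @property
    def target_locations(self) -> np.ndarray:
        return np.array(
            [e.location for e in self.events if e.kind == "target"], dtype=int
        )


@dataclass(frozen=True)
class PvtTrial:
    isi_ms: int
    tertile: str

    def __post_init__(self) -> None:
        if self.tertile not in TERTILES:
            raise ScheduleError(f"unknown tertile {self.tertile!r}")


@dataclass
class PvtSchedule:
    """Response-initiated ISI schedule of the PVT, grouped into blocks."""

    blocks: list[list[PvtTrial]]
    fixed_ms: int
    random_range_ms: tuple[int, int]

    @property
    def all_isis_ms(self) -> np.ndarray:
        return np.array([t.isi_ms for b in self.blocks for t in b], dtype=int)

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)


def generate_vigilance_schedule(
    duration_min: int = 30,
    targets_per_min: int = 6,
    min_gap_s: float = 6.0,
    max_gap_s: float = 30.0,
    edge_buffer_s: float = 2.0,
    n_locations: int = 4,
    seed: int = 0,
    tick_period_ms: int = 500,
    max_retries: int = 10_000,
) -> StimulusSchedule:
    """Place ``duration_min * targets_per_min`` targets on the tick grid.

    Targets are drawn by rejection sampling of gap sequences: per-gap excesses
    above the minimum gap are sampled uniformly and rescaled so the train fits
    the session, then snapped to ticks and validated against every constraint
    (gap bounds, edge buffer); invalid draws are rejected and resampled.
    Locations are an exact balanced assignment shuffled across the whole run.
    """
    duration_ms = int(duration_min * 60_000)
    n_targets = int(duration_min * targets_per_min)
    min_gap_ms = int(round(min_gap_s * 1000))
    max_gap_ms = int(round(max_gap_s * 1000))
    edge_ms = int(round(edge_buffer_s * 1000))

    if n_targets <= 0:
        raise ScheduleError("schedule must contain at least one target")
    if min_gap_ms > max_gap_ms:
        raise ScheduleError("min_gap_s exceeds max_gap_s")
    span_ms = duration_ms - 2 * edge_ms
    if (n_targets - 1) * min_gap_ms > span_ms:
        raise ScheduleError(
            f"infeasible: {n_targets} targets with min gap {min_gap_ms} ms "
            f"do not fit in {span_ms} ms of usable session"
        )
    if n_targets % n_locations != 0:
        raise ScheduleError(
            f"{n_targets} targets not divisible by {n_locations} locations"
        )

    rng = np.random.default_rng(seed)
    tick = tick_period_ms
    # usable tick indices for targets
    first_tick = int(np.ceil(edge_ms / tick))
    last_tick = (duration_ms - edge_ms) // tick

    min_gap_t = int(np.ceil(min_gap_ms / tick))
    max_gap_t = max_gap_ms // tick
    span_t = last_tick - first_tick

    for _ in range(max_retries):
        # total span of the target train, in ticks
        lo = (n_targets - 1) * min_gap_t
        hi = min(span_t, (n_targets - 1) * max_gap_t)
        if lo > hi:
            raise ScheduleError("infeasible: min-gap total exceeds usable span")
        # keep the train spread over (almost) the whole session so the
        # targets-per-minute density holds throughout, not just on average
        total = int(rng.integers(max(lo, int(0.95 * hi)), hi + 1))
        excess_budget = total - lo
        # uniform excesses rescaled to the budget, rounded onto the tick grid
        raw = rng.uniform(0.0, 1.0, size=n_targets - 1)
        raw_sum = raw.sum()
        if raw_sum == 0:
            excess = np.zeros(n_targets - 1, dtype=int)
        else:
            scaled = raw * (excess_budget / raw_sum)
            excess = np.floor(scaled).astype(int)
            shortfall = excess_budget - int(excess.sum())
            # distribute the rounding remainder one tick at a time
            order = rng.permutation(n_targets - 1)
            for idx in order[:shortfall]:
                excess[idx] += 1
        gaps_t = min_gap_t + excess
        if gaps_t.max(initial=min_gap_t) > max_gap_t:
            continue
        start = first_tick + int(rng.integers(0, span_t - int(gaps_t.sum()) + 1))
        target_ticks = start + np.concatenate([[0], np.cumsum(gaps_t)])
        if target_ticks[-1] > last_tick:
            continue
        target_times = target_ticks * tick
        gaps_ms = np.diff(target_times)
        if gaps_ms.size and (gaps_ms.min() < min_gap_ms or gaps_ms.max() > max_gap_ms):
            continue
        break
    else:
        raise ScheduleError(f"no valid schedule found after {max_retries} attempts")

    locations = np.repeat(np.arange(n_locations), n_targets // n_locations)
    rng.shuffle(locations)

    target_set = set(int(t) for t in target_times)
    events: list[StimulusEvent] = []
    loc_iter = iter(locations)
    for t in range(0, duration_ms, tick):
        if t in target_set:
            events.append(StimulusEvent(t, "target", int(next(loc_iter))))
        else:
            events.append(StimulusEvent(t, "neutral"))
    return StimulusSchedule(events=events, duration_ms=duration_ms, tick_period_ms=tick)


def _tertile_bounds(low_ms: int, high_ms: int) -> list[tuple[float, float]]:
    edges = np.linspace(low_ms, high_ms, 4)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(3)]


def generate_pvt_schedule(
    n_blocks: int = 3,
    trials_per_block: int = 90,
    fixed_ms: int = 2000,
    random_low_ms: int = 2000,
    random_high_ms: int = 10_000,
    seed: int = 0,
) -> PvtSchedule:
    """Draw a tertile-balanced PVT schedule.

    Within each block the trials are split as evenly as possible into
    short/medium/long tertiles of the random-component range; each trial's
    random component is uniform within its tertile, and the tertile order is
    shuffled.  ISI = fixed + random component.
    """
    if n_blocks <= 0 or trials_per_block <= 0:
        raise ScheduleError("block and trial counts must be positive")
    if random_low_ms >= random_high_ms:
        raise ScheduleError("random_low_ms must be below random_high_ms")

    rng = np.random.default_rng(seed)
    bounds = _tertile_bounds(random_low_ms, random_high_ms)

    blocks: list[list[PvtTrial]] = []
    for _ in range(n_blocks):
        base, rem = divmod(trials_per_block, 3)
        counts = np.full(3, base)
        counts[rng.choice(3, size=rem, replace=False)] += 1
        labels = np.repeat(np.arange(3), counts)
        rng.shuffle(labels)
        trials = []
        for lab in labels:
            lo, hi = bounds[lab]
            rand_ms = float(rng.uniform(lo, hi))
            trials.append(
                PvtTrial(isi_ms=int(round(fixed_ms + rand_ms)), tertile=TERTILES[lab])
            )
        blocks.append(trials)
    return PvtSchedule(
        blocks=blocks,
        fixed_ms=fixed_ms,
        random_range_ms=(random_low_ms, random_high_ms),
    )


# --- event-log serialization (tab-separated text) ---------------------------

def write_events(path: str | Path, rows: Iterable[tuple[int, str, object]]) -> None:
    """Write an event log: columns ``time_ms  kind  location`` ('.' if absent)."""
    with open(path, "w") as fh:
        fh.write("time_ms\tkind\tlocation\n")
        for time_ms, kind, loc in rows:
            fh.write(f"{time_ms}\t{kind}\t{'.' if loc is None else loc}\n")


def schedule_rows(schedule: StimulusSchedule) -> list[tuple[int, str, object]]:
    return [
        (e.time_ms, "TARGET" if e.kind == "target" else "NEUTRAL", e.location)
        for e in schedule.events
    ]


def read_events(path: str | Path) -> list[tuple[int, str, int | None]]:
    rows: list[tuple[int, str, int | None]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("time_ms"):
            raise ScheduleError(f"{path}: not an event log")
        for line in fh:
            t, kind, loc = line.rstrip("\n").split("\t")
            rows.append((int(t), kind, None if loc == "." else int(loc)))
    return rows
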