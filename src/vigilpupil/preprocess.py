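"""Pupil preprocessing: blink interpolation, smoothing, downsampling, z-units.

The chain is order-exact: detect blinks (missing-sample runs) -> extend the
endpoints by 100 ms and linearly interpolate -> third-order 4 Hz low-pass
Butterworth (zero-phase) -> block-average to 50 Hz -> session z-transform.
An interpolation mask travels with the series so epoch-level exclusion rules
can count reconstructed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "SampleSeries",
    "BlinkInterval",
    "PreprocessError",
    "detect_blinks",
    "extend_and_interpolate",
    "lowpass_butterworth",
    "downsample",
    "zscore_series",
    "minute_bins",
    "preprocess_session",
]


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class BlinkInterval:
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.start_ms >= self.end_ms:
            raise PreprocessError("blink interval must have start < end")


@dataclass
class SampleSeries:
    """Uniformly sampled pupil/gaze stream with an interpolation mask."""

    rate_hz: int
    t0_ms: float
    pupil: np.ndarray
    gaze_x: np.ndarray | None = None
    gaze_y: np.ndarray | None = None
    interp_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.interp_mask is None:
            self.interp_mask = np.zeros(self.pupil.size, dtype=bool)
        self.interp_mask = np.asarray(self.interp_mask, dtype=bool)
        if self.interp_mask.size != self.pupil.size:
            raise PreprocessError("interp_mask length mismatch")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.pupil.size) * self.dt_ms

    def index_of(self, time_ms: float) -> int:
        return int(round((time_ms - self.t0_ms) / self.dt_ms))

    @property
    def interpolated_fraction(self) -> float:
        return float(self.interp_mask.mean())


def detect_blinks(series: SampleSeries, missing_code: float = 0.0) -> list[BlinkInterval]:
    """Maximal runs of samples equal to ``missing_code``, as time intervals."""
    missing = series.pupil == missing_code
    if not missing.any():
        return []
    edges = np.diff(missing.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if missing[0]:
        starts = np.r_[0, starts]
    if missing[-1]:
        ends = np.r_[ends, missing.size]
    dt = series.dt_ms
    return [
        BlinkInterval(series.t0_ms + s * dt, series.t0_ms + e * dt)
        for s, e in zip(starts, ends)
    ]


def extend_and_interpolate(
    series: SampleSeries,
    blinks: list[BlinkInterval],
    pad_ms: float = 100.0,
) -> SampleSeries:
    """Widen each blink by ``pad_ms`` per side and linearly interpolate inside.

    Pre- and post-blink samples are routinely contaminated, so endpoints are
    extended before reconstruction.  Intervals touching the series edge are
    filled with the nearest valid value.  The returned mask is true over every
    reconstructed sample.
    """
    n = series.pupil.size
    if not blinks:
        return replace(series, pupil=series.pupil.copy(),
                       interp_mask=series.interp_mask.copy())
    dt = series.dt_ms
    mask = np.zeros(n, dtype=bool)
    for b in blinks:
        i0 = max(int(np.floor((b.start_ms - pad_ms - series.t0_ms) / dt)), 0)
        i1 = min(int(np.ceil((b.end_ms + pad_ms - series.t0_ms) / dt)), n)
        mask[i0:i1] = True
    if mask.all():
        raise PreprocessError("blink intervals cover the entire series")
    pupil = series.pupil.copy()
    valid = ~mask
    idx = np.arange(n)
    pupil[mask] = np.interp(idx[mask], idx[valid], pupil[valid])
    return replace(series, pupil=pupil, interp_mask=series.interp_mask | mask)


def lowpass_butterworth(
    series: SampleSeries, order: int = 3, cutoff_hz: float = 4.0
) -> SampleSeries:
    """Zero-phase low-pass on the pupil channel (mask untouched)."""
    nyq = series.rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise PreprocessError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    if not np.all(np.isfinite(series.pupil)):
        raise PreprocessError("series contains non-finite samples; interpolate first")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=series.rate_hz, output="sos")
    return replace(series, pupil=signal.sosfiltfilt(sos, series.pupil),
                   interp_mask=series.interp_mask.copy())


def downsample(series: SampleSeries, target_hz: int = 50) -> SampleSeries:
    """Block-average to ``target_hz``; output mask is the block-wise OR."""
    if series.rate_hz % target_hz != 0:
        raise PreprocessError(
            f"rate {series.rate_hz} Hz not divisible by target {target_hz} Hz"
        )
    step = series.rate_hz // target_hz
    n_out = series.pupil.size // step
    trimmed = series.pupil[: n_out * step].reshape(n_out, step)
    mask = series.interp_mask[: n_out * step].reshape(n_out, step)
    out = replace(
        series,
        rate_hz=target_hz,
        pupil=trimmed.mean(axis=1),
        interp_mask=mask.any(axis=1),
    )
    if series.gaze_x is not None:
        out.gaze_x = series.gaze_x[: n_out * step].reshape(n_out, step).mean(axis=1)
    if series.gaze_y is not None:
        out.gaze_y = series.gaze_y[: n_out * step].reshape(n_out, step).mean(axis=1)
    return out


def zscore_series(series: SampleSeries) -> SampleSeries:
    """Session-wise z-transform (population-SD convention)."""
    sd = float(series.pupil.std())
    if sd == 0:
        raise PreprocessError("zero-variance series cannot be z-scored")
    z = (series.pupil - series.pupil.mean()) / sd
    return replace(series, pupil=z, interp_mask=series.interp_mask.copy())


def minute_bins(zseries: SampleSeries) -> np.ndarray:
    """Mean per whole minute; a trailing partial minute averages what exists."""
    per_min = zseries.rate_hz * 60
    n = zseries.pupil.size
    n_bins = int(np.ceil(n / per_min))
    return np.array(
        [zseries.pupil[i * per_min: (i + 1) * per_min].mean() for i in range(n_bins)]
    )


def preprocess_session(
    raw: SampleSeries,
    missing_code: float = 0.0,
    pad_ms: float = 100.0,
    order: int = 3,
    cutoff_hz: float = 4.0,
    target_hz: int = 50,
) -> tuple[SampleSeries, SampleSeries]:
    """Full chain; returns (50 Hz filtered a.u. series, its z-scored twin)."""
    blinks = detect_blinks(raw, missing_code)
    interp = extend_and_interpolate(raw, blinks, pad_ms)
    filt = lowpass_butterworth(interp, order, cutoff_hz)
    low = downsample(filt, target_hz)
    return low, zscore_series(low)
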