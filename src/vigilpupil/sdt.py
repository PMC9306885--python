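"""Signal detection theory summaries: hit/false-alarm rates, d' and c.

d' = z(H) - z(F) and c = -(z(H) + z(F)) / 2, with extreme rates clamped to
[1/(2n), 1 - 1/(2n)] before the inverse-normal transform so that perfect or
empty cells stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .classify import OutcomeTable

__all__ = ["SdtError", "SdtSummary", "rates", "dprime_criterion", "summarize_periods"]


class SdtError(ValueError):
    pass


@dataclass(frozen=True)
class SdtSummary:
    period: int
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion_c: float
    rt_mean_ms: float
    n_signal: int
    n_noise: int


def rates(outcomes: OutcomeTable, t0_ms: float = -np.inf, t1_ms: float = np.inf):
    """Hit and false-alarm rates (and counts) for events in [t0, t1)."""
    sub = outcomes.subset(t0_ms, t1_ms)
    n_hit = int((sub.outcome == "HIT").sum())
    n_miss = int((sub.outcome == "MISS").sum())
    n_fa = int((sub.outcome == "FA").sum())
    n_cr = int((sub.outcome == "CR").sum())
    n_signal, n_noise = n_hit + n_miss, n_fa + n_cr
    if n_signal == 0 or n_noise == 0:
        raise SdtError("no signal or no noise events in the requested window")
    return n_hit / n_signal, n_fa / n_noise, n_signal, n_noise


def dprime_criterion(
    hit_rate: float, fa_rate: float, n_signal: int, n_noise: int
) -> tuple[float, float]:
    """Sensitivity and criterion with 1/(2n) clamping of extreme rates."""
    h = float(np.clip(hit_rate, 1 / (2 * n_signal), 1 - 1 / (2 * n_signal)))
    f = float(np.clip(fa_rate, 1 / (2 * n_noise), 1 - 1 / (2 * n_noise)))
    zh, zf = norm.ppf(h), norm.ppf(f)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def summarize_periods(
    outcomes: OutcomeTable, duration_ms: float, n_periods: int = 3
) -> pd.DataFrame:
    """Per-watch-period SDT summary (plus the whole session as period 0)."""
    edges = np.linspace(0.0, duration_ms, n_periods + 1)
    windows = [(0, 0.0, duration_ms)] + [
        (i + 1, edges[i], edges[i + 1]) for i in range(n_periods)
    ]
    rows = []
    for period, t0, t1 in windows:
        h, f, ns, nn = rates(outcomes, t0, t1)
        d, c = dprime_criterion(h, f, ns, nn)
        sub = outcomes.subset(t0, t1)
        hit_rts = sub.loc[sub.outcome == "HIT", "rt_ms"]
        rows.append(
            SdtSummary(period, h, f, d, c,
                       float(hit_rts.mean()) if len(hit_rts) else np.nan, ns, nn)
        )
    return pd.DataFrame([r.__dict__ for r in rows])
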