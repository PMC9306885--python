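#!/usr/bin/env python
"""Simulate one observer per experiment and summarise the raw streams.

Writes per-session summary statistics (sampling rate, blink/interpolation
fractions, press counts, RT distribution) rather than the multi-megabyte
sample streams themselves; `vigilpupil simulate --out DIR` exports full
TSV streams when they are wanted.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from vigilpupil.pipeline import RunConfig, simulate_subject_exp1, simulate_subject_exp2

OUT = Path(__file__).resolve().parent.parent / "results" / "simulation"
OUT.mkdir(parents=True, exist_ok=True)


def summarise(name: str, subj: dict) -> dict:
    series = subj["series_au"]
    presses = subj["responses"].presses
    rt = subj["truth"].rt_ms
    rt = rt[np.isfinite(rt)]
    return dict(
        session=name,
        rate_hz=series.rate_hz,
        duration_min=series.pupil.size / series.rate_hz / 60.0,
        interpolated_fraction=series.interpolated_fraction,
        n_presses=presses.size,
        rt_median_ms=float(np.median(rt)),
        rt_p90_ms=float(np.quantile(rt, 0.9)),
        pupil_mean_au=float(series.pupil.mean()),
        pupil_cv=float(series.pupil.std() / series.pupil.mean()),
    )


def main() -> None:
    rows = []
    cfg1 = RunConfig(experiment=1, seed=11, n_subjects=1)
    rows.append(summarise("vigilance", simulate_subject_exp1(cfg1, cfg1.subject_seeds()[0])))
    cfg2 = RunConfig(experiment=2, seed=12, n_subjects=1)
    rows.append(summarise("pvt", simulate_subject_exp2(cfg2, cfg2.subject_seeds()[0])))
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "session_summaries.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nsummaries in {OUT}")


if __name__ == "__main__":
    main()
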