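"""Repeated-measures ANOVA, post hoc tests, correlations and bootstrap errors.

One- and two-factor within-subject ANOVAs report F, dfs, p, and partial eta
squared; where an effect has more than two levels, Mauchly's test gates a
Greenhouse-Geisser correction of the p-value (epsilon-scaled dfs).  The
repeated-measures machinery is delegated to pingouin; this module fixes the
reporting conventions (partial eta squared from F and the dfs, the Mauchly
p < .05 gate) and the output schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "AnovaResult",
    "rm_anova",
    "bonferroni_paired_t",
    "simple_main_effects",
    "pearson_r",
    "bootstrap_interval",
    "bootstrap_sem",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float
    mauchly_w: float = np.nan
    mauchly_p: float = np.nan
    gg_epsilon: float = np.nan
    gg_applied: bool = False


def _partial_eta_sq(F: float, df1: float, df2: float) -> float:
    # exact for balanced within designs: SS_e/(SS_e+SS_err) = F*df1/(F*df1+df2)
    return float(F * df1 / (F * df1 + df2))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str | list[str],
    subject: str,
    gg_gate_p: float = 0.05,
    always_gg: bool = False,
) -> list[AnovaResult]:
    """Within-subject ANOVA on a long-format table of cell means.

    Requires a complete balanced design (every subject in every cell);
    subjects with missing cells are dropped listwise.  For each effect with
    more than two levels, Mauchly's W is tested and the Greenhouse-Geisser
    corrected p is reported when its p falls below ``gg_gate_p`` (or always,
    with ``always_gg``).
    """
    within_list = [within] if isinstance(within, str) else list(within)
    cells = data.groupby([subject, *within_list], observed=True)[dv].mean().reset_index()
    n_cells = int(np.prod([cells[w].nunique() for w in within_list]))
    counts = cells.groupby(subject, observed=True).size()
    complete = counts[counts == n_cells].index
    if len(complete) < len(counts):
        cells = cells[cells[subject].isin(complete)]
    if len(complete) < 2:
        raise ValueError("fewer than 2 subjects with complete cells")

    n_subj = cells[subject].nunique()
    max_levels = max(cells[w].nunique() for w in within_list)
    # Mauchly/GG machinery needs more subjects than levels
    can_correct = n_subj > max_levels
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="Epsilon values might be innaccurate"
        )
        # degenerate (zero-variance) cells surface as 0/0 ratios handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.rm_anova(
            data=cells,
            dv=dv,
            within=within_list if len(within_list) > 1 else within_list[0],
            subject=subject,
            detailed=True,
            effsize="np2",
            correction=(can_correct if len(within_list) == 1 else "auto"),
        )
    results: list[AnovaResult] = []
    for _, row in aov.iterrows():
        if row["Source"] in ("Error", "Residual"):
            continue
        effect = str(row["Source"])
        if "ddof1" in aov.columns:  # two-way layout
            df1, df2 = float(row["ddof1"]), float(row["ddof2"])
        else:  # one-way layout: error row carries the denominator df
            df1 = float(row["DF"])
            err = aov[aov["Source"].isin(("Error", "Residual"))]
            df2 = float(err["DF"].iloc[0]) if len(err) else np.nan
        F = float(row["F"]) if "F" in aov.columns else np.nan
        p = float(row["p_unc"]) if "p_unc" in aov.columns else np.nan
        if not np.isfinite(F):
            # 0/0 mean square ratio: identical cell means, no evidence at all
            F, p = 0.0, 1.0
        eps = (
            float(row["eps"])
            if "eps" in aov.columns and np.isfinite(row.get("eps", np.nan))
            else np.nan
        )
        p_gg = (
            float(row["p_GG_corr"])
            if "p_GG_corr" in aov.columns and np.isfinite(row.get("p_GG_corr", np.nan))
            else np.nan
        )

        w = w_p = np.nan
        gg_applied = False
        if effect in within_list:
            n_levels = cells[effect].nunique()
            if n_levels > 2 and can_correct:
                collapsed = (
                    cells.groupby([subject, effect], observed=True)[dv]
                    .mean()
                    .reset_index()
                )
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        sph = pg.sphericity(
                            data=collapsed, dv=dv, within=effect, subject=subject
                        )
                    w, w_p = float(sph.W), float(sph.pval)
                except (ZeroDivisionError, ValueError):
                    w = w_p = np.nan
                if (always_gg or w_p < gg_gate_p) and np.isfinite(p_gg):
                    p = p_gg
                    gg_applied = True
        elif np.isfinite(p_gg):
            # interaction term: Mauchly for interactions is not exposed by the
            # backend, so the correction is gated on its epsilon departing
            # from sphericity
            if always_gg or (np.isfinite(eps) and eps < 0.95):
                p = p_gg
                gg_applied = True
        results.append(
            AnovaResult(
                effect=effect, F=F,
                df_num=df1 * eps if gg_applied and np.isfinite(eps) else df1,
                df_den=df2 * eps if gg_applied and np.isfinite(eps) else df2,
                p=p,
                partial_eta_sq=_partial_eta_sq(F, df1, df2),
                mauchly_w=w, mauchly_p=w_p, gg_epsilon=eps, gg_applied=gg_applied,
            )
        )
    return results


def bonferroni_paired_t(
    data: pd.DataFrame, dv: str, within: str, subject: str,
    pairs: list[tuple] | None = None,
) -> pd.DataFrame:
    """Paired t per level pair; p multiplied by the number of comparisons."""
    wide = data.pivot_table(index=subject, columns=within, values=dv, observed=True)
    levels = list(wide.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        x, y = wide[a].dropna(), wide[b].dropna()
        common = x.index.intersection(y.index)
        if len(common) < 2:
            raise ValueError(f"fewer than 2 paired observations for {a} vs {b}")
        diff = (x.loc[common] - y.loc[common]).to_numpy()
        if diff.std(ddof=1) == 0.0:
            # identical paired samples carry no evidence either way
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(x.loc[common], y.loc[common])
        rows.append(
            dict(level_a=a, level_b=b, n=len(common), t=float(t),
                 p_uncorrected=float(p), p_adjusted=min(float(p) * m, 1.0),
                 mean_difference=float((x.loc[common] - y.loc[common]).mean()))
        )
    return pd.DataFrame(rows)


def simple_main_effects(
    data: pd.DataFrame, dv: str, free: str, fix: str, subject: str, **kwargs
) -> pd.DataFrame:
    """One-way RM-ANOVA of ``free`` at each level of ``fix`` (per-slice error)."""
    rows = []
    for level, sub in data.groupby(fix, observed=True):
        res = rm_anova(sub, dv=dv, within=free, subject=subject, **kwargs)[0]
        rows.append(dict(fixed_level=level, F=res.F, df_num=res.df_num,
                         df_den=res.df_den, p=res.p,
                         partial_eta_sq=res.partial_eta_sq))
    return pd.DataFrame(rows)


def pearson_r(x, y) -> tuple[float, int, float]:
    """Product-moment correlation with df = n - 2 and a two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length sequences with at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), x.size - 2, float(p)


def _bootstrap_means(values, n_boot: int, seed: int) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    return values[idx].mean(axis=1)


def bootstrap_interval(
    values, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean, resampling participants."""
    means = _bootstrap_means(values, n_boot, seed)
    lo = (1 - level) / 2
    return (float(np.quantile(means, lo)), float(np.quantile(means, 1 - lo)))


def bootstrap_sem(values, n_boot: int = 5000, seed: int = 0) -> float:
    """SD of bootstrap means (the bootstrapped standard error of the mean)."""
    return float(_bootstrap_means(values, n_boot, seed).std(ddof=1))
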