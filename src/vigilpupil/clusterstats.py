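"""Cluster-based permutation tests on event-locked 1-D traces.

Pointwise t statistics (one-sample vs. 0, or paired-difference) are
thresholded at the two-tailed critical t for the sample's degrees of
freedom; contiguous supra-threshold runs of uniform sign form clusters whose
mass is the summed t.  The null distribution of the maximal |mass| is built
by random per-participant sign flips (one-sample) or condition swaps
(paired; equivalent to sign-flipping the differences), and each observed
cluster's corrected p is the inclusive proportion of permutations reaching
its |mass|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats

__all__ = [
    "Cluster",
    "ClusterResult",
    "pointwise_t",
    "form_clusters",
    "permutation_test",
]


@dataclass(frozen=True)
class Cluster:
    start_index: int
    end_index: int          # exclusive
    mass: float
    sign: int
    p_corrected: float = np.nan

    def extent_ms(self, t_rel_ms: np.ndarray) -> tuple[float, float]:
        return float(t_rel_ms[self.start_index]), float(t_rel_ms[self.end_index - 1])


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    t_threshold: float
    alpha: float
    max_mass_null: np.ndarray = field(repr=False, default=None)  # type: ignore

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected <= self.alpha]


def _one_sample_t(data: np.ndarray) -> np.ndarray:
    """Rowwise-vectorised one-sample t against 0; zero-variance points get 0."""
    n = data.shape[-2]
    mean = data.mean(axis=-2)
    sd = data.std(axis=-2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn("zero-variance time points set to t = 0", RuntimeWarning)
        t = np.where(bad, 0.0, t)
    return t


def pointwise_t(
    traces: np.ndarray,
    traces_b: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """t-value series and df.

    ``traces`` is (participants x time).  With ``traces_b`` given, a paired
    test of the within-participant differences is computed; otherwise a
    one-sample test against 0.  df = n - 1.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need a 2-D (participants x time) array with n >= 2")
    if traces_b is not None:
        traces_b = np.asarray(traces_b, dtype=float)
        if traces_b.shape != traces.shape:
            raise ValueError("paired conditions must have identical shape")
        traces = traces - traces_b
    return _one_sample_t(traces), traces.shape[0] - 1


def form_clusters(
    t_series: np.ndarray, df: int, alpha: float = 0.05
) -> tuple[list[Cluster], float]:
    """Maximal uniform-sign runs of |t| above the two-tailed critical t."""
    threshold = float(stats.t.ppf(1 - alpha / 2, df))
    clusters: list[Cluster] = []
    for sign in (1, -1):
        exceed = t_series * sign > threshold
        edges = np.diff(np.r_[0, exceed.astype(int), 0])
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            clusters.append(
                Cluster(int(s), int(e), float(t_series[s:e].sum()), sign)
            )
    clusters.sort(key=lambda c: c.start_index)
    return clusters, threshold


def _max_cluster_masses(t_matrix: np.ndarray, threshold: float) -> np.ndarray:
    """Maximal |cluster mass| per row of a (perms x time) t matrix, vectorised.

    Rows are separated by a sentinel column so runs never cross rows.
    """
    n_rows, n_t = t_matrix.shape
    out = np.zeros(n_rows)
    for sign in (1.0, -1.0):
        signed = t_matrix * sign
        padded = np.zeros((n_rows, n_t + 1))
        padded[:, :n_t] = np.where(signed > threshold, signed, 0.0)
        flat = padded.ravel()
        active = flat > 0
        edges = np.diff(np.r_[0, active.astype(int), 0])
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        if starts.size == 0:
            continue
        csum = np.r_[0.0, np.cumsum(flat)]
        masses = csum[ends] - csum[starts]
        rows = starts // (n_t + 1)
        np.maximum.at(out, rows, masses)
    return out


def permutation_test(
    traces: np.ndarray,
    traces_b: np.ndarray | None = None,
    n_perm: int = 1024,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-corrected permutation test (two-tailed).

    One-sample mode flips each participant's sign at random per permutation;
    paired mode swaps condition labels per participant, which reduces to sign
    flips on the difference traces.  When the 2^n possible flips do not exceed
    ``n_perm``, the full set is enumerated instead.  The corrected p uses the
    inclusive (+1) convention, so p >= 1/(n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    traces = np.asarray(traces, dtype=float)
    if traces_b is not None:
        traces = traces - np.asarray(traces_b, dtype=float)
    n = traces.shape[0]

    t_obs, df = pointwise_t(traces)
    observed, threshold = form_clusters(t_obs, df, alpha)

    if 2**n <= n_perm:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    flipped = signs[:, :, None] * traces[None, :, :]
    t_perm = _one_sample_t(flipped)
    null = _max_cluster_masses(t_perm, threshold)

    n_eff = null.size
    clusters = [
        Cluster(
            c.start_index, c.end_index, c.mass, c.sign,
            p_corrected=float((np.sum(null >= abs(c.mass)) + 1) / (n_eff + 1)),
        )
        for c in observed
    ]
    return ClusterResult(
        clusters=clusters,
        n_permutations=n_eff,
        t_threshold=threshold,
        alpha=alpha,
        max_mass_null=null,
    )
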