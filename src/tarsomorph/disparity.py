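"""Morphospace occupation (disparity) metrics and between-group tests.

Three complementary metrics quantify how a group of taxa fills an
ordination space: the sum of per-axis ranges (overall spread), the sum of
per-axis sample variances (dissimilarity around the group mean) and the
mean pairwise Euclidean distance (density of taxa relative to each other).
Bootstrap pseudoreplication gives confidence intervals; rarefaction
(resampling at reduced sizes) removes sample-size bias.  Groups are
compared with Wilcoxon rank-sum tests and Bhattacharyya overlap
coefficients on their bootstrap distributions, and with a
sample-size-respecting permutation test on the raw group difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu

METRICS = ("sum_of_ranges", "sum_of_variances", "mean_pairwise_distance")


def disparity_metric(scores, metric: str) -> float:
    """One disparity metric on a group's taxa × axes score matrix.

    sum_of_ranges = Σ_axes (max − min); sum_of_variances = Σ_axes sample
    variance (n−1); mean_pairwise_distance = mean Euclidean distance over
    all unordered taxon pairs.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("empty group")
    if metric == "sum_of_ranges":
        return float(np.sum(X.max(axis=0) - X.min(axis=0)))
    if metric == "sum_of_variances":
        if X.shape[0] == 1:
            return 0.0
        return float(np.sum(X.var(axis=0, ddof=1)))
    if metric == "mean_pairwise_distance":
        if X.shape[0] < 2:
            raise ValueError("mean pairwise distance needs at least 2 taxa")
        return float(pdist(X).mean())
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class DisparityResult:
    """Observed metric with bootstrap distribution and 95% CI."""

    group: str
    metric: str
    observed: float
    bootstrap_values: np.ndarray
    ci_low: float
    ci_high: float
    n_taxa: int
    seed: int
    rarefied_mean: float | None = None
    rarefaction_levels: dict[int, np.ndarray] = field(default_factory=dict)


def _resample_metric(
    X: np.ndarray, metric: str, size: int, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    vals = np.empty(n_boot)
    n = X.shape[0]
    for b in range(n_boot):
        idx = rng.integers(0, n, size=size)
        vals[b] = disparity_metric(X[idx], metric)
    return vals


def bootstrap_disparity(
    scores,
    metric: str,
    n_boot: int = 200,
    seed: int = 0,
    group: str = "",
) -> DisparityResult:
    """Bootstrap a disparity metric (resample taxa with replacement).

    ``n_boot`` pseudoreplicates at full group size; 95% CI from the 2.5 and
    97.5 empirical percentiles.  Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("bootstrap needs a group of >= 2 taxa")
    rng = np.random.default_rng(seed)
    vals = _resample_metric(X, metric, X.shape[0], n_boot, rng)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return DisparityResult(
        group=group,
        metric=metric,
        observed=disparity_metric(X, metric),
        bootstrap_values=vals,
        ci_low=float(lo),
        ci_high=float(hi),
        n_taxa=X.shape[0],
        seed=seed,
    )


def rarefied_disparity(
    scores,
    metric: str,
    level_range: tuple[int, int],
    n_boot: int = 200,
    seed: int = 0,
    group: str = "",
    with_replacement: bool = True,
) -> DisparityResult:
    """Rarefy a disparity metric over a range of subsample sizes.

    For each level n in ``level_range`` (inclusive), draw ``n_boot``
    subsamples of size n and evaluate the metric; ``rarefied_mean`` is the
    mean over levels of the per-level means, and the per-level
    distributions are retained for CI construction.  Subsampling is with
    replacement by default (bootstrap-style); a without-replacement mode is
    available for levels below the group size.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    n = X.shape[0]
    lo, hi = level_range
    if not (2 <= lo <= hi <= n):
        raise ValueError(f"invalid rarefaction range {level_range} for group of {n}")
    rng = np.random.default_rng(seed)
    levels: dict[int, np.ndarray] = {}
    for size in range(lo, hi + 1):
        if with_replacement:
            levels[size] = _resample_metric(X, metric, size, n_boot, rng)
        else:
            vals = np.empty(n_boot)
            for b in range(n_boot):
                idx = rng.choice(n, size=size, replace=False)
                vals[b] = disparity_metric(X[idx], metric)
            levels[size] = vals
    per_level_means = np.array([levels[s].mean() for s in sorted(levels)])
    pooled = np.concatenate([levels[s] for s in sorted(levels)])
    clo, chi = np.percentile(pooled, [2.5, 97.5])
    return DisparityResult(
        group=group,
        metric=metric,
        observed=disparity_metric(X, metric),
        bootstrap_values=levels[hi],
        ci_low=float(clo),
        ci_high=float(chi),
        n_taxa=n,
        seed=seed,
        rarefied_mean=float(per_level_means.mean()),
        rarefaction_levels=levels,
    )


def wilcoxon_ranksum(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test (midrank ties).

    Exact enumeration when n_a·n_b ≤ 400 and the pooled sample is tie-free,
    otherwise the tie-corrected normal approximation with continuity
    correction.  Returns (rank-sum statistic of the first sample, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input sample")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (a.size * b.size <= 400 and tie_free) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)


def bhattacharyya(values_a, values_b, n_bins: int | None = None) -> float:
    """Bhattacharyya coefficient between two samples via common binning.

    Both samples are histogrammed on ⌊√(n_a+n_b)⌋ equal-width bins (default
    rule) spanning the pooled range; the coefficient Σ√(f_a·f_b) of the
    relative frequencies lies in [0, 1] — 1 for identical distributions,
    0 for bin-separated supports.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input sample")
    if n_bins is None:
        n_bins = int(np.floor(np.sqrt(a.size + b.size)))
    n_bins = max(n_bins, 1)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    fa, _ = np.histogram(a, bins=edges)
    fb, _ = np.histogram(b, bins=edges)
    return float(np.sum(np.sqrt((fa / a.size) * (fb / b.size))))


def permutation_disparity_test(
    scores_a,
    scores_b,
    metric: str,
    n_perm: int = 10000,
    seed: int = 0,
    exhaustive: bool = False,
) -> dict:
    """Two-sided permutation test on the difference in group disparity.

    Observed statistic = disparity(a) − disparity(b), both computed without
    resampling; the null redistributes the pooled taxa into groups of the
    original sizes (so sample-size effects are respected) and recomputes the
    statistic.  p = (#{|null| ≥ |observed|} + 1)/(n_perm + 1) for sampled
    reassignments; with ``exhaustive=True`` every C(n, n_a) split is
    enumerated and p is the exact tail fraction (the identity split counts).
    """
    A = np.atleast_2d(np.asarray(scores_a, dtype=float))
    B = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("both groups need >= 2 taxa")
    pooled = np.vstack([A, B])
    n_a, n = A.shape[0], pooled.shape[0]
    observed = disparity_metric(A, metric) - disparity_metric(B, metric)
    if exhaustive:
        null = np.empty(comb(n, n_a))
        for i, idx_a in enumerate(combinations(range(n), n_a)):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            null[i] = disparity_metric(pooled[mask], metric) - disparity_metric(
                pooled[~mask], metric
            )
        p = np.count_nonzero(np.abs(null) >= np.abs(observed) - 1e-12) / len(null)
        n_used = len(null)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(n)
            null[i] = disparity_metric(pooled[perm[:n_a]], metric) - disparity_metric(
                pooled[perm[n_a:]], metric
            )
        p = (np.count_nonzero(np.abs(null) >= np.abs(observed)) + 1) / (n_perm + 1)
        n_used = n_perm
    return {
        "observed": float(observed),
        "expected": float(null.mean()),
        "p": float(p),
        "n_perm": n_used,
        "seed": seed,
    }
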