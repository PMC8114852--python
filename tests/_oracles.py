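"""Independent brute-force oracles shared by the test modules.

Each function here evaluates a definition directly (loops, enumeration,
grid search) and deliberately avoids the package's own code paths.
"""

from itertools import combinations

import numpy as np
from scipy.stats import boxcox_llf


def grid_lambda_oracle(x, step=0.001, lo=-5.0, hi=5.0):
    """Brute-force Box-Cox profile-likelihood grid search.

    Two-stage enumeration: a coarse 0.01 scan of the whole interval, then a
    full scan at ``step`` resolution around the coarse winner.
    """
    coarse = np.arange(lo, hi + 0.01, 0.01)
    lls = [boxcox_llf(lam, x) for lam in coarse]
    best = coarse[int(np.argmax(lls))]
    fine = np.arange(max(lo, best - 0.02), min(hi, best + 0.02) + step, step)
    lls = [boxcox_llf(lam, x) for lam in fine]
    return fine[int(np.argmax(lls))]


def brute_force_by(p):
    """Direct evaluation of the Benjamini–Yekutieli definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    adj = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * c_m / ranks[j] * p[j]) for j in range(m) if ranks[j] >= ranks[i]
        ]
        adj[i] = min(candidates)
    return adj


def _metric(X, metric):
    X = np.asarray(X, dtype=float)
    if metric == "sum_of_ranges":
        return float(np.sum(X.max(axis=0) - X.min(axis=0)))
    if metric == "sum_of_variances":
        return float(np.sum(X.var(axis=0, ddof=1)))
    if metric == "mean_pairwise_distance":
        n = X.shape[0]
        d = [
            np.sqrt(np.sum((X[i] - X[j]) ** 2))
            for i in range(n)
            for j in range(i + 1, n)
        ]
        return float(np.mean(d))
    raise ValueError(metric)


def exhaustive_disparity_p(A, B, metric):
    """Exact permutation p for the disparity difference by full enumeration."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    pooled = np.vstack([A, B])
    n, n_a = pooled.shape[0], A.shape[0]
    obs = _metric(A, metric) - _metric(B, metric)
    hits = total = 0
    for idx in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        stat = _metric(pooled[mask], metric) - _metric(pooled[~mask], metric)
        hits += abs(stat) >= abs(obs) - 1e-12
        total += 1
    return hits / total
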