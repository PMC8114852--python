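"""Pairwise PERMANOVA, Benjamini–Yekutieli FDR control, Bayes factor bounds.

Group separation in morphospace is tested with permutational MANOVA on
Euclidean distances between ordination scores: the pseudo-F statistic is
computed from pairwise squared distances and its null distribution from
random relabelling.  Raw p-values across the set of pairwise tests are
adjusted with the Benjamini–Yekutieli step-up procedure (valid under
arbitrary dependence), and each p-value is supplemented with the Bayes
factor bound 1/(−e·p·ln p), an upper bound on the odds in favour of the
alternative that a p-value can justify.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io import ValidationError


def permanova_pseudo_f(dist2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from a squared Euclidean distance matrix and group codes.

    SS_total = Σ_{i<j} d²_ij / N; SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g;
    F = (SS_between/(g−1)) / (SS_within/(N−g)).
    """
    N = len(codes)
    ss_total = dist2.sum() / (2.0 * N)
    ss_within = 0.0
    for k in range(n_groups):
        mask = codes == k
        n_k = int(mask.sum())
        if n_k < 2:
            raise ValidationError("PERMANOVA requires every group to have >= 2 members")
        ss_within += dist2[np.ix_(mask, mask)].sum() / (2.0 * n_k)
    ss_between = ss_total - ss_within
    g = n_groups
    return float((ss_between / (g - 1)) / (ss_within / (N - g)))


def _two_group_permutation_f(
    dist2: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized pseudo-F for random two-group relabellings."""
    N = dist2.shape[0]
    perms = np.empty((n_perm, N), dtype=bool)
    base = np.zeros(N, dtype=bool)
    base[:n_a] = True
    for i in range(n_perm):
        perms[i] = rng.permutation(base)
    Za = perms.astype(float)
    Zb = 1.0 - Za
    qa = np.einsum("pi,ij,pj->p", Za, dist2, Za)
    qb = np.einsum("pi,ij,pj->p", Zb, dist2, Zb)
    ss_within = qa / (2.0 * n_a) + qb / (2.0 * (N - n_a))
    ss_total = dist2.sum() / (2.0 * N)
    ss_between = ss_total - ss_within
    return (ss_between / 1.0) / (ss_within / (N - 2))


def pairwise_permanova(
    scores: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 1999,
    seed: int = 0,
    adjust: bool = True,
) -> pd.DataFrame:
    """All pairwise PERMANOVA tests between groups of score rows.

    For each pair of groups, Euclidean distances on their pooled scores give
    the observed pseudo-F; significance comes from ``n_perm`` random
    relabellings within the pair (subset permutation), with
    p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1).  Raw p-values are adjusted
    across pairs with Benjamini–Yekutieli and each raw p gets its Bayes
    factor bound.  Deterministic given ``seed``.
    """
    groups = pd.Series(groups).reindex(scores.index)
    if groups.isna().any():
        raise ValidationError("every score row needs a group label")
    labels = sorted(groups.unique())
    rows = []
    for pair_idx, (a, b) in enumerate(combinations(labels, 2)):
        sub = scores[groups.isin([a, b])]
        sub_groups = groups.loc[sub.index]
        n_a = int((sub_groups == a).sum())
        n_b = int((sub_groups == b).sum())
        if min(n_a, n_b) < 2:
            raise ValidationError(f"group {a if n_a < 2 else b!r} has fewer than 2 members")
        # order rows group-a first so the permutation base vector is simple
        sub = pd.concat([sub[sub_groups == a], sub[sub_groups == b]])
        dist2 = squareform(pdist(sub.to_numpy(dtype=float)) ** 2)
        codes = np.concatenate([np.zeros(n_a, dtype=int), np.ones(n_b, dtype=int)])
        f_obs = permanova_pseudo_f(dist2, codes, 2)
        rng = np.random.default_rng([seed, pair_idx])
        f_perm = _two_group_permutation_f(dist2, n_a, n_perm, rng)
        p = (np.count_nonzero(f_perm >= f_obs) + 1) / (n_perm + 1)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "F": f_obs,
                "p_raw": p,
                "n_perm": n_perm,
                "seed": seed,
            }
        )
    table = pd.DataFrame(rows)
    if adjust and len(table):
        table["p_BY"] = adjust_benjamini_yekutieli(table["p_raw"].to_numpy())
    table["BFB"] = [bayes_factor_bound(p) for p in table["p_raw"]]
    return table


def adjust_benjamini_yekutieli(p_values) -> np.ndarray:
    """Benjamini–Yekutieli step-up FDR adjustment.

    p_adj(i) = min over j with rank(j) ≥ rank(i) of
    min(1, m·c(m)/rank(j)·p(j)) with c(m) = Σ_{k≤m} 1/k.  Order-preserving,
    never below the raw p, valid under arbitrary dependence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]


def bayes_factor_bound(p: float) -> float:
    """Upper Bayes factor bound 1/(−e·p·ln p) for 0 < p < 1/e.

    Strictly decreasing in p on its domain, reaching exactly 1 at the
    boundary p = 1/e; beyond it the bound is uninformative (< 1) and NaN is
    returned as the undefined marker.
    """
    if not (0.0 < p):
        raise ValueError("p must be positive")
    if p > 1.0 / np.e:
        return float("nan")
    return float(1.0 / (-np.e * p * np.log(p)))
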