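"""Consensus trees and Blomberg's K phylogenetic signal.

Blomberg's K compares the observed ratio of (variance around the
phylogenetically weighted mean) to (variance of phylogenetically
independent contrasts) with the ratio expected under Brownian motion on
the supplied tree: K ≈ 1 when trait covariance tracks shared ancestry,
K ≪ 1 when the trait is independent of the tree.  Significance comes from
randomly permuting trait values across tips and asking how often the
permuted tree-fit (MSE under the Brownian covariance) beats the observed
one.

The tree used is a majority-rule consensus of a posterior sample of rooted,
node-dated trees; consensus here is clade-based (the input trees are
rooted), keeping exactly the clades present in more than the threshold
fraction of trees, with consensus branch lengths averaged over the trees
containing each clade.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

from .io import TreeSet, ValidationError


@dataclass
class PhyloCovariance:
    """Tip covariance structure under Brownian motion: shared root paths."""

    V: np.ndarray
    tip_order: list[str]

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        if V.shape[0] != V.shape[1] or V.shape[0] != len(self.tip_order):
            raise ValidationError("V must be square and match tip_order")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValidationError("V must be symmetric")
        self.V = V


@dataclass
class KResult:
    """Blomberg's K with its building blocks and (optionally) permutation p."""

    K: float
    MSE0: float
    MSE: float
    p: float | None = None
    n_randomizations: int | None = None
    seed: int | None = None


def majority_consensus(trees: TreeSet, threshold: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus of rooted trees.

    Keeps exactly the clades (tip subsets) present in strictly more than
    ``threshold`` of the trees; regions with no majority clade collapse to
    polytomies.  Consensus branch lengths are the mean of the clade's
    subtending branch length over the trees that contain it.  ``threshold``
    must lie in [0.5, 1) so retained clades are mutually compatible.
    """
    if not (0.5 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0.5, 1)")
    n_trees = len(trees)
    counts: dict[frozenset, int] = defaultdict(int)
    length_sums: dict[frozenset, float] = defaultdict(float)
    length_counts: dict[frozenset, int] = defaultdict(int)
    for tree in trees.trees:
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                clade = frozenset([node.taxon.label])
            else:
                clade = frozenset(
                    lf.taxon.label for lf in node.leaf_iter()
                )
            counts[clade] += 1
            if node.edge.length is not None:
                length_sums[clade] += node.edge.length
                length_counts[clade] += 1
    all_tips = frozenset(trees.tip_names)
    retained = [
        c for c, k in counts.items() if k > threshold * n_trees or c == all_tips
    ]
    retained.sort(key=len)
    # parent of each clade = the smallest retained clade strictly containing it
    ns = dendropy.TaxonNamespace(sorted(all_tips))
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: dict[frozenset, dendropy.Node] = {}
    for clade in retained:
        node = dendropy.Node()
        if len(clade) == 1:
            node.taxon = ns.get_taxon(next(iter(clade)))
        if length_counts[clade]:
            node.edge.length = length_sums[clade] / length_counts[clade]
        nodes[clade] = node
    for clade in retained:
        if clade == all_tips:
            continue
        parent = min(
            (c for c in retained if len(c) > len(clade) and clade < c),
            key=len,
        )
        nodes[parent].add_child(nodes[clade])
    tree.seed_node = nodes[all_tips]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def phylo_vcv(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian-motion tip covariance matrix from a rooted tree.

    V[i, j] is the depth (from the root) of the most recent common ancestor
    of tips i and j; the diagonal holds root-to-tip path lengths.
    """
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            bl = node.edge.length
            if bl is None:
                raise ValidationError("tree has a missing branch length")
            if bl < 0:
                raise ValidationError("tree has a negative branch length")
            depths[node] = depths[node.parent_node] + bl
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    order = {lb: i for i, lb in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))
    # for every internal node, tip pairs split across its children coalesce there
    leafsets: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = order[node.taxon.label]
            leafsets[node] = [i]
            V[i, i] = depths[node]
        else:
            child_sets = [leafsets[c] for c in node.child_nodes()]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            V[i, j] = V[j, i] = depths[node]
            leafsets[node] = [i for s in child_sets for i in s]
    return PhyloCovariance(V=V, tip_order=tips)


def blomberg_k(trait, V: PhyloCovariance | np.ndarray) -> KResult:
    """Blomberg's K for a continuous trait on a tree.

    With phylogenetic GLS mean â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1):
    MSE0 = (x−â)ᵀ(x−â)/(n−1), MSE = (x−â)ᵀV⁻¹(x−â)/(n−1), and
    K = (MSE0/MSE) / {[tr(V) − n/(1ᵀV⁻¹1)] / (n−1)}.  Under Brownian motion
    on the tree E[K] ≈ 1; on a star tree (V = c·I) K = 1 exactly.
    """
    if isinstance(V, PhyloCovariance):
        trait = pd.Series(trait)
        if set(trait.index) == set(V.tip_order):
            trait = trait.reindex(V.tip_order)
        V = V.V
    x = np.asarray(trait, dtype=float)
    n = len(x)
    if V.shape != (n, n):
        raise ValidationError("trait length does not match V")
    if np.ptp(x) == 0:
        raise ValidationError("constant trait: K undefined (MSE = 0)")
    try:
        cho = linalg.cho_factor(V)
    except linalg.LinAlgError as exc:
        raise ValidationError("singular phylogenetic covariance") from exc
    ones = np.ones(n)
    Vinv_x = linalg.cho_solve(cho, x)
    Vinv_1 = linalg.cho_solve(cho, ones)
    c = float(ones @ Vinv_1)
    ahat = float(ones @ Vinv_x) / c
    resid = x - ahat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ linalg.cho_solve(cho, resid)) / (n - 1)
    expected_ratio = (np.trace(V) - n / c) / (n - 1)
    K = (mse0 / mse) / expected_ratio
    return KResult(K=float(K), MSE0=mse0, MSE=mse)


def k_significance(
    trait,
    V: PhyloCovariance | np.ndarray,
    n_randomizations: int,
    seed: int = 0,
) -> KResult:
    """Permutation significance for Blomberg's K.

    Trait values are shuffled across tips; a lower MSE (variance of the
    GLS residuals under the Brownian covariance) indicates a better fit of
    trait to tree, so p = (#{MSE_perm ≤ MSE_obs} + 1)/(n_rand + 1).
    Deterministic given ``seed``.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    if isinstance(V, PhyloCovariance):
        trait = pd.Series(trait)
        if set(trait.index) == set(V.tip_order):
            trait = trait.reindex(V.tip_order)
        V = V.V
    x = np.asarray(trait, dtype=float)
    res = blomberg_k(x, V)
    n = len(x)
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_randomizations))
    for j in range(n_randomizations):
        perms[:, j] = rng.permutation(x)
    cho = linalg.cho_factor(V)
    ones = np.ones(n)
    Vinv_P = linalg.cho_solve(cho, perms)
    Vinv_1 = linalg.cho_solve(cho, ones)
    c = float(ones @ Vinv_1)
    num = ones @ Vinv_P  # 1'V^-1 x_j per permutation
    # (x−â1)'V⁻¹(x−â1) = x'V⁻¹x − (1'V⁻¹x)²/c
    quad = np.einsum("ij,ij->j", perms, Vinv_P) - num**2 / c
    mse_perm = quad / (n - 1)
    p = (np.count_nonzero(mse_perm <= res.MSE) + 1) / (n_randomizations + 1)
    return KResult(
        K=res.K,
        MSE0=res.MSE0,
        MSE=res.MSE,
        p=float(p),
        n_randomizations=n_randomizations,
        seed=seed,
    )
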