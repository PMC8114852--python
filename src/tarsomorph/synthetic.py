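"""Synthetic measurement tables and trees with known ground truth.

The generator emulates the structure of the study system: 85 extant taxa in
six locomotor groups, 40 Palaeocene and 5 Cretaceous fossil taxa displaced
toward "robust" morphologies outside the extant clusters, 29 strictly
positive linear measurements sharing a common allometric size factor, and
ultrametric birth–death trees carrying Brownian-motion traits.

The data model: each taxon has a latent shape vector s drawn from its
group's multivariate normal (fossils get an additional offset along a
latent direction orthogonal to every group-mean axis, and inflated
covariance), plus a latent log-size z ~ N(0, size_log_sd²); measurement j
is exp((L·s)_j + intercept_j + allometry_j·z), so size acts as a
multiplicative confounder that the geometric-mean correction removes
exactly when all allometry exponents are 1.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io import LOCOMOTOR_MODES, MeasurementTable, TreeSet

#: Fixed RNG stream for structural constants (loading matrix, intercepts,
#: group-mean directions) so they do not vary with the simulation seed.
_STRUCTURE_SEED = 718281828

#: Fossil true-group sampling weights, matching the study's reported
#: plurality of ground-dwelling classifications.
_PALAEOCENE_GROUP_WEIGHTS = {
    "terrestrial": 19 / 45,
    "semi-fossorial": 13 / 45,
    "arboreal": 9 / 45,
    "scansorial": 4 / 45,
}
_CRETACEOUS_GROUP_WEIGHTS = {"terrestrial": 0.5, "arboreal": 0.5}


@dataclass
class SimConfig:
    """Parameters of the synthetic study system (defaults = study layout)."""

    n_extant_per_group: tuple[int, ...] = (15, 14, 14, 14, 14, 14)
    n_palaeocene: int = 40
    n_cretaceous: int = 5
    n_variables: int = 29
    n_latent: int = 8
    group_sep: float = 3.0  # group-mean separation in within-group sds
    group_means: np.ndarray | None = None  # 6 × n_latent
    within_cov: np.ndarray | None = None  # n_latent × n_latent
    fossil_offset: np.ndarray | None = None  # latent displacement of fossils
    fossil_offset_sd: float = 5.0  # magnitude of default offset
    cretaceous_shift: float = 2.0  # extra Cretaceous displacement
    fossil_cov_scale: float = 1.5
    size_log_sd: float = 0.3
    allometry: np.ndarray | None = None  # per-variable size exponents
    seed: int = 0
    group_labels: tuple[str, ...] = field(default=LOCOMOTOR_MODES)

    def __post_init__(self) -> None:
        if len(self.n_extant_per_group) != len(self.group_labels):
            raise ValueError("one extant count per locomotor group required")
        if self.n_latent < len(self.group_labels) + 2:
            raise ValueError("need n_latent >= n_groups + 2 latent factors")
        if min(self.n_extant_per_group) < 0 or self.n_palaeocene < 0 or self.n_cretaceous < 0:
            raise ValueError("counts must be >= 0")
        g = len(self.group_labels)
        if self.group_means is None:
            # orthogonal group-mean directions on the first g latent axes
            self.group_means = self.group_sep * np.eye(self.n_latent)[:g]
        self.group_means = np.asarray(self.group_means, dtype=float)
        if self.within_cov is None:
            self.within_cov = np.eye(self.n_latent)
        self.within_cov = np.asarray(self.within_cov, dtype=float)
        eigs = np.linalg.eigvalsh(self.within_cov)
        if eigs.min() < -1e-10:
            raise ValueError("within_cov must be positive semidefinite")
        if self.fossil_offset is None:
            # displacement along latent axis g (orthogonal to all group means):
            # fossils occupy their own region while staying nearest their
            # generating group among the extant clusters
            off = np.zeros(self.n_latent)
            off[g] = self.fossil_offset_sd
            self.fossil_offset = off
        self.fossil_offset = np.asarray(self.fossil_offset, dtype=float)
        if self.allometry is None:
            self.allometry = np.ones(self.n_variables)
        self.allometry = np.asarray(self.allometry, dtype=float)
        if self.fossil_cov_scale < 1.0:
            raise ValueError("fossil_cov_scale must be >= 1")


def _psd_factor(C: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix (handles the zero-covariance case)."""
    w, U = np.linalg.eigh(C)
    return U @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _structure(config: SimConfig):
    rng = np.random.default_rng(_STRUCTURE_SEED)
    L = rng.normal(0.0, 1.0 / np.sqrt(config.n_latent), (config.n_latent, config.n_variables))
    intercepts = rng.uniform(np.log(3.0), np.log(25.0), config.n_variables)
    return L, intercepts


def generate_measurements(config: SimConfig) -> tuple[MeasurementTable, pd.DataFrame]:
    """Draw a full synthetic measurement table plus its ground truth.

    Returns ``(table, truth)`` where ``truth`` holds each taxon's true
    latent group, time subset and log-size.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    L, intercepts = _structure(config)
    factor = _psd_factor(config.within_cov)
    g = len(config.group_labels)

    names, time_subset, locomotor, true_group, latents, sizes = [], [], [], [], [], []

    def draw(mean_latent, cov_scale, n):
        z = rng.standard_normal((n, config.n_latent))
        return mean_latent + np.sqrt(cov_scale) * (z @ factor.T)

    for k, label in enumerate(config.group_labels):
        n_k = config.n_extant_per_group[k]
        lat = draw(config.group_means[k], 1.0, n_k)
        for i in range(n_k):
            names.append(f"Extant_{label.replace('-', '')}_{i + 1:02d}")
            time_subset.append("extant")
            locomotor.append(label)
            true_group.append(label)
            latents.append(lat[i])

    for subset, n_fossil, weights, shift in (
        ("Palaeocene", config.n_palaeocene, _PALAEOCENE_GROUP_WEIGHTS, 0.0),
        ("Cretaceous", config.n_cretaceous, _CRETACEOUS_GROUP_WEIGHTS, config.cretaceous_shift),
    ):
        pool = list(weights)
        probs = np.array([weights[lb] for lb in pool])
        picks = rng.choice(len(pool), size=n_fossil, p=probs / probs.sum())
        for i in range(n_fossil):
            label = pool[picks[i]]
            k = config.group_labels.index(label)
            mean = config.group_means[k] + config.fossil_offset
            if shift:
                extra = np.zeros(config.n_latent)
                extra[g + 1] = shift
                mean = mean + extra
            lat = draw(mean, config.fossil_cov_scale, 1)[0]
            names.append(f"{subset}_{i + 1:02d}")
            time_subset.append(subset)
            locomotor.append(np.nan)
            true_group.append(label)
            latents.append(lat)

    latents = np.asarray(latents)
    n = len(names)
    logsize = rng.normal(0.0, config.size_log_sd, n)
    log_meas = latents @ L + intercepts + np.outer(logsize, config.allometry)
    meas = pd.DataFrame(
        np.exp(log_meas),
        index=pd.Index(names, name="taxon"),
        columns=[f"M{j + 1:02d}" for j in range(config.n_variables)],
    )
    idx = meas.index
    table = MeasurementTable(
        meas,
        pd.Series(time_subset, index=idx),
        pd.Series(locomotor, index=idx, dtype=object),
    )
    truth = pd.DataFrame(
        {
            "time_subset": time_subset,
            "true_group": true_group,
            "log_size": logsize,
            "is_fossil": [t != "extant" for t in time_subset],
        },
        index=idx,
    )
    return table, truth


def simulate_bd_tree(
    n_tips: int, birth: float = 1.0, death: float = 0.5, seed: int = 0
) -> dendropy.Tree:
    """Rooted ultrametric birth–death tree conditioned on ``n_tips`` survivors."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not (birth > death >= 0):
        raise ValueError("rates must satisfy birth > death >= 0")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_tips,
        rng=rng,
        repeat_until_success=True,
    )
    # the simulator stops exactly at the nth speciation, leaving the youngest
    # divergence at age zero; run the clock forward by the waiting time to the
    # next event so all divergences have positive age (tree stays ultrametric)
    dt = rng.expovariate(n_tips * (birth + death))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + dt
    return tree


def simulate_tree_set(
    labels,
    n_trees: int,
    birth: float = 1.0,
    death: float = 0.5,
    seed: int = 0,
) -> TreeSet:
    """A sample of birth–death trees relabelled with the given tip names."""
    labels = list(labels)
    ns = dendropy.TaxonNamespace(labels)
    trees = dendropy.TreeList(taxon_namespace=ns)
    for t in range(n_trees):
        tree = simulate_bd_tree(len(labels), birth, death, seed=seed * 100003 + t)
        shuffled = list(labels)
        random.Random(seed * 99991 + t).shuffle(shuffled)
        for leaf, name in zip(tree.leaf_node_iter(), shuffled):
            leaf.taxon.label = name
        trees.append(
            dendropy.Tree.get(
                data=tree.as_string(schema="newick"),
                schema="newick",
                taxon_namespace=ns,
            )
        )
    return TreeSet(trees)


def simulate_bm_trait(
    tree: dendropy.Tree, sigma2: float = 1.0, seed: int = 0, root_state: float = 0.0
) -> pd.Series:
    """Brownian-motion trait on a tree: Gaussian increments per branch.

    Increment variance along a branch is ``sigma2`` × branch length, so the
    tip covariance equals ``sigma2`` × the Brownian tip covariance matrix.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = np.random.default_rng(seed)
    values: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = root_state
        else:
            bl = node.edge.length
            if bl is None:
                raise ValueError("tree has a missing branch length")
            values[node] = values[node.parent_node] + rng.normal(
                0.0, np.sqrt(sigma2 * bl)
            )
    tips = {lf.taxon.label: values[lf] for lf in tree.leaf_node_iter()}
    return pd.Series(tips)
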