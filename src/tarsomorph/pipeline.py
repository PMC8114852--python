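"""End-to-end analysis pipeline driven by a YAML/dict configuration.

Stage order: read/validate → standardize → PCA → LDA + fossil projection →
RDA optimization + fossil classification → pairwise PERMANOVA (+BY, +BFB)
on PC and DF scores → Blomberg's K per axis (if trees supplied) →
disparity suite per time subset → manifest.  One global seed expands into
per-stage seeds through a fixed counter scheme so any stage can be rerun in
isolation; every output is a CSV (or Newick) plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .disparity import (
    METRICS,
    bhattacharyya,
    bootstrap_disparity,
    permutation_disparity_test,
    rarefied_disparity,
    wilcoxon_ranksum,
)
from .group_tests import adjust_benjamini_yekutieli, bayes_factor_bound, pairwise_permanova
from .io import (
    MeasurementTable,
    read_measurement_table,
    read_trees,
    validate_against_tree,
    write_measurement_table,
    write_trees,
)
from .ordination import classify, da_project, lda_fit, pca_covariance, rda_optimize
from .phylosignal import k_significance, majority_consensus, phylo_vcv
from .preprocess import standardize_table
from .synthetic import SimConfig, generate_measurements, simulate_tree_set

STAGES = (
    "load",
    "standardize",
    "pca",
    "lda",
    "rda",
    "permanova",
    "phylosignal",
    "disparity",
)

DEFAULT_CONFIG = {
    "standardization": {"mode": "gm-boxcox-z", "interval": [-5.0, 5.0]},
    "rda": {"grid": 21, "scheme": "crossval", "folds": 10, "n_boot": 25,
            "priors": "proportional"},
    "permanova": {"n_perm": 1999},
    "blomberg": {"n_randomizations": 9999, "n_axes": 3},
    "disparity": {"n_boot": 200, "metrics": list(METRICS)},
    "seed": 0,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed (counter scheme)."""
    idx = STAGES.index(stage)
    return int(
        np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0]
        % (2**31)
    )


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    return _merge(DEFAULT_CONFIG, config or {})


def run_pipeline(
    config,
    out_dir: str | Path,
    seed: int | None = None,
    stages=None,
) -> Path:
    """Run the analysis end to end; returns the output directory.

    ``config`` is a YAML path or dict (see ``DEFAULT_CONFIG`` for knobs and
    the ``input``/``simulate`` sections for data sources).  ``stages``
    optionally restricts which stages run (prerequisites always run).
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    global_seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    selected = set(stages or STAGES)
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "global_seed": global_seed,
        "stage_seeds": {s: stage_seed(global_seed, s) for s in STAGES},
        "inputs": {},
        "outputs": [],
        "stages_run": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def emit(name: str, df: pd.DataFrame, index_label="taxon"):
        path = out / name
        df.to_csv(path, index_label=index_label)
        manifest["outputs"].append(name)

    # -- load ---------------------------------------------------------------
    trees = None
    if "simulate" in cfg:
        sim_cfg = SimConfig(**{**cfg["simulate"].get("measurements", {}),
                               "seed": stage_seed(global_seed, "load")})
        table, truth = generate_measurements(sim_cfg)
        write_measurement_table(table, out / "measurements.csv", seed=sim_cfg.seed)
        truth.to_csv(out / "truth.csv", index_label="taxon")
        manifest["outputs"] += ["measurements.csv", "truth.csv"]
        tree_cfg = cfg["simulate"].get("trees")
        if tree_cfg:
            extant = table.measurements.index[~table.is_fossil]
            trees = simulate_tree_set(
                extant,
                n_trees=tree_cfg.get("n_trees", 50),
                birth=tree_cfg.get("birth", 1.0),
                death=tree_cfg.get("death", 0.5),
                seed=stage_seed(global_seed, "load"),
            )
            write_trees(trees, out / "trees.nwk")
            manifest["outputs"].append("trees.nwk")
    else:
        meas_path = Path(cfg["input"]["measurements"])
        table = read_measurement_table(
            meas_path, allow_missing=cfg.get("input", {}).get("allow_missing", False)
        )
        manifest["inputs"][str(meas_path)] = _sha256(meas_path)
        tree_path = cfg["input"].get("trees")
        if tree_path:
            trees = read_trees(tree_path)
            manifest["inputs"][str(tree_path)] = _sha256(Path(tree_path))
    if trees is not None:
        manifest["tree_validation"] = validate_against_tree(table, trees)
    manifest["stages_run"].append("load")

    # -- standardize --------------------------------------------------------
    std = cfg["standardization"]
    shape = standardize_table(
        table,
        mode=std["mode"],
        interval=tuple(std["interval"]),
        impute_missing=std.get("impute_missing", False),
    )
    shape.to_csv(out / "shape_matrix.csv")
    manifest["outputs"] += ["shape_matrix.csv", "shape_matrix.constants.csv"]
    manifest["stages_run"].append("standardize")

    extant_mask = ~table.is_fossil
    extant_shape = shape.values[extant_mask]
    fossil_shape = shape.values[~extant_mask]

    # -- pca ----------------------------------------------------------------
    pca = pca_covariance(shape)
    emit("pca_scores.csv", pca.scores)
    emit("pca_axes.csv", pca.axes, index_label="variable")
    emit(
        "pca_variance.csv",
        pd.DataFrame(
            {"axis": pca.scores.columns, "variance_fraction": pca.variance_fraction}
        ).set_index("axis"),
        index_label="axis",
    )
    manifest["stages_run"].append("pca")

    # -- lda + fossil superimposition --------------------------------------
    loco = table.locomotor[extant_mask]
    da, lda_model = lda_fit(extant_shape, loco)
    df_scores = pd.concat([da.scores, da_project(da, fossil_shape)])
    df_scores = df_scores.loc[shape.values.index]
    emit("df_scores.csv", df_scores)
    emit("df_axes.csv", da.axes, index_label="variable")
    emit(
        "df_variance.csv",
        pd.DataFrame(
            {"axis": da.scores.columns, "variance_fraction": da.variance_fraction}
        ).set_index("axis"),
        index_label="axis",
    )
    manifest["stages_run"].append("lda")

    # -- rda ----------------------------------------------------------------
    rda_cfg = cfg["rda"]
    grid_n = rda_cfg["grid"]
    ticks = np.linspace(0.0, 1.0, grid_n)
    grid = [(g, l) for g in ticks for l in ticks]
    model = rda_optimize(
        extant_shape,
        loco,
        grid=grid,
        scheme=rda_cfg["scheme"],
        folds=rda_cfg["folds"],
        n_boot=rda_cfg["n_boot"],
        seed=stage_seed(global_seed, "rda"),
        priors=rda_cfg["priors"],
    )
    fossil_pred, fossil_post = classify(model, fossil_shape)
    cls = fossil_post.copy()
    cls.insert(0, "predicted", fossil_pred)
    cls.insert(1, "time_subset", table.time_subset[~extant_mask])
    emit("rda_classification.csv", cls)
    manifest["rda"] = {
        "gamma": model.gamma,
        "lambda": model.lam,
        "error_estimates": model.error_estimates,
    }
    manifest["stages_run"].append("rda")

    # -- permanova ----------------------------------------------------------
    if "permanova" in selected:
        n_perm = cfg["permanova"]["n_perm"]
        pm_seed = stage_seed(global_seed, "permanova")
        pc_groups = table.time_subset
        emit(
            "permanova_pc.csv",
            pairwise_permanova(pca.scores, pc_groups, n_perm, pm_seed),
            index_label="row",
        )
        # DF space: extant locomotor groups plus fossils under RDA prediction
        df_groups = table.locomotor.copy()
        df_groups.loc[fossil_pred.index] = fossil_pred
        big_enough = df_groups.map(df_groups.value_counts()) >= 2
        emit(
            "permanova_df.csv",
            pairwise_permanova(
                df_scores[big_enough], df_groups[big_enough], n_perm, pm_seed
            ),
            index_label="row",
        )
        manifest["stages_run"].append("permanova")

    # -- phylosignal --------------------------------------------------------
    if "phylosignal" in selected and trees is not None:
        bl_cfg = cfg["blomberg"]
        consensus = majority_consensus(trees)
        consensus.write(path=str(out / "consensus.nwk"), schema="newick")
        manifest["outputs"].append("consensus.nwk")
        vcv = phylo_vcv(consensus)
        rows = []
        ps_seed = stage_seed(global_seed, "phylosignal")
        for space, sc in (("PC", pca.scores), ("DF", df_scores)):
            sub = sc.loc[extant_mask[extant_mask].index]
            for axis in sub.columns[: bl_cfg["n_axes"]]:
                res = k_significance(
                    sub[axis], vcv, bl_cfg["n_randomizations"], seed=ps_seed
                )
                rows.append(
                    {
                        "axis": axis,
                        "space": space,
                        "K": res.K,
                        "p": res.p,
                        "BFB": bayes_factor_bound(res.p),
                        "n_randomizations": res.n_randomizations,
                        "seed": ps_seed,
                    }
                )
        emit("blomberg_k.csv", pd.DataFrame(rows).set_index("axis"), index_label="axis")
        manifest["stages_run"].append("phylosignal")
    elif "phylosignal" in selected:
        manifest["skipped"] = manifest.get("skipped", []) + [
            "phylosignal (no trees supplied)"
        ]

    # -- disparity ----------------------------------------------------------
    if "disparity" in selected:
        d_cfg = cfg["disparity"]
        d_seed = stage_seed(global_seed, "disparity")
        groups = table.time_subset
        present = [g for g in groups.unique() if (groups == g).sum() >= 2]
        min_n = min((groups == g).sum() for g in present)
        res_rows, cmp_rows = [], []
        for space, sc in (("PC", pca.scores), ("DF", df_scores)):
            boots = {}
            for grp in present:
                X = sc[groups == grp].to_numpy()
                for metric in d_cfg["metrics"]:
                    br = bootstrap_disparity(
                        X, metric, n_boot=d_cfg["n_boot"], seed=d_seed, group=grp
                    )
                    rr = rarefied_disparity(
                        X,
                        metric,
                        (max(2, min_n), X.shape[0]),
                        n_boot=d_cfg["n_boot"],
                        seed=d_seed,
                        group=grp,
                    )
                    boots[(grp, metric)] = br.bootstrap_values
                    res_rows.append(
                        {
                            "space": space,
                            "group": grp,
                            "metric": metric,
                            "observed": br.observed,
                            "rarefied_mean": rr.rarefied_mean,
                            "ci_low": br.ci_low,
                            "ci_high": br.ci_high,
                            "n_taxa": br.n_taxa,
                            "n_boot": d_cfg["n_boot"],
                            "seed": d_seed,
                        }
                    )
            for metric in d_cfg["metrics"]:
                pvals = []
                for a in present:
                    for b in present:
                        if a >= b:
                            continue
                        w_stat, w_p = wilcoxon_ranksum(
                            boots[(a, metric)], boots[(b, metric)]
                        )
                        bc = bhattacharyya(boots[(a, metric)], boots[(b, metric)])
                        perm = permutation_disparity_test(
                            sc[groups == a].to_numpy(),
                            sc[groups == b].to_numpy(),
                            metric,
                            n_perm=d_cfg.get("n_perm", 10000),
                            seed=d_seed,
                        )
                        cmp_rows.append(
                            {
                                "space": space,
                                "group_a": a,
                                "group_b": b,
                                "metric": metric,
                                "wilcoxon_p": w_p,
                                "bhattacharyya": bc,
                                "permutation_p": perm["p"],
                                "BFB": bayes_factor_bound(perm["p"]),
                            }
                        )
                        pvals.append(perm["p"])
        cmp_df = pd.DataFrame(cmp_rows)
        if len(cmp_df):
            cmp_df["permutation_p_BY"] = adjust_benjamini_yekutieli(
                cmp_df["permutation_p"].to_numpy()
            )
        emit("disparity.csv", pd.DataFrame(res_rows), index_label="row")
        emit("disparity_comparisons.csv", cmp_df, index_label="row")
        manifest["stages_run"].append("disparity")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
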