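"""Core data containers and delimited-text / Newick input-output.

The two containers defined here — :class:`MeasurementTable` for the
taxa × linear-measurement matrix with its per-taxon metadata, and
:class:`TreeSet` for a sample of rooted, branch-length-bearing phylogenies —
are what every downstream stage (standardization, ordination, group tests,
phylogenetic signal, disparity) consumes.  All validation happens here, before
any statistics run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import __version__

TIME_SUBSETS = ("Cretaceous", "Palaeocene", "extant")
LOCOMOTOR_MODES = (
    "arboreal",
    "cursorial",
    "scansorial",
    "semi-aquatic",
    "semi-fossorial",
    "terrestrial",
)
#: Reserved metadata column names in a measurement CSV; every other column is
#: treated as a measurement.
METADATA_COLUMNS = ("time_subset", "locomotor", "clade")


class ValidationError(ValueError):
    """A table or tree set violates one of its structural invariants."""


def _header_comment(seed: int | None) -> str:
    return f"# tarsomorph {__version__} seed={seed}\n"


@dataclass
class MeasurementTable:
    """Taxa × measurement matrix with per-taxon metadata.

    Parameters
    ----------
    measurements
        DataFrame indexed by unique taxon identifiers; columns are named
        linear measurements in mm.  Values must be strictly positive and
        finite; NaN marks a missing cell (tolerated by the container,
        rejected by downstream stages unless imputation is requested).
    time_subset
        Per-taxon category in ``{"Cretaceous", "Palaeocene", "extant"}``.
    locomotor
        Per-taxon locomotor mode for extant taxa (one of
        :data:`LOCOMOTOR_MODES`); NaN for fossils.
    clade
        Optional per-taxon clade label (e.g. marsupial/placental).
    """

    measurements: pd.DataFrame
    time_subset: pd.Series
    locomotor: pd.Series | None = None
    clade: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.locomotor is None:
            self.locomotor = pd.Series(
                np.nan, index=self.measurements.index, dtype=object
            )
        self.measurements = self.measurements.astype(float)
        self.time_subset = self.time_subset.reindex(self.measurements.index)
        self.locomotor = self.locomotor.reindex(self.measurements.index)
        if self.clade is not None:
            self.clade = self.clade.reindex(self.measurements.index)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        idx = self.measurements.index
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon identifiers: {dupes}")
        vals = self.measurements.to_numpy()
        bad = ~(np.isnan(vals) | (np.isfinite(vals) & (vals > 0)))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                "non-positive or non-finite measurement at "
                f"taxon {idx[i]!r}, column {self.measurements.columns[j]!r}"
            )
        if self.time_subset.isna().any():
            missing = idx[self.time_subset.isna()].tolist()
            raise ValidationError(f"taxa without a time subset: {missing}")
        unknown = set(self.time_subset) - set(TIME_SUBSETS)
        if unknown:
            raise ValidationError(f"unknown time subsets: {sorted(unknown)}")
        extant = self.time_subset == "extant"
        loco = self.locomotor[extant]
        if loco.isna().any():
            missing = loco.index[loco.isna()].tolist()
            raise ValidationError(f"extant taxa without a locomotor label: {missing}")
        unknown = set(loco) - set(LOCOMOTOR_MODES)
        if unknown:
            raise ValidationError(f"unknown locomotor modes: {sorted(unknown)}")

    # -- convenience --------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(self.measurements.index)

    @property
    def n_taxa(self) -> int:
        return len(self.measurements)

    @property
    def is_fossil(self) -> pd.Series:
        return self.time_subset != "extant"

    def subset(self, taxa: Sequence[str]) -> "MeasurementTable":
        taxa = list(taxa)
        return MeasurementTable(
            self.measurements.loc[taxa],
            self.time_subset.loc[taxa],
            self.locomotor.loc[taxa],
            None if self.clade is None else self.clade.loc[taxa],
        )

    def extant(self) -> "MeasurementTable":
        return self.subset(self.measurements.index[~self.is_fossil])

    def fossils(self) -> "MeasurementTable":
        return self.subset(self.measurements.index[self.is_fossil])

    def has_missing(self) -> bool:
        return bool(self.measurements.isna().to_numpy().any())


@dataclass
class TreeSet:
    """A sample of rooted trees sharing one tip set (branch lengths in time)."""

    trees: dendropy.TreeList
    tip_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.trees) == 0:
            raise ValidationError("empty tree set")
        tip_sets = [
            frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in self.trees
        ]
        ref = tip_sets[0]
        for k, s in enumerate(tip_sets[1:], start=2):
            if s != ref:
                diff = sorted((s - ref) | (ref - s))
                raise ValidationError(
                    f"tree {k} has a different tip set (symmetric difference {diff})"
                )
        for t in self.trees:
            for e in t.preorder_edge_iter():
                if e.length is not None and e.length < 0:
                    raise ValidationError("negative branch length")
        self.tip_names = tuple(sorted(ref))

    def __len__(self) -> int:
        return len(self.trees)


# -- readers / writers ------------------------------------------------------


def read_measurement_table(
    path: str | Path,
    schema: Sequence[str] | None = None,
    delimiter: str = ",",
    allow_missing: bool = False,
) -> MeasurementTable:
    """Read a delimited measurement table (header row, one row per taxon).

    ``schema`` optionally lists the measurement columns in canonical order;
    the returned table's columns follow it.  Columns named in
    :data:`METADATA_COLUMNS` carry metadata; everything else is a measurement.
    """
    df = pd.read_csv(path, sep=delimiter, comment="#", index_col=0)
    meta = {c: df[c] for c in METADATA_COLUMNS if c in df.columns}
    if "time_subset" not in meta:
        raise ValidationError("missing required column 'time_subset'")
    meas_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    if schema is not None:
        missing = [c for c in schema if c not in meas_cols]
        if missing:
            raise ValidationError(f"missing required measurement columns: {missing}")
        meas_cols = list(schema)
    meas = df[meas_cols]
    for col in meas_cols:
        coerced = pd.to_numeric(meas[col], errors="coerce")
        bad = coerced.isna() & meas[col].notna()
        if bad.any():
            raise ValidationError(
                f"non-numeric measurement at taxon {meas.index[bad][0]!r}, "
                f"column {col!r}"
            )
    meas = meas.apply(pd.to_numeric)
    table = MeasurementTable(
        meas,
        meta["time_subset"],
        meta.get("locomotor"),
        meta.get("clade"),
    )
    if table.has_missing() and not allow_missing:
        rows = table.measurements.index[table.measurements.isna().any(axis=1)]
        raise ValidationError(f"missing measurement cells in rows: {list(rows)}")
    return table


def write_measurement_table(
    table: MeasurementTable,
    path: str | Path,
    seed: int | None = None,
    delimiter: str = ",",
) -> None:
    df = table.measurements.copy()
    df.insert(0, "time_subset", table.time_subset)
    df.insert(1, "locomotor", table.locomotor)
    if table.clade is not None:
        df.insert(2, "clade", table.clade)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep=delimiter, index_label="taxon")


def read_trees(path: str | Path) -> TreeSet:
    """Read one or more Newick trees sharing a tip set."""
    try:
        trees = dendropy.TreeList.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"unparseable Newick file {path}: {exc}") from exc
    return TreeSet(trees)


def write_trees(trees: TreeSet | dendropy.TreeList, path: str | Path) -> None:
    tl = trees.trees if isinstance(trees, TreeSet) else trees
    tl.write(path=str(path), schema="newick", suppress_rooting=True)


def validate_against_tree(table: MeasurementTable, trees: TreeSet) -> dict:
    """Report name mismatches between extant taxa and tree tips.

    Matching is exact, case-sensitive string identity.  Returns a report dict;
    never raises and never mutates its inputs.
    """
    extant = set(table.measurements.index[~table.is_fossil])
    tips = set(trees.tip_names)
    return {
        "extant_missing_from_tree": sorted(extant - tips),
        "tips_missing_from_table": sorted(tips - extant),
    }
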