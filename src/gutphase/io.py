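"""Readers and writers for abundance tables, metadata, ledgers, trees and
growth-reference charts.

All tabular formats are TSV (tab-delimited, UTF-8, header row); trees are
Newick; configuration is YAML; timestamps are ISO-8601.  Ages follow one
canonical rule throughout: PMA (weeks) = gaBirth (weeks) + DOL / 7.

Taxonomy lineages are pipe-separated rank strings running from phylum
(level 2) down to species (level 7); unassigned ranks are rendered as
``unclassified``.  Rolling a table up to a coarser level sums child counts
and orders columns lexicographically, so rollups are deterministic.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

LINEAGE_SEP = "|"
UNCLASSIFIED = "unclassified"

#: lineage position (0-based) of each taxonomy level; level 2 = phylum.
_LEVEL_OFFSET = 1


class ParseError(ValueError):
    """A file did not conform to its documented format."""


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Samples x taxa count (or normalized) matrix.

    ``data`` has sample IDs as the index and taxonomy lineage strings as
    columns.  Raw tables hold non-negative integers whose row sums are the
    per-sample library sizes.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ParseError(f"duplicate sample IDs: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ParseError(f"duplicate taxon IDs: {dupes}")
        if (self.data.to_numpy() < 0).any():
            raise ParseError("negative counts in abundance table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=1)

    @property
    def is_integer(self) -> bool:
        vals = self.data.to_numpy()
        return bool(np.issubdtype(vals.dtype, np.integer) or np.allclose(vals, np.round(vals)))

    def rollup(self, level: int) -> "AbundanceTable":
        """Sum counts of all taxa sharing a lineage prefix at ``level``.

        ``level`` runs from 2 (phylum) to 7 (species).  Columns of the
        result are sorted lexicographically.
        """
        if not 2 <= level <= 7:
            raise ValueError(f"taxonomy level must be in 2..7, got {level}")
        n_ranks = level - _LEVEL_OFFSET
        prefixes = [
            LINEAGE_SEP.join((t.split(LINEAGE_SEP) + [UNCLASSIFIED] * n_ranks)[:n_ranks])
            for t in self.data.columns
        ]
        rolled = self.data.T.groupby(pd.Index(prefixes, name="taxon")).sum().T
        return AbundanceTable(rolled.sort_index(axis=1))

    def terminal_names(self) -> "AbundanceTable":
        """Rename lineage columns to their last rank (e.g. the bare class
        name), for matching against tree leaf labels."""
        renamed = self.data.copy()
        renamed.columns = [c.split(LINEAGE_SEP)[-1] for c in renamed.columns]
        return AbundanceTable(renamed)

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        sizes = self.library_sizes
        if (sizes <= 0).any():
            bad = sizes.index[sizes <= 0].tolist()
            raise ValueError(f"samples with zero total abundance: {bad}")
        return self.data.div(sizes, axis=0)

    def write(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def read_abundance_table(path: str | Path, level: int | None = None) -> AbundanceTable:
    """Read a samples x taxa TSV, optionally rolling up to ``level``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty abundance table") from None
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no taxon columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ParseError(f"{path}: ragged or missing values in rows {bad}")
    table = AbundanceTable(df)
    if level is not None:
        table = table.rollup(level)
    return table


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "subject_id", "sex", "ga_birth", "dol", "pma", "weight_kg"]

#: one day expressed in weeks; PMA consistency tolerance
PMA_TOL_WEEKS = 0.15


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"metadata missing columns: {missing}")
    if (df["dol"] < 0).any():
        raise ParseError("metadata contains negative DOL")
    implied = df["ga_birth"] + df["dol"] / 7.0
    off = (implied - df["pma"]).abs() > PMA_TOL_WEEKS
    if off.any():
        bad = df.loc[off, "sample_id"].tolist()
        raise ParseError(f"PMA != gaBirth + DOL/7 for samples: {bad[:5]}")
    if df["sample_id"].duplicated().any():
        raise ParseError("duplicate sample_id in metadata")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return validate_metadata(df)


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LMS growth reference chart
# ---------------------------------------------------------------------------


@dataclass
class LMSChart:
    """Sex x PMA grid of LMS (skewness, median, coefficient-of-variation)
    parameters for a weight reference, linearly interpolated in PMA."""

    table: pd.DataFrame  # columns: sex, pma_weeks, L, M, S

    def __post_init__(self) -> None:
        req = {"sex", "pma_weeks", "L", "M", "S"}
        if not req.issubset(self.table.columns):
            raise ParseError(f"LMS chart missing columns: {sorted(req - set(self.table.columns))}")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise ParseError("LMS chart requires M > 0 and S > 0")
        for sex, grp in self.table.groupby("sex"):
            pma = grp["pma_weeks"].to_numpy()
            if not np.all(np.diff(pma) > 0):
                raise ParseError(f"LMS chart PMA grid not strictly increasing for sex={sex}")

    def interpolate(self, sex: str, pma: float) -> tuple[float, float, float]:
        grp = self.table[self.table["sex"] == sex]
        if grp.empty:
            raise KeyError(f"no LMS rows for sex={sex!r}")
        grid = grp["pma_weeks"].to_numpy()
        if pma < grid[0] or pma > grid[-1]:
            raise ValueError(
                f"PMA {pma} outside LMS chart range [{grid[0]}, {grid[-1]}] (no extrapolation)"
            )
        return tuple(
            float(np.interp(pma, grid, grp[c].to_numpy())) for c in ("L", "M", "S")
        )

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_lms_reference(path: str | Path) -> LMSChart:
    return LMSChart(pd.read_csv(path, sep="\t"))


def synthetic_lms_chart(
    pma_lo: float = 22.0, pma_hi: float = 48.0, s: float = 0.11
) -> LMSChart:
    """Bundled synthetic weight reference (not a published chart).

    Median weight grows exponentially from ~0.5 kg at 22 weeks PMA toward
    ~3.5 kg at term-plus; L = 1 (no skew) and S constant.  Males are given
    a 4% heavier median than the combined curve, females 4% lighter,
    mirroring the direction of sex differences in published preterm
    references.  A real chart can be supplied by file wherever an
    ``LMSChart`` is accepted.
    """
    pma = np.arange(pma_lo, pma_hi + 0.5, 1.0)
    m = np.exp(-2.816 + 0.0885 * pma)
    rows = []
    for sex, factor in (("M", 1.04), ("F", 0.96)):
        for p, mv in zip(pma, m):
            rows.append({"sex": sex, "pma_weeks": float(p), "L": 1.0, "M": mv * factor, "S": s})
    return LMSChart(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """Rooted tree with taxon-labeled leaves and non-negative branch lengths."""

    tree: TreeNode

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def check_taxa(self, taxa) -> None:
        missing = sorted(set(taxa) - set(self.leaf_names()))
        if missing:
            raise KeyError(f"taxa absent from tree: {missing}")


def read_tree_newick(path: str | Path) -> PhyloTree:
    tree = TreeNode.read(str(path), format="newick")
    for tip in tree.tips():
        if tip.name is None:
            raise ParseError("tree contains unlabeled leaves")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ParseError("tree contains negative branch lengths")
    return PhyloTree(tree)


def parse_tree_newick(newick: str) -> PhyloTree:
    tree = TreeNode.read(_stdio.StringIO(newick), format="newick")
    for tip in tree.tips():
        if tip.name is None:
            raise ParseError("tree contains unlabeled leaves")
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Ledgers, medications, diaper records
# ---------------------------------------------------------------------------

LEDGER_COLUMNS = [
    "subject_id", "date", "kcal", "lipid_g", "protein_g", "carb_g", "route", "weight_kg",
]


def read_ledger(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, parse_dates=["date"])
    missing = [c for c in LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"ledger missing columns: {missing}")
    bad_route = ~df["route"].isin(["enteral", "parenteral"])
    if bad_route.any():
        raise ParseError(f"unknown routes: {sorted(df.loc[bad_route, 'route'].unique())}")
    return df


def read_medications(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, parse_dates=["date"])
    missing = [c for c in ("subject_id", "date", "drug_class") if c not in df.columns]
    if missing:
        raise ParseError(f"medication log missing columns: {missing}")
    return df


def read_diaper_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in ("subject_id", "timestamp", "text") if c not in df.columns]
    if missing:
        raise ParseError(f"diaper records missing columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    return df.sort_values(["subject_id", "timestamp"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Reports and config
# ---------------------------------------------------------------------------


def write_report(results: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Write a dict of result tables to ``<path>/<name>.tsv`` plus a short
    human-readable summary file."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = []
    for name, df in results.items():
        df.to_csv(path / f"{name}.tsv", sep="\t", index=False)
        lines.append(f"{name}: {len(df)} rows x {df.shape[1]} columns")
    (path / "summary.txt").write_text("\n".join(lines) + "\n")


def read_report_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml_config(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
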