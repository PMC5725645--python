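"""Week-to-week community dissimilarity within subjects.

Weighted UniFrac measures the dissimilarity of two abundance profiles on
a shared phylogeny: each branch contributes its length times the
absolute difference between the fractions of the two communities that
descend through it.  The raw (unnormalized) form is the default; the
normalized form divides by the abundance-weighted mean root-to-leaf
depth, bounding the distance in [0, 1].

Consecutive within-subject sample pairs — adjacent in PMA order,
regardless of gap length — are the unit of the stability analysis: pairs
that stay in one phase should be closer than pairs that straddle a phase
transition, and the contrast is tested with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gutphase.io import PhyloTree
from gutphase.phases import PhaseLabel


class _BranchIndex:
    """Branch lengths and leaf-descent incidence for fast UniFrac."""

    def __init__(self, tree: PhyloTree, taxa: list[str]):
        tree.check_taxa(taxa)
        order = {t: i for i, t in enumerate(taxa)}
        lengths, rows = [], []
        for node in tree.tree.traverse(include_self=False):
            length = node.length or 0.0
            mask = np.zeros(len(taxa))
            for tip in node.tips(include_self=True):
                if tip.name in order:
                    mask[order[tip.name]] = 1.0
            lengths.append(length)
            rows.append(mask)
        self.lengths = np.asarray(lengths)
        self.incidence = np.asarray(rows)  # branches x taxa
        self.leaf_depths = self.incidence.T @ self.lengths  # root-to-leaf distance


def weighted_unifrac(
    a,
    b,
    taxa: list[str],
    tree: PhyloTree,
    normalized: bool = False,
    _index: _BranchIndex | None = None,
) -> float:
    """Weighted UniFrac distance between two abundance vectors.

    ``a`` and ``b`` are abundances (any non-negative scale) over
    ``taxa``, each of which must be a leaf of ``tree``.  Raw form:
    ``sum_e L_e * |A_e - B_e|`` with ``A_e`` the fraction of sample a
    descending through branch e.  Symmetric; zero iff the two relative
    profiles coincide on the tree.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("abundance vectors must have positive totals")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    idx = _index if _index is not None else _BranchIndex(tree, list(taxa))
    pa, pb = a / a.sum(), b / b.sum()
    diff = idx.incidence @ (pa - pb)
    raw = float(idx.lengths @ np.abs(diff))
    if not normalized:
        return raw
    denom = float(idx.leaf_depths @ (pa + pb))
    return raw / denom if denom > 0 else 0.0


@dataclass
class ConsecutivePair:
    subject_id: str
    sample_i: str
    sample_j: str
    phase_i: PhaseLabel
    phase_j: PhaseLabel
    gap_days: float
    distance: float


def consecutive_dissimilarity(
    labels: pd.Series,
    metadata: pd.DataFrame,
    table,
    tree: PhyloTree,
    normalized: bool = False,
) -> pd.DataFrame:
    """Distance records for every adjacent within-subject sample pair.

    ``table`` is a (typically rarefied) abundance table restricted to
    the samples carrying labels; pairs never cross subjects.  Returns a
    DataFrame with one row per pair.
    """
    data = table.data if hasattr(table, "data") else table
    idx = _BranchIndex(tree, list(data.columns))
    meta = metadata.set_index("sample_id")
    rows = []
    usable = [s for s in labels.index if s in data.index]
    frame = pd.DataFrame(
        {
            "subject_id": meta.loc[usable, "subject_id"],
            "pma": meta.loc[usable, "pma"],
            "dol": meta.loc[usable, "dol"],
        },
        index=usable,
    )
    for subject, grp in frame.groupby("subject_id", sort=True):
        ordered = grp.sort_values("pma", kind="stable")
        ids = list(ordered.index)
        for s_i, s_j in zip(ids[:-1], ids[1:]):
            d = weighted_unifrac(
                data.loc[s_i].to_numpy(),
                data.loc[s_j].to_numpy(),
                list(data.columns),
                tree,
                normalized=normalized,
                _index=idx,
            )
            rows.append(
                {
                    "subject_id": str(subject),
                    "sample_i": s_i,
                    "sample_j": s_j,
                    "phase_i": labels[s_i],
                    "phase_j": labels[s_j],
                    "gap_days": float(ordered.loc[s_j, "dol"] - ordered.loc[s_i, "dol"]),
                    "distance": d,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "sample_i", "sample_j", "phase_i", "phase_j", "gap_days", "distance",
        ],
    )
    for col in ("phase_i", "phase_j"):  # keep PhaseLabel, not int64
        out[col] = pd.Series(
            [PhaseLabel(v) for v in out[col]], index=out.index, dtype=object
        )
    return out


_PHASE_NAMES = [p.name for p in PhaseLabel]


def mean_dissimilarity_by_phase_pair(
    pairs: pd.DataFrame, average: str = "per_subject"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3x3 matrix of mean distances by (initial phase, next phase).

    ``average='per_subject'`` first averages each subject's pairs within
    a cell, then across subjects (each infant weighted equally);
    ``'pooled'`` averages all pairs directly.  Returns ``(means,
    counts)``; cells with no pairs are NaN with count 0.
    """
    if pairs.empty:
        raise ValueError("no consecutive pairs supplied")
    if average not in ("per_subject", "pooled"):
        raise ValueError(f"unknown averaging mode {average!r}")
    means = pd.DataFrame(np.nan, index=_PHASE_NAMES, columns=_PHASE_NAMES)
    counts = pd.DataFrame(0, index=_PHASE_NAMES, columns=_PHASE_NAMES)
    for (pi, pj), cell in pairs.groupby(["phase_i", "phase_j"]):
        i, j = PhaseLabel(pi).name, PhaseLabel(pj).name
        counts.loc[i, j] = len(cell)
        if average == "pooled":
            means.loc[i, j] = cell["distance"].mean()
        else:
            means.loc[i, j] = cell.groupby("subject_id")["distance"].mean().mean()
    return means, counts


@dataclass
class RankSumResult:
    median_within: float
    median_cross: float
    statistic: float
    pvalue: float
    n_within: int
    n_cross: int
    method: str  # "exact" or "normal-approximation" (midranks, continuity)


def within_vs_cross_test(pairs: pd.DataFrame) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of consecutive-pair distances,
    same-phase pairs versus phase-change pairs.

    The p-value is approximate for all but tiny inputs: the normal
    approximation uses midranks for ties and a continuity correction;
    exact enumeration is used when both groups have at most 12 pairs and
    no ties are present.
    """
    within = pairs.loc[pairs["phase_i"] == pairs["phase_j"], "distance"].to_numpy()
    cross = pairs.loc[pairs["phase_i"] != pairs["phase_j"], "distance"].to_numpy()
    if len(within) == 0 or len(cross) == 0:
        raise ValueError("both same-phase and phase-change pair groups must be nonempty")
    values = np.concatenate([within, cross])
    has_ties = len(np.unique(values)) < len(values)
    exact = len(within) <= 12 and len(cross) <= 12 and not has_ties
    res = stats.mannwhitneyu(
        within, cross, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return RankSumResult(
        median_within=float(np.median(within)),
        median_cross=float(np.median(cross)),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_within=len(within),
        n_cross=len(cross),
        method="exact" if exact else "normal-approximation",
    )


#: fixed class-level toy phylogeny for synthetic runs (unit branch lengths)
TOY_CLASS_TREE_NEWICK = (
    "((Bacilli:1,Clostridia:1):1,((Gammaproteobacteria:1):1,"
    "(Bacteroidia:1,Actinobacteria:1):1):1):0;"
)


def toy_class_tree() -> PhyloTree:
    from gutphase.io import parse_tree_newick

    return parse_tree_newick(TOY_CLASS_TREE_NEWICK)
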