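"""Decision-tree phase classification and phase-sequence analytics.

The preterm gut microbiota progresses through three compositional phases:
P1 dominated by Bacilli, P2 by Gammaproteobacteria, P3 by Clostridia.  A
sample is assigned by two log-ratio tests on the relative abundances of
those focal classes:

1. ``r1 = log((bacilli + gammaproteobacteria) / clostridia)``;
   if ``r1 <= tau`` the sample is P3 (Clostridia have taken over).
2. otherwise ``r2 = log(bacilli / gammaproteobacteria)``;
   if ``r2 <= tau`` the sample is P2, else P1.

The threshold ``tau`` defaults to 2 and ties go to the lower branch.
Zero-abundance classes are resolved without arithmetic on 0/0: if
Clostridia are entirely absent the P1|P2 branch is taken; on that branch
an absent Gammaproteobacteria class yields P1 and an absent Bacilli class
yields P2; a sample with exactly one focal class present belongs to the
phase that class characterizes.  A sample devoid of all three focal
classes cannot be placed on the tree and raises
:class:`UnresolvablePhaseError`.

The log base is configurable (natural log by default) because the ratio
boundary moves with it; the threshold itself is held at 2.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 2.0

_LOG_FUNCS = {"ln": math.log, "log2": math.log2, "log10": math.log10}

#: default mapping from focal role to Greengenes-style class name
DEFAULT_CLASS_NAMES = {
    "bacilli": "Bacilli",
    "gammaproteobacteria": "Gammaproteobacteria",
    "clostridia": "Clostridia",
}


class UnresolvablePhaseError(ValueError):
    """All three focal classes absent; the decision tree cannot place the sample."""


class PhaseLabel(enum.IntEnum):
    """Ordered phase labels; P1 < P2 < P3 gives forward/reverse semantics."""

    P1 = 1
    P2 = 2
    P3 = 3

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name


@dataclass(frozen=True)
class ClassComposition:
    """Relative abundances of the three focal classes plus the remainder."""

    bacilli: float
    gammaproteobacteria: float
    clostridia: float
    other: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.bacilli, self.gammaproteobacteria, self.clostridia, self.other)
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError(f"abundances must lie in [0, 1]: {vals}")
        if sum(vals) > 1 + 1e-9:
            raise ValueError(f"abundances sum to more than 1: {vals}")


def classify_phase(
    comp: ClassComposition,
    threshold: float = DEFAULT_THRESHOLD,
    log_base: str = "ln",
) -> PhaseLabel:
    """Assign one sample to P1/P2/P3 by the two-step log-ratio tree."""
    log = _LOG_FUNCS[log_base]
    b, g, c = comp.bacilli, comp.gammaproteobacteria, comp.clostridia
    if b == 0 and g == 0 and c == 0:
        raise UnresolvablePhaseError(
            "all three focal classes absent; sample cannot be resolved"
        )
    # exactly one focal class present -> the phase that class characterizes
    present = [(b > 0), (g > 0), (c > 0)]
    if sum(present) == 1:
        return (PhaseLabel.P1, PhaseLabel.P2, PhaseLabel.P3)[present.index(True)]
    # step 1: P3 vs the P1|P2 branch
    if c > 0:
        if b + g == 0:
            return PhaseLabel.P3  # ratio is -inf, trivially <= threshold
        if log((b + g) / c) <= threshold:
            return PhaseLabel.P3
    # P1|P2 branch (taken either because r1 > threshold or Clostridia absent)
    if g == 0:
        return PhaseLabel.P1
    if b == 0:
        return PhaseLabel.P2
    return PhaseLabel.P2 if log(b / g) <= threshold else PhaseLabel.P1


def composition_from_counts(
    counts: pd.Series, class_names: dict[str, str] | None = None
) -> ClassComposition:
    """Build a :class:`ClassComposition` from one sample's class-level counts."""
    names = {**DEFAULT_CLASS_NAMES, **(class_names or {})}
    total = float(counts.sum())
    if total <= 0:
        raise ValueError("sample has zero total abundance")

    def frac(role: str) -> float:
        cols = [c for c in counts.index if c.split("|")[-1] == names[role] or c == names[role]]
        return float(counts[cols].sum()) / total

    b, g, c = (frac(r) for r in ("bacilli", "gammaproteobacteria", "clostridia"))
    return ClassComposition(b, g, c, max(0.0, 1.0 - b - g - c))


def classify_cohort(
    table,
    threshold: float = DEFAULT_THRESHOLD,
    log_base: str = "ln",
    class_names: dict[str, str] | None = None,
) -> pd.Series:
    """Classify every sample of a class-level abundance table.

    Relative abundances are computed from raw counts; the focal class
    columns are located by their terminal lineage rank (``...|Bacilli``)
    or a bare class name.  Returns a Series of :class:`PhaseLabel` indexed
    by sample ID.
    """
    names = {**DEFAULT_CLASS_NAMES, **(class_names or {})}
    data = table.data if hasattr(table, "data") else table
    for role, want in names.items():
        if not any(c.split("|")[-1] == want or c == want for c in data.columns):
            raise KeyError(f"focal class column for {role!r} ({want!r}) not found in table")
    labels = {}
    for sample_id, row in data.iterrows():
        labels[sample_id] = classify_phase(
            composition_from_counts(row, names), threshold=threshold, log_base=log_base
        )
    # object dtype keeps PhaseLabel values (pandas would coerce to int64)
    return pd.Series(labels, name="phase", dtype=object)


# ---------------------------------------------------------------------------
# Phase-sequence analytics
# ---------------------------------------------------------------------------


@dataclass
class TransitionMatrix:
    """3x3 empirical transition probabilities between consecutive samples.

    Rows with no observed outgoing pairs are NaN, not zero-filled.
    """

    probabilities: pd.DataFrame
    counts: pd.DataFrame
    n_pairs: int

    def __post_init__(self) -> None:
        rowsums = self.counts.sum(axis=1)
        for phase in self.probabilities.index:
            if rowsums[phase] > 0:
                total = self.probabilities.loc[phase].sum()
                assert abs(total - 1.0) < 1e-12, f"row {phase} sums to {total}"


_PHASES = [PhaseLabel.P1, PhaseLabel.P2, PhaseLabel.P3]
_PHASE_NAMES = [p.name for p in _PHASES]


def subject_timelines(labels: pd.Series, metadata: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-subject frames of (sample_id, dol, pma, phase) ordered by PMA."""
    meta = metadata.set_index("sample_id")
    df = pd.DataFrame(
        {
            "phase": labels,
            "subject_id": meta.loc[labels.index, "subject_id"],
            "dol": meta.loc[labels.index, "dol"],
            "pma": meta.loc[labels.index, "pma"],
        }
    )
    out = {}
    for subject, grp in df.groupby("subject_id", sort=True):
        out[str(subject)] = grp.sort_values("pma", kind="stable")
    return out


def transition_matrix(timelines) -> TransitionMatrix:
    """Estimate transition probabilities from within-subject consecutive pairs.

    ``timelines`` is an iterable of per-subject ordered phase sequences
    (lists of :class:`PhaseLabel`) or the dict produced by
    :func:`subject_timelines`.  Pairs never cross subjects.
    """
    if isinstance(timelines, dict):
        seqs = [list(grp["phase"]) for grp in timelines.values()]
    else:
        seqs = [list(s) for s in timelines]
    counts = np.zeros((3, 3), dtype=int)
    for seq in seqs:
        for a, b in zip(seq[:-1], seq[1:]):
            counts[int(a) - 1, int(b) - 1] += 1
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        raise ValueError("no within-subject consecutive pairs observed")
    probs = np.full((3, 3), np.nan)
    rowsums = counts.sum(axis=1)
    for i in range(3):
        if rowsums[i] > 0:
            probs[i] = counts[i] / rowsums[i]
    idx = pd.Index(_PHASE_NAMES, name="from")
    cols = pd.Index(_PHASE_NAMES, name="to")
    return TransitionMatrix(
        probabilities=pd.DataFrame(probs, index=idx, columns=cols),
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        n_pairs=n_pairs,
    )


def phase_pma_distribution(
    labels: pd.Series, metadata: pd.DataFrame, bins: list[float]
) -> pd.DataFrame:
    """Fraction of each phase's samples falling in PMA ranges.

    ``bins`` are cutpoints; range ``k`` is ``[bins[k], bins[k+1])`` with
    the last range closed on the right.  Per-phase fractions sum to 1.
    """
    meta = metadata.set_index("sample_id")
    pma = meta.loc[labels.index, "pma"].to_numpy()
    edges = np.asarray(bins, dtype=float)
    rows = {}
    col_names = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    for phase in _PHASES:
        mask = np.array([p == phase for p in labels])
        if mask.sum() == 0:
            rows[phase.name] = [np.nan] * (len(edges) - 1)
            continue
        hist, _ = np.histogram(pma[mask], bins=edges)
        # np.histogram closes the final bin on the right, matching the contract
        rows[phase.name] = (hist / mask.sum()).tolist()
    return pd.DataFrame.from_dict(rows, orient="index", columns=col_names)


def phase_pma_fraction(
    labels: pd.Series,
    metadata: pd.DataFrame,
    phase: PhaseLabel,
    pma_min: float = -np.inf,
    pma_max: float = np.inf,
) -> float:
    """Fraction of samples of ``phase`` whose PMA lies in [pma_min, pma_max]."""
    meta = metadata.set_index("sample_id")
    pma = meta.loc[labels.index, "pma"].to_numpy()
    mask = np.array([p == phase for p in labels])
    if mask.sum() == 0:
        return float("nan")
    inside = (pma[mask] >= pma_min) & (pma[mask] <= pma_max)
    return float(inside.mean())


def time_to_phase3(timeline: pd.DataFrame) -> tuple[float | None, bool]:
    """DOL of the first P3 sample, or ``(None, True)`` when censored."""
    ordered = timeline.sort_values("pma", kind="stable")
    hits = ordered[ordered["phase"] == PhaseLabel.P3]
    if hits.empty:
        return None, True
    return float(hits.iloc[0]["dol"]), False


def last_p1_before_exit(timeline: pd.DataFrame) -> float | None:
    """DOL of the last P1 sample preceding the subject's first move out of P1.

    Requires the subject to start in P1 and to be observed leaving it;
    returns None otherwise.  Later reversions back into P1 are ignored:
    the quantity is anchored to the *initial* transition.
    """
    ordered = timeline.sort_values("pma", kind="stable")
    phases = list(ordered["phase"])
    if not phases or phases[0] != PhaseLabel.P1:
        return None
    exit_idx = None
    for i, p in enumerate(phases):
        if p != PhaseLabel.P1:
            exit_idx = i
            break
    if exit_idx is None:
        return None
    return float(ordered.iloc[exit_idx - 1]["dol"])
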