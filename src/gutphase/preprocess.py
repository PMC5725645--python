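"""Sample and taxon filters plus count normalizations.

Order of operations mirrors the analysis pipeline: minimum-depth sample
filter, then taxon prevalence filter, then normalization.  Phase
classification consumes raw relative abundances (counts over library
size) computed *before* any scaling transform; cumulative-sum-scaling
(CSS) plus log2(x+1) feeds the longitudinal abundance models; rarefaction
feeds beta diversity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gutphase.io import AbundanceTable

DEFAULT_MIN_READS = 12_000
DEFAULT_MAX_ZERO_FRACTION = 0.98
DEFAULT_RAREFY_DEPTH = 12_000


def filter_min_depth(table: AbundanceTable, min_reads: int = DEFAULT_MIN_READS) -> AbundanceTable:
    """Keep samples whose library size is at least ``min_reads``.

    The boundary is inclusive: a sample with exactly ``min_reads`` reads
    is retained (samples *below* the threshold are excluded).  Input must
    be raw counts; sample order is preserved.
    """
    if not table.is_integer:
        raise ValueError("depth filter expects raw integer counts, got normalized values")
    keep = table.library_sizes >= min_reads
    if not keep.any():
        warnings.warn("all samples fall below the minimum depth; returning empty table")
    return AbundanceTable(table.data.loc[keep])


def filter_taxa_prevalence(
    table: AbundanceTable, max_zero_fraction: float = DEFAULT_MAX_ZERO_FRACTION
) -> AbundanceTable:
    """Drop taxa with ``>= max_zero_fraction`` exactly-zero entries.

    The boundary is inclusive on the zero fraction ("equal or more than"
    is dropped): with the 0.98 default, a taxon zero in 98 of 100 samples
    goes, one zero in 97 stays.
    """
    zero_frac = (table.data == 0).mean(axis=0)
    keep = zero_frac < max_zero_fraction
    if not keep.any():
        warnings.warn("prevalence filter removed every taxon")
    return AbundanceTable(table.data.loc[:, keep])


@dataclass
class NormalizationResult:
    """A scaled table plus provenance of how the scaling was done."""

    table: pd.DataFrame
    scaling_factors: pd.Series
    method: str
    parameters: dict = field(default_factory=dict)


def _css_quantile_auto(data: pd.DataFrame) -> float:
    """Adaptive CSS quantile in the spirit of the published heuristic.

    Scans candidate quantiles of each sample's nonzero-count
    distribution and picks the smallest one at which the per-sample
    quantiles start to diverge from the cohort reference (relative
    instability above 0.1); falls back to 0.5 when the scan is
    degenerate (e.g. identical samples).
    """
    grid = np.arange(0.25, 0.97, 0.01)
    qmat = []
    for _, row in data.iterrows():
        nz = row[row > 0].to_numpy(dtype=float)
        if nz.size == 0:
            raise ValueError("CSS normalization: sample with all-zero counts")
        qmat.append(np.quantile(nz, grid))
    qmat = np.asarray(qmat)
    ref = np.median(qmat, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        spread = np.median(np.abs(qmat - ref), axis=0) / np.where(ref > 0, ref, np.nan)
    if not np.isfinite(spread).any() or np.nanmax(spread) == 0:
        return 0.5
    unstable = np.where(spread >= 0.1)[0]
    for idx in unstable:
        if grid[idx] >= 0.5:
            return float(grid[idx])
    return 0.5


def css_normalize(
    table: AbundanceTable, quantile: float | str = "auto", log2: bool = True
) -> NormalizationResult:
    """Cumulative-sum-scaling normalization with optional log2(x+1).

    Per sample, the cumulative sum of counts at or below the chosen
    quantile of its nonzero counts is the raw factor; dividing by the
    median of those sums across samples gives the scaling factor, and
    the transformed value is ``log2(count / factor + 1)``.
    """
    data = table.data.astype(float)
    if (data.sum(axis=1) <= 0).any():
        bad = data.index[data.sum(axis=1) <= 0].tolist()
        raise ValueError(f"CSS normalization: all-zero samples {bad}")
    q = _css_quantile_auto(data) if quantile == "auto" else float(quantile)
    if not 0 < q < 1:
        raise ValueError(f"CSS quantile must be in (0, 1), got {q}")
    raw_factors = []
    for _, row in data.iterrows():
        nz = row[row > 0].to_numpy(dtype=float)
        cutoff = np.quantile(nz, q)
        raw_factors.append(row[row <= cutoff].sum())
    raw_factors = pd.Series(raw_factors, index=data.index, dtype=float)
    if (raw_factors <= 0).any():
        raise ValueError("CSS normalization produced a nonpositive scaling sum")
    global_const = float(np.median(raw_factors))
    factors = raw_factors / global_const
    scaled = data.div(factors, axis=0)
    out = np.log2(scaled + 1.0) if log2 else scaled
    return NormalizationResult(
        table=out,
        scaling_factors=factors,
        method="CSS",
        parameters={"quantile": q, "log2": log2, "global_constant": global_const},
    )


def rarefy(
    table: AbundanceTable, depth: int = DEFAULT_RAREFY_DEPTH, seed: int = 0
) -> AbundanceTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples shallower than ``depth`` are dropped with a warning.  Uses
    the multivariate hypergeometric distribution, so marginal counts are
    hypergeometric; deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    if not table.is_integer:
        raise ValueError("rarefaction expects raw integer counts")
    rng = np.random.default_rng(seed)
    sizes = table.library_sizes
    shallow = sizes.index[sizes < depth].tolist()
    if shallow:
        warnings.warn(f"dropping {len(shallow)} samples shallower than {depth} reads")
    rows = {}
    for sid, row in table.data.iterrows():
        if sizes[sid] < depth:
            continue
        counts = row.to_numpy().astype(np.int64)
        if sizes[sid] == depth:
            rows[sid] = counts
        else:
            rows[sid] = rng.multivariate_hypergeometric(counts, depth)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.data.columns)
    out.index.name = table.data.index.name
    return AbundanceTable(out)
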