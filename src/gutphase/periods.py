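"""Early/late changepoint from smoothed longitudinal abundance curves.

Per subject and taxon, normalized abundances over PMA are smoothed onto
a common grid (cubic smoothing splines with generalized cross-validation
penalty selection).  Each taxon's curves are then decomposed by
functional PCA into a mean curve plus eigen-function expansion; the
pointwise between-subject variance

    V_v(t) = 1/(N-1) * sum_i (xhat_{i,v}(t) - xbar_v(t))^2

is averaged over taxa into the total variance curve Vbar(t), whose grid
argmax (rounded to a whole week) is the boundary between the EARLY
(< cutoff) and LATE (>= cutoff) periods of postmenstrual age.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline


class Period(enum.Enum):
    EARLY = "EARLY"
    LATE = "LATE"


@dataclass
class TaxonFPCA:
    """Mean curve, eigen-functions and scores for one taxon's curves."""

    subjects: list[str]
    mean_curve: np.ndarray  # (grid,)
    eigenfunctions: np.ndarray  # (K_full, grid)
    scores: np.ndarray  # (subjects, K_full)
    explained: np.ndarray  # variance fraction per component
    n_components_99: int

    def reconstruct(self) -> np.ndarray:
        """Fitted curves from the full decomposition (exact)."""
        return self.mean_curve + self.scores @ self.eigenfunctions


@dataclass
class FittedCurves:
    grid: np.ndarray
    curves: dict[str, pd.DataFrame]  # taxon -> (subjects x grid) fitted values
    fpca: dict[str, TaxonFPCA]
    excluded_subjects: list[str] = field(default_factory=list)

    @property
    def taxa(self) -> list[str]:
        return list(self.curves)

    def mean_components_99(self) -> float:
        return float(np.mean([f.n_components_99 for f in self.fpca.values()]))


@dataclass
class VarianceCurve:
    grid: np.ndarray
    per_taxon: pd.DataFrame  # taxa x grid pointwise variances
    vbar: np.ndarray
    cutoff_week: int
    n_subjects: int
    n_taxa: int
    tie: bool = False
    degenerate: bool = False


def _fpca(curves: np.ndarray, subjects: list[str]) -> TaxonFPCA:
    mean = curves.mean(axis=0)
    centered = curves - mean
    # SVD of centered curves: rows are subjects, columns grid points
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        explained = np.zeros_like(var)
        k99 = 1
    else:
        explained = var / total
        k99 = int(np.searchsorted(np.cumsum(explained), 0.99 - 1e-12) + 1)
    return TaxonFPCA(
        subjects=subjects,
        mean_curve=mean,
        eigenfunctions=vt,
        scores=u * s,
        explained=explained,
        n_components_99=k99,
    )


def fit_subject_taxon_curves(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    grid_step: float = 0.5,
    min_samples: int = 4,
    min_span_weeks: float = 4.0,
    grid_range: tuple[float, float] | None = None,
) -> FittedCurves:
    """Smooth each subject's per-taxon trajectory onto a common PMA grid.

    ``values`` is a samples x taxa frame of normalized (CSS + log2)
    abundances; ``metadata`` supplies subject_id and pma per sample.
    Subjects with fewer than ``min_samples`` samples or spanning less
    than ``min_span_weeks`` weeks are excluded with a warning.  Spline
    smoothness is chosen by generalized cross-validation.
    """
    meta = metadata.set_index("sample_id")
    sample_ids = [s for s in values.index if s in meta.index]
    frame = pd.DataFrame(
        {
            "subject_id": meta.loc[sample_ids, "subject_id"],
            "pma": meta.loc[sample_ids, "pma"].astype(float),
        },
        index=sample_ids,
    )
    eligible: dict[str, pd.DataFrame] = {}
    excluded: list[str] = []
    for subject, grp in frame.groupby("subject_id", sort=True):
        span = grp["pma"].max() - grp["pma"].min()
        if len(grp) < min_samples or span < min_span_weeks:
            excluded.append(str(subject))
            continue
        eligible[str(subject)] = grp
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} subjects with sparse sampling "
            f"(< {min_samples} samples or < {min_span_weeks} weeks span)"
        )
    if not eligible:
        raise ValueError("no subjects with enough samples to fit curves")

    if grid_range is None:
        lo = float(np.floor(frame["pma"].min()))
        hi = float(np.ceil(frame["pma"].max()))
    else:
        lo, hi = grid_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)

    curves: dict[str, pd.DataFrame] = {}
    fpca: dict[str, TaxonFPCA] = {}
    subjects = sorted(eligible)
    for taxon in values.columns:
        mat = np.empty((len(subjects), len(grid)))
        for si, subject in enumerate(subjects):
            grp = eligible[subject]
            y = values.loc[grp.index, taxon].to_numpy(dtype=float)
            t = grp["pma"].to_numpy()
            # average duplicate PMA values; splines need increasing x
            order = np.argsort(t, kind="stable")
            t, y = t[order], y[order]
            tu, inverse = np.unique(t, return_inverse=True)
            yu = np.bincount(inverse, weights=y) / np.bincount(inverse)
            if len(tu) < 4 or np.allclose(yu, yu[0]):
                # too few distinct points (or flat data) for GCV smoothing
                mat[si] = np.interp(grid, tu, yu)
            else:
                spline = make_smoothing_spline(tu, yu)
                # constant extrapolation beyond the subject's observed range:
                # polynomial extrapolation would dominate the variance curve
                mat[si] = spline(np.clip(grid, tu[0], tu[-1]))
        df = pd.DataFrame(mat, index=subjects, columns=grid)
        curves[taxon] = df
        fpca[taxon] = _fpca(mat, subjects)
    return FittedCurves(grid=grid, curves=curves, fpca=fpca, excluded_subjects=excluded)


def total_variance_curve(fitted: FittedCurves) -> VarianceCurve:
    """Pointwise between-subject variance per taxon and its taxon mean."""
    any_curves = next(iter(fitted.curves.values()))
    n_subjects = len(any_curves)
    if n_subjects < 2:
        raise ValueError("variance curve needs at least 2 subjects")
    rows = {}
    for taxon, df in fitted.curves.items():
        rows[taxon] = df.to_numpy().var(axis=0, ddof=1)
    per_taxon = pd.DataFrame.from_dict(rows, orient="index", columns=fitted.grid)
    vbar = per_taxon.to_numpy().mean(axis=0)
    cutoff, tie, degenerate = _argmax_week(fitted.grid, vbar)
    return VarianceCurve(
        grid=fitted.grid,
        per_taxon=per_taxon,
        vbar=vbar,
        cutoff_week=cutoff,
        n_subjects=n_subjects,
        n_taxa=len(fitted.curves),
        tie=tie,
        degenerate=degenerate,
    )


def _argmax_week(grid: np.ndarray, vbar: np.ndarray) -> tuple[int, bool, bool]:
    if not np.all(np.isfinite(vbar)):
        raise ValueError("variance curve contains non-finite values")
    vmax = vbar.max()
    if np.isclose(vmax, vbar.min()):
        warnings.warn("variance curve is (near) constant; cutoff degenerate")
        return int(round(float(grid[0]))), False, True
    at_max = np.isclose(vbar, vmax)
    first = int(np.flatnonzero(at_max)[0])
    tie = int(at_max.sum()) > 1
    if tie:
        warnings.warn("variance curve has a tied maximum; using the earliest week")
    return int(round(float(grid[first]))), tie, False


def find_period_cutoff(vc: VarianceCurve) -> int:
    """Grid argmax of the total variance curve, as an integer PMA week."""
    return vc.cutoff_week


def assign_period(pma: float, cutoff: float) -> Period:
    """EARLY for PMA strictly below the cutoff, LATE at or above it.

    The late interval is closed at the cutoff: [cutoff, infinity).
    """
    if pma <= 0:
        raise ValueError(f"PMA must be positive, got {pma}")
    return Period.EARLY if pma < cutoff else Period.LATE
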