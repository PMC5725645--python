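"""Growth Z-scores, windowed nutrition/medication covariates, and
meconium-clearance detection.

Weight Z-scores use the LMS method: with chart parameters L (skewness),
M (median) and S (coefficient of variation) interpolated at the infant's
sex and PMA,

    z = ((w/M)^L - 1) / (L*S)     for L != 0
    z = ln(w/M) / S               for L == 0,

and the percentile is the normal CDF of z.

Nutrition and medication covariates summarize the 7 calendar days before
sample collection (half-open window [t-7d, t): the sampling day itself
is excluded).  Calories are summed as daily kcal/kg; macronutrient
ratios are sums of daily (g/kg)/(kcal/kg); the enteral proportion is the
ratio of weekly enteral to total kcal/kg sums.

The meconium-to-stool transition is the first diaper record not
mentioning meconium that is followed by at most two records that do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from gutphase.config import MED_CLASSES
from gutphase.io import LMSChart

_EPOCH = pd.Timestamp("2020-01-01")


# ---------------------------------------------------------------------------
# LMS weight Z-scores
# ---------------------------------------------------------------------------


@dataclass
class GrowthRecord:
    subject_id: str | None
    sex: str
    pma: float
    weight_kg: float
    L: float
    M: float
    S: float
    zscore: float
    percentile: float


#: below this |L| the power transform is numerically indistinguishable
#: from its log-form limit and the latter is used directly
_L_EPS = 1e-4


def lms_zscore(weight: float, L: float, M: float, S: float) -> float:
    """Cole's LMS transform of a measurement against (L, M, S).

    Uses the log-form limit for |L| <= 1e-4, where the power formula is
    dominated by cancellation error and the two branches agree to well
    below chart precision.
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    if abs(L) <= _L_EPS:
        return float(np.log(weight / M) / S)
    return float(np.expm1(L * np.log(weight / M)) / (L * S))


def weight_zscore(
    weight: float,
    sex: str,
    pma: float,
    chart: LMSChart,
    subject_id: str | None = None,
) -> GrowthRecord:
    """Z-score and percentile of a weight against the reference chart.

    L, M, S are linearly interpolated in PMA within sex; PMA outside the
    chart range raises (no extrapolation).
    """
    L, M, S = chart.interpolate(sex, pma)
    z = lms_zscore(weight, L, M, S)
    return GrowthRecord(
        subject_id=subject_id,
        sex=sex,
        pma=pma,
        weight_kg=weight,
        L=L,
        M=M,
        S=S,
        zscore=z,
        percentile=float(norm.cdf(z)),
    )


def percentile_to_zscore(p: float) -> float:
    return float(norm.ppf(p))


def delta_weight_zscore(records: pd.DataFrame) -> float:
    """Change in weight Z-score from the first to the last record.

    ``records`` needs columns pma and zscore; rows are sorted by PMA
    before differencing, so input order does not matter.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 growth records for a change score")
    ordered = records.sort_values("pma", kind="stable")
    return float(ordered["zscore"].iloc[-1] - ordered["zscore"].iloc[0])


def growth_table(metadata: pd.DataFrame, chart: LMSChart) -> pd.DataFrame:
    """Per-sample Z-scores and percentiles for a whole metadata table."""
    rows = []
    for _, r in metadata.iterrows():
        rec = weight_zscore(r["weight_kg"], r["sex"], r["pma"], chart, r["subject_id"])
        rows.append(
            {
                "sample_id": r["sample_id"],
                "subject_id": r["subject_id"],
                "pma": r["pma"],
                "zscore": rec.zscore,
                "percentile": rec.percentile,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Windowed nutrition covariates
# ---------------------------------------------------------------------------

RATIO_MODES = ("daily_sum", "weekly_ratio")


def weekly_nutrition(
    ledger: pd.DataFrame,
    sample_date: pd.Timestamp,
    ratio_mode: str = "daily_sum",
) -> dict:
    """Nutrition covariates over the 7 days before ``sample_date``.

    ``ledger`` holds one subject's daily intake rows (possibly two per
    day, one per route) with absolute kcal/grams and that day's weight.
    Returns kcal_per_kg_week, the three macronutrient ratios, the
    enteral proportion, and a coverage field counting window days with
    any data.  ``ratio_mode='daily_sum'`` sums daily (g/kg)/(kcal/kg)
    ratios; ``'weekly_ratio'`` divides the weekly gram and kcal sums.
    """
    if ratio_mode not in RATIO_MODES:
        raise ValueError(f"ratio_mode must be one of {RATIO_MODES}")
    sample_date = pd.Timestamp(sample_date).normalize()
    start = sample_date - pd.Timedelta(days=7)
    dates = pd.to_datetime(ledger["date"]).dt.normalize()
    window = ledger.loc[(dates >= start) & (dates < sample_date)].copy()
    window["date"] = pd.to_datetime(window["date"]).dt.normalize()

    out = {
        "kcal_per_kg_week": 0.0,
        "protein_ratio": 0.0,
        "lipid_ratio": 0.0,
        "carb_ratio": 0.0,
        "enteral_proportion": np.nan,
        "window_days_covered": 0,
        "ratio_undefined": False,
    }
    if window.empty:
        return out

    enteral_kcal_kg = 0.0
    total_kcal_kg = 0.0
    ratios = {"protein": 0.0, "lipid": 0.0, "carb": 0.0}
    weekly_g_kg = {"protein": 0.0, "lipid": 0.0, "carb": 0.0}
    days = 0
    for _, day in window.groupby("date"):
        w = float(day["weight_kg"].iloc[0])
        kcal_kg = day["kcal"].sum() / w
        total_kcal_kg += kcal_kg
        enteral_kcal_kg += day.loc[day["route"] == "enteral", "kcal"].sum() / w
        days += 1
        for macro, col in (("protein", "protein_g"), ("lipid", "lipid_g"), ("carb", "carb_g")):
            g_kg = day[col].sum() / w
            weekly_g_kg[macro] += g_kg
            if kcal_kg > 0:
                ratios[macro] += g_kg / kcal_kg
            elif g_kg > 0:
                out["ratio_undefined"] = True
    out["kcal_per_kg_week"] = float(total_kcal_kg)
    out["window_days_covered"] = days
    if total_kcal_kg > 0:
        out["enteral_proportion"] = float(enteral_kcal_kg / total_kcal_kg)
    if ratio_mode == "daily_sum":
        for macro in ratios:
            out[f"{macro}_ratio"] = float(ratios[macro])
    else:
        for macro in weekly_g_kg:
            out[f"{macro}_ratio"] = (
                float(weekly_g_kg[macro] / total_kcal_kg) if total_kcal_kg > 0 else np.nan
            )
    return out


def medication_window_flags(
    med_log: pd.DataFrame,
    sample_date: pd.Timestamp,
    classes: list[str] = MED_CLASSES,
) -> dict[str, int]:
    """Binary exposure flags for the half-open window [t-7d, t).

    A dose exactly 7 days before the sample counts; a dose on the
    sampling day does not.  Duplicate log rows are harmless.
    """
    sample_date = pd.Timestamp(sample_date).normalize()
    start = sample_date - pd.Timedelta(days=7)
    if med_log.empty:
        return {c: 0 for c in classes}
    dates = pd.to_datetime(med_log["date"]).dt.normalize()
    in_window = med_log.loc[(dates >= start) & (dates < sample_date)]
    hit = set(in_window["drug_class"])
    return {c: int(c in hit) for c in classes}


def covariate_table(
    metadata: pd.DataFrame,
    ledger: pd.DataFrame,
    medications: pd.DataFrame,
    birth_date: pd.Timestamp = _EPOCH,
    ratio_mode: str = "daily_sum",
) -> pd.DataFrame:
    """Per-sample covariate rows joining nutrition and medication windows.

    Sample dates are ``birth_date + DOL`` (the convention the bundled
    generator writes its ledgers with); supply per-subject birth dates
    via a mapping if they differ.
    """
    birth = (
        birth_date
        if not isinstance(birth_date, dict)
        else None
    )
    rows = []
    led_by_subj = dict(tuple(ledger.groupby("subject_id")))
    med_by_subj = dict(tuple(medications.groupby("subject_id"))) if len(medications) else {}
    empty_med = medications.iloc[0:0]
    for _, r in metadata.iterrows():
        b = birth if birth is not None else pd.Timestamp(birth_date[r["subject_id"]])
        date = b + pd.Timedelta(days=int(r["dol"]))
        subj_ledger = led_by_subj.get(r["subject_id"])
        if subj_ledger is None:
            subj_ledger = ledger.iloc[0:0]
        nut = weekly_nutrition(subj_ledger, date, ratio_mode=ratio_mode)
        med = medication_window_flags(med_by_subj.get(r["subject_id"], empty_med), date)
        rows.append({"sample_id": r["sample_id"], "subject_id": r["subject_id"], **nut, **med})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Meconium-to-stool transition
# ---------------------------------------------------------------------------


@dataclass
class StoolTransition:
    subject_id: str
    transition_dol: float | None  # None when censored
    censored: bool
    record_index: int | None  # positional index of the qualifying record


def detect_stool_transition(
    records: pd.DataFrame,
    birth_date: pd.Timestamp = _EPOCH,
    max_later_meconium: int = 2,
) -> StoolTransition:
    """Apply the text rule to one subject's time-sorted diaper records.

    The transition is the earliest record whose text lacks the word
    "meconium" (case-insensitive) and which is followed by at most
    ``max_later_meconium`` records containing it, counting *all* later
    records.  Censored when no record qualifies.
    """
    if len(records) == 0:
        raise ValueError("empty diaper record list")
    ordered = records.sort_values("timestamp", kind="stable").reset_index(drop=True)
    has_mec = (
        ordered["text"].str.contains("meconium", case=False, regex=False).to_numpy()
    )
    subject = str(ordered["subject_id"].iloc[0])
    # suffix counts of meconium mentions after each position
    suffix = np.concatenate([np.cumsum(has_mec[::-1])[::-1][1:], [0]])
    for i in range(len(ordered)):
        if not has_mec[i] and suffix[i] <= max_later_meconium:
            ts = pd.Timestamp(ordered["timestamp"].iloc[i])
            dol = (ts.normalize() - pd.Timestamp(birth_date).normalize()).days
            return StoolTransition(subject, float(dol), False, int(i))
    return StoolTransition(subject, None, True, None)


def p1_exit_stool_gap(
    labels: pd.Series,
    metadata: pd.DataFrame,
    diapers: pd.DataFrame,
    birth_date: pd.Timestamp = _EPOCH,
) -> pd.DataFrame:
    """Join each subject's last-P1 sample (before the initial phase exit)
    with the detected meconium-to-stool transition.

    Only subjects whose first classified sample is P1, who are observed
    leaving P1, and whose stool transition is detected contribute a row;
    ``gap_days`` is stool-transition DOL minus last-P1 DOL.
    """
    from gutphase.phases import last_p1_before_exit, subject_timelines

    timelines = subject_timelines(labels, metadata)
    stool = stool_transitions(diapers, birth_date=birth_date).set_index("subject_id")
    ga = metadata.drop_duplicates("subject_id").set_index("subject_id")["ga_birth"]
    rows = []
    for subject, tl in timelines.items():
        last_p1 = last_p1_before_exit(tl)
        if last_p1 is None or subject not in stool.index:
            continue
        if stool.loc[subject, "censored"]:
            continue
        stool_dol = float(stool.loc[subject, "transition_dol"])
        rows.append(
            {
                "subject_id": subject,
                "last_p1_dol": last_p1,
                "stool_dol": stool_dol,
                "gap_days": stool_dol - last_p1,
                "ga_birth": float(ga.get(subject, np.nan)),
            }
        )
    return pd.DataFrame(rows)


def stool_transitions(
    diapers: pd.DataFrame, birth_date: pd.Timestamp = _EPOCH
) -> pd.DataFrame:
    """Per-subject transition table for a cohort's diaper records."""
    rows = []
    for subject, grp in diapers.groupby("subject_id", sort=True):
        st = detect_stool_transition(grp, birth_date=birth_date)
        rows.append(
            {
                "subject_id": str(subject),
                "transition_dol": st.transition_dol,
                "censored": st.censored,
            }
        )
    return pd.DataFrame(rows)
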