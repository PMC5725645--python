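"""Synthetic preterm-cohort generator.

Every downstream stage of the pipeline (classification, transition
analytics, dissimilarity, changepoint, covariates, association models) is
exercised on cohorts produced here, so the generator mirrors the
statistical structure the analysis assumes:

* phase progression is a discrete-time Markov chain on the weekly
  sampling grid, with logistic-in-PMA forward hazards and a small fixed
  reversion probability;
* compositions are phase-conditional Dirichlet-multinomial draws at the
  genus level, with concentrations separated enough for the decision
  tree to recover the generating phase;
* library sizes are negative-binomial (mean 30,000, dispersion 5),
  floored at 1, so the minimum-depth filter has work to do;
* weight Z-scores follow a Model-B-style linear predictor plus subject
  random intercept plus noise, and are mapped to kilograms through the
  bundled LMS chart, guaranteeing round-trip consistency with the
  growth module;
* meconium clearance in the free-text diaper records lags the last
  phase-1 sample by a truncated-normal delay (mean 4.7 days).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gutphase.config import (
    MED_CLASSES,
    MED_EPISODE_PROBS,
    TAXA,
    HazardParams,
    SimConfig,
)
from gutphase.io import AbundanceTable, LMSChart, synthetic_lms_chart
from gutphase.phases import PhaseLabel

_EPOCH = pd.Timestamp("2020-01-01")

#: class membership of each taxon (index into TAXA) for truth bookkeeping
_CLASS_OF_TAXON = [t.split("|")[1] for t in TAXA]


# ---------------------------------------------------------------------------
# Phase paths
# ---------------------------------------------------------------------------


def simulate_phase_path(
    ga_birth: float,
    hazard_p1p2: HazardParams,
    hazard_p2p3: HazardParams,
    reversion_prob: float,
    n_steps: int,
    rng: np.random.Generator,
    start: PhaseLabel = PhaseLabel.P1,
) -> list[PhaseLabel]:
    """Simulate the weekly phase chain from birth.

    The chain starts in ``start`` at PMA = ``ga_birth`` and takes
    ``n_steps`` weekly steps; the label *after* step ``k`` is the state
    at PMA = ``ga_birth + k``, i.e. at the k-th weekly sample.  Forward
    hazards are evaluated at the PMA being stepped into; reversions
    (P2->P1, P3->P2) occur with a small fixed probability.
    """
    if not 22.0 <= ga_birth <= 42.0:
        raise ValueError(f"ga_birth {ga_birth} outside supported range [22, 42]")
    state = start
    path: list[PhaseLabel] = []
    u = rng.random(n_steps)
    for k in range(n_steps):
        pma = ga_birth + (k + 1)
        if state == PhaseLabel.P1:
            if u[k] < hazard_p1p2.probability(pma):
                state = PhaseLabel.P2
        elif state == PhaseLabel.P2:
            h = min(hazard_p2p3.probability(pma), 1.0 - reversion_prob)
            if u[k] < h:
                state = PhaseLabel.P3
            elif u[k] < h + reversion_prob:
                state = PhaseLabel.P1
        else:  # P3
            if u[k] < reversion_prob:
                state = PhaseLabel.P2
        path.append(state)
    return path


def chain_transition_matrix(
    hazard_p1p2: HazardParams,
    hazard_p2p3: HazardParams,
    reversion_prob: float,
    pma: float,
) -> np.ndarray:
    """The generating one-step transition matrix at a given PMA."""
    h12 = hazard_p1p2.probability(pma)
    r = reversion_prob
    h23 = min(hazard_p2p3.probability(pma), 1.0 - r)
    return np.array(
        [
            [1 - h12, h12, 0.0],
            [r, 1 - r - h23, h23],
            [0.0, r, 1 - r],
        ]
    )


# ---------------------------------------------------------------------------
# Compositions
# ---------------------------------------------------------------------------


def simulate_composition_counts(
    phase: PhaseLabel | str,
    alphas: dict[str, list[float]],
    depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one genus-level count vector for a sample in ``phase``.

    Dirichlet-multinomial: proportions ~ Dirichlet(alpha_phase), counts ~
    Multinomial(depth, proportions).  Counts sum exactly to ``depth``.
    """
    key = phase.name if isinstance(phase, PhaseLabel) else str(phase)
    if key not in alphas:
        raise KeyError(f"unknown phase label {key!r}; expected one of {sorted(alphas)}")
    if depth < 1:
        raise ValueError(f"sequencing depth must be >= 1, got {depth}")
    p = rng.dirichlet(np.asarray(alphas[key], dtype=float))
    return rng.multinomial(int(depth), p)


def dirichlet_mean_fractions(alphas: list[float]) -> np.ndarray:
    a = np.asarray(alphas, dtype=float)
    return a / a.sum()


# ---------------------------------------------------------------------------
# Growth and nutrition
# ---------------------------------------------------------------------------


@dataclass
class _SubjectFrame:
    """Internal per-subject scaffold shared by the generator stages."""

    subject_id: str
    sex: str
    ga_birth: float
    discharge_dol: int
    sample_dols: np.ndarray  # integer DOLs of the weekly samples
    path: list[PhaseLabel]  # phase at each sample


def _daily_nutrition_intents(
    frame: _SubjectFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-kg daily nutrition plan for DOL 1..discharge.

    Calories ramp from ~60 toward ~120 kcal/kg/day over the first two
    weeks; the enteral fraction follows a logistic ramp whose midpoint is
    later for more premature infants; macronutrients sit in standard
    NICU ranges (protein ~3.2, lipid ~2.8 g/kg/day) with carbohydrate
    absorbing the remaining calories.
    """
    days = np.arange(1, frame.discharge_dol + 1)
    n = len(days)
    kcal_kg = 60.0 + 60.0 * (1.0 - np.exp(-days / 10.0)) + rng.normal(0.0, 5.0, n)
    kcal_kg = np.clip(kcal_kg, 40.0, None)
    ramp_mid = 12.0 + 0.5 * (30.0 - frame.ga_birth) + rng.normal(0.0, 3.0)
    enteral_frac = 1.0 / (1.0 + np.exp(-(days - ramp_mid) / 4.0))
    enteral_frac = np.clip(enteral_frac + rng.normal(0.0, 0.03, n), 0.0, 1.0)
    protein_g_kg = np.clip(rng.normal(3.2, 0.3, n), 1.5, None)
    lipid_g_kg = np.clip(rng.normal(2.8, 0.4, n), 1.0, None)
    carb_g_kg = np.clip((kcal_kg - 4.0 * protein_g_kg - 9.0 * lipid_g_kg) / 4.0, 0.0, None)
    return pd.DataFrame(
        {
            "dol": days,
            "kcal_kg": kcal_kg,
            "enteral_frac": enteral_frac,
            "protein_g_kg": protein_g_kg,
            "lipid_g_kg": lipid_g_kg,
            "carb_g_kg": carb_g_kg,
        }
    )


def _weekly_covariates_from_intents(
    intents: pd.DataFrame, sample_dols: np.ndarray
) -> pd.DataFrame:
    """Nutrition covariates over the 7 days before each sample, computed
    directly from the per-kg intents (the generative counterpart of the
    analysis-side window sums)."""
    rows = []
    by_dol = intents.set_index("dol")
    for dol in sample_dols:
        window = by_dol.loc[max(1, dol - 7) : dol - 1]
        kcal = window["kcal_kg"].sum()
        enteral = (window["kcal_kg"] * window["enteral_frac"]).sum()
        rows.append(
            {
                "dol": int(dol),
                "kcal_per_kg_week": kcal,
                "enteral_proportion": enteral / kcal if kcal > 0 else np.nan,
                "protein_ratio": (window["protein_g_kg"] / window["kcal_kg"]).sum(),
                "lipid_ratio": (window["lipid_g_kg"] / window["kcal_kg"]).sum(),
                "carb_ratio": (window["carb_g_kg"] / window["kcal_kg"]).sum(),
            }
        )
    return pd.DataFrame(rows)


def simulate_growth_and_nutrition(
    frame: _SubjectFrame,
    config: SimConfig,
    chart: LMSChart,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the daily ledger and per-sample weights for one subject.

    Weight Z-scores are generated on the Z scale as the Model-B-style
    linear predictor (phase indicators, centered gestational age, weekly
    nutrition covariates) plus a subject random intercept plus i.i.d.
    noise, then mapped to kilograms through the LMS chart.  The ledger
    stores absolute kcal and grams per day together with that day's
    weight, so the analysis side can recover per-kg values exactly.

    Returns ``(ledger, samples)`` where ``samples`` has one row per
    weekly sample with columns dol, pma, weight_kg, zscore and the
    nutrition covariates used in the linear predictor.
    """
    if len(frame.path) == 0:
        raise ValueError("phase path must be nonempty")
    betas = config.growth_betas
    intents = _daily_nutrition_intents(frame, rng)
    cov = _weekly_covariates_from_intents(intents, frame.sample_dols)

    a_i = rng.normal(0.0, config.random_intercept_sd)
    eps = rng.normal(0.0, config.residual_sd, len(frame.sample_dols))
    z = np.empty(len(frame.sample_dols))
    for j, (dol, phase) in enumerate(zip(frame.sample_dols, frame.path)):
        row = cov.iloc[j]
        lin = (
            betas.get("intercept", 0.0)
            + betas.get("p1", 0.0) * (phase == PhaseLabel.P1)
            + betas.get("p2", 0.0) * (phase == PhaseLabel.P2)
            + betas.get("ga_birth_c", 0.0) * (frame.ga_birth - 29.0)
            + betas.get("enteral_proportion", 0.0) * row["enteral_proportion"]
            + betas.get("kcal_per_kg_week", 0.0) * row["kcal_per_kg_week"]
            + betas.get("protein_ratio", 0.0) * row["protein_ratio"]
            + betas.get("lipid_ratio", 0.0) * row["lipid_ratio"]
        )
        z[j] = lin + a_i + eps[j]

    pma = frame.ga_birth + frame.sample_dols / 7.0
    weight = np.array(
        [_lms_weight(chart, frame.sex, p, zz) for p, zz in zip(pma, z)]
    )
    samples = cov.copy()
    samples.insert(1, "pma", pma)
    samples["zscore"] = z
    samples["weight_kg"] = weight

    # daily weights: interpolate between birth weight (z = a_i) and samples
    birth_w = _lms_weight(chart, frame.sex, frame.ga_birth, a_i)
    day_grid = intents["dol"].to_numpy()
    known_dols = np.concatenate([[0], frame.sample_dols])
    known_w = np.concatenate([[birth_w], weight])
    daily_w = np.interp(day_grid, known_dols, known_w)

    ledger_rows = []
    for i, day in enumerate(day_grid):
        w = daily_w[i]
        r = intents.iloc[i]
        date = (_EPOCH + pd.Timedelta(days=int(day))).date().isoformat()
        for route, fac in (("enteral", r["enteral_frac"]), ("parenteral", 1 - r["enteral_frac"])):
            if fac <= 1e-9:
                continue
            ledger_rows.append(
                {
                    "subject_id": frame.subject_id,
                    "date": date,
                    "kcal": r["kcal_kg"] * w * fac,
                    "lipid_g": r["lipid_g_kg"] * w * fac,
                    "protein_g": r["protein_g_kg"] * w * fac,
                    "carb_g": r["carb_g_kg"] * w * fac,
                    "route": route,
                    "weight_kg": w,
                }
            )
    return pd.DataFrame(ledger_rows), samples


def _lms_weight(chart: LMSChart, sex: str, pma: float, z: float) -> float:
    """Invert the LMS transform: weight giving Z-score ``z`` at this PMA."""
    L, M, S = chart.interpolate(sex, pma)
    if abs(L) < 1e-12:
        return M * np.exp(S * z)
    return M * (1.0 + L * S * z) ** (1.0 / L)


# ---------------------------------------------------------------------------
# Diaper records
# ---------------------------------------------------------------------------

_MEC_TEXTS = [
    "dark meconium stool, small amount",
    "thick meconium, diaper changed",
    "meconium noted at change",
]
_NORMAL_TEXTS = [
    "yellow seedy stool, moderate",
    "soft green stool",
    "loose yellow stool, small",
]


def simulate_diaper_records(
    subject_id: str,
    last_p1_dol: float | None,
    n_days: int,
    lag_mean: float,
    lag_sd: float,
    relapse_prob: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, float | None]:
    """Daily timestamped free-text diaper records for one subject.

    Records before the clearance day mention meconium; the clearance day
    is the last-P1 DOL plus a Normal(lag_mean, lag_sd) draw truncated at
    zero, rounded to a whole day.  With probability ``relapse_prob`` up
    to two stray post-clearance meconium mentions are injected (they do
    not move the detected transition, which tolerates two).  When
    ``last_p1_dol`` is None (subject never observed leaving P1) every
    record mentions meconium and no clearance occurs.

    Returns ``(records, clearance_dol)``.
    """
    if last_p1_dol is None:
        clearance = None
    else:
        draw = rng.normal(lag_mean, lag_sd)
        while draw < 0:
            draw = rng.normal(lag_mean, lag_sd)
        clearance = float(round(last_p1_dol + draw))
    relapse_days: set[int] = set()
    if clearance is not None and rng.random() < relapse_prob:
        later = np.arange(clearance + 1, n_days + 1)
        if len(later) > 0:
            k = min(int(rng.integers(1, 3)), len(later))
            relapse_days = set(rng.choice(later, size=k, replace=False).astype(int))
    rows = []
    for day in range(1, n_days + 1):
        is_mec = (clearance is None or day < clearance) or (day in relapse_days)
        pool = _MEC_TEXTS if is_mec else _NORMAL_TEXTS
        text = pool[int(rng.integers(0, len(pool)))]
        ts = (_EPOCH + pd.Timedelta(days=day, hours=8)).isoformat()
        rows.append({"subject_id": subject_id, "timestamp": ts, "text": text})
    if clearance is not None and clearance > n_days:
        clearance = None  # cleared only after discharge; censored in-record
    return pd.DataFrame(rows), clearance


# ---------------------------------------------------------------------------
# Whole cohort
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """All tables of one simulated cohort plus the generating truth."""

    abundance: AbundanceTable  # genus-level raw counts
    metadata: pd.DataFrame  # sample_id, subject_id, sex, ga_birth, dol, pma, weight_kg
    true_phases: pd.Series  # sample_id -> PhaseLabel
    ledger: pd.DataFrame
    medications: pd.DataFrame
    diapers: pd.DataFrame
    truth: pd.DataFrame  # per-subject truth (last P1 DOL, clearance DOL, ...)
    sample_covariates: pd.DataFrame  # generator-side weekly covariates + zscore
    config: SimConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.abundance.write(outdir / "abundance.tsv")
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        self.ledger.to_csv(outdir / "ledger.tsv", sep="\t", index=False)
        self.medications.to_csv(outdir / "medications.tsv", sep="\t", index=False)
        self.diapers.to_csv(outdir / "diapers.tsv", sep="\t", index=False)
        truth = self.truth.copy()
        truth.to_csv(outdir / "truth_subjects.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "sample_id": self.true_phases.index,
                "true_phase": [PhaseLabel(p).name for p in self.true_phases],
            }
        ).to_csv(outdir / "truth_phases.tsv", sep="\t", index=False)
        self.config.to_yaml(outdir / "config.yaml")
        from gutphase.dynamics import TOY_CLASS_TREE_NEWICK

        (outdir / "class_tree.nwk").write_text(TOY_CLASS_TREE_NEWICK + "\n")


def _stratum_counts(config: SimConfig) -> np.ndarray:
    """Apportion subjects to gestational-age strata by largest remainder,
    so every cohort reproduces the configured stratum spread exactly."""
    weights = np.array([s[2] for s in config.ga_birth_strata], dtype=float)
    quota = weights / weights.sum() * config.n_subjects
    counts = np.floor(quota).astype(int)
    short = config.n_subjects - counts.sum()
    for idx in np.argsort(-(quota - counts))[:short]:
        counts[idx] += 1
    return counts


def _draw_ga_births(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    gas = []
    for (lo, hi, _), count in zip(config.ga_birth_strata, _stratum_counts(config)):
        gas.extend(np.round(rng.uniform(lo, hi + 1.0, count), 1))
    return np.array(gas)


def _simulate_medications(
    subject_id: str, n_days: int, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for drug in MED_CLASSES:
        if rng.random() >= MED_EPISODE_PROBS[drug]:
            continue
        for _ in range(int(rng.integers(1, 4))):
            start = int(rng.integers(1, max(2, n_days)))
            duration = int(rng.integers(3, 15))
            for day in range(start, min(start + duration, n_days + 1)):
                date = (_EPOCH + pd.Timedelta(days=day)).date().isoformat()
                rows.append({"subject_id": subject_id, "date": date, "drug_class": drug})
    return pd.DataFrame(rows, columns=["subject_id", "date", "drug_class"])


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    chart = synthetic_lms_chart()

    meta_rows, count_rows, sample_ids, true_phase_rows = [], [], [], []
    ledger_parts, med_parts, diaper_parts, truth_rows, cov_parts = [], [], [], [], []

    ga_births = _draw_ga_births(config, rng)
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:03d}"
        sex = "M" if rng.random() < 0.5 else "F"
        ga = float(ga_births[i])
        discharge_pma = min(
            config.pma_end,
            max(
                ga + 2.0,
                config.discharge_pma_min,
                rng.normal(config.discharge_pma_mean, config.discharge_pma_sd),
            ),
        )
        n_weeks = int(np.floor(discharge_pma - ga))
        if n_weeks < 2:
            n_weeks = 2
        sample_dols = np.array(
            [config.first_sample_dol + k * config.sampling_interval_days for k in range(n_weeks)]
        )
        path = simulate_phase_path(
            ga,
            config.hazard_p1p2,
            config.hazard_p2p3,
            config.reversion_prob,
            n_weeks,
            rng,
        )
        frame = _SubjectFrame(
            subject_id=subject_id,
            sex=sex,
            ga_birth=ga,
            discharge_dol=int(sample_dols[-1]),
            sample_dols=sample_dols,
            path=path,
        )

        ledger, samples = simulate_growth_and_nutrition(frame, config, chart, rng)
        ledger_parts.append(ledger)
        cov = samples.copy()
        cov.insert(0, "subject_id", subject_id)
        cov.insert(
            0, "sample_id", [f"{subject_id}_W{k + 1:02d}" for k in range(len(sample_dols))]
        )
        cov_parts.append(cov)

        depths = rng.negative_binomial(
            config.depth_dispersion,
            config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
            size=n_weeks,
        )
        depths = np.maximum(depths, 1)
        for k in range(n_weeks):
            sid = f"{subject_id}_W{k + 1:02d}"
            sample_ids.append(sid)
            counts = simulate_composition_counts(
                path[k], config.dirichlet_alphas, int(depths[k]), rng
            )
            count_rows.append(counts)
            true_phase_rows.append(path[k])
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subject_id,
                    "sex": sex,
                    "ga_birth": ga,
                    "dol": int(sample_dols[k]),
                    "pma": ga + sample_dols[k] / 7.0,
                    "weight_kg": samples["weight_kg"].iloc[k],
                }
            )

        # last P1 sample DOL before the initial exit from P1 (generator truth)
        last_p1 = None
        if path[0] == PhaseLabel.P1:
            exit_idx = next((j for j, p in enumerate(path) if p != PhaseLabel.P1), None)
            if exit_idx is not None:
                last_p1 = float(sample_dols[exit_idx - 1])
        elif any(p != PhaseLabel.P1 for p in path):
            last_p1 = 0.0  # exited before the first sample
        diapers, clearance = simulate_diaper_records(
            subject_id,
            last_p1,
            frame.discharge_dol,
            config.meconium_lag_mean,
            config.meconium_lag_sd,
            config.meconium_relapse_prob,
            rng,
        )
        diaper_parts.append(diapers)
        med_parts.append(_simulate_medications(subject_id, frame.discharge_dol, rng))
        truth_rows.append(
            {
                "subject_id": subject_id,
                "ga_birth": ga,
                "sex": sex,
                "discharge_dol": frame.discharge_dol,
                "true_last_p1_dol": last_p1,
                "true_clearance_dol": clearance,
            }
        )

    counts_df = pd.DataFrame(
        np.vstack(count_rows), index=pd.Index(sample_ids, name="sample_id"), columns=TAXA
    )
    metadata = pd.DataFrame(meta_rows)
    return SyntheticCohort(
        abundance=AbundanceTable(counts_df),
        metadata=metadata,
        true_phases=pd.Series(
            true_phase_rows, index=sample_ids, name="true_phase", dtype=object
        ),
        ledger=pd.concat(ledger_parts, ignore_index=True),
        medications=pd.concat(med_parts, ignore_index=True),
        diapers=pd.concat(diaper_parts, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        sample_covariates=pd.concat(cov_parts, ignore_index=True),
        config=config,
    )


# ---------------------------------------------------------------------------
# Focused generators for calibration-style checks
# ---------------------------------------------------------------------------


def simulate_variance_bump_curves(
    n_subjects: int,
    center: float,
    rng: np.random.Generator,
    pma_range: tuple[float, float] = (24.0, 46.0),
    width: float = 2.5,
    noise_sd: float = 0.15,
    n_obs: int = 12,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Longitudinal observations whose between-subject variance peaks at
    ``center``: x_i(t) = a_i * exp(-(t-center)^2 / (2 width^2)) + noise,
    a_i ~ N(0, 1).  Returns (observations, metadata) shaped like one
    taxon's normalized abundance for the changepoint machinery."""
    lo, hi = pma_range
    rows, meta = [], []
    for i in range(n_subjects):
        subject = f"B{i + 1:03d}"
        a_i = rng.normal(0.0, 1.0)
        t = np.sort(rng.uniform(lo, hi, n_obs))
        x = a_i * np.exp(-((t - center) ** 2) / (2 * width**2)) + rng.normal(
            0.0, noise_sd, n_obs
        )
        for k, (tt, xx) in enumerate(zip(t, x)):
            sid = f"{subject}_{k:02d}"
            rows.append({"sample_id": sid, "taxon": "bump", "value": xx})
            meta.append({"sample_id": sid, "subject_id": subject, "pma": tt})
    return pd.DataFrame(rows), pd.DataFrame(meta)


def simulate_regression_dataset(
    n_subjects: int,
    n_obs_per_subject: int,
    betas: dict[str, float],
    random_intercept_sd: float,
    residual_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Small Model-B-style dataset with known coefficients for recovery
    and calibration studies: phase indicators, centered gestational age,
    and nutrition covariates drawn from realistic ranges."""
    rows = []
    for i in range(n_subjects):
        subject = f"R{i + 1:03d}"
        a_i = rng.normal(0.0, random_intercept_sd)
        ga_c = rng.uniform(-6.0, 6.0)
        for j in range(n_obs_per_subject):
            phase = int(rng.integers(1, 4))
            enteral = rng.uniform(0.0, 1.0)
            kcal = rng.uniform(400.0, 900.0)
            protein = rng.uniform(0.1, 0.3)
            lipid = rng.uniform(0.1, 0.3)
            y = (
                betas.get("intercept", 0.0)
                + betas.get("p1", 0.0) * (phase == 1)
                + betas.get("p2", 0.0) * (phase == 2)
                + betas.get("ga_birth_c", 0.0) * ga_c
                + betas.get("enteral_proportion", 0.0) * enteral
                + betas.get("kcal_per_kg_week", 0.0) * kcal
                + betas.get("protein_ratio", 0.0) * protein
                + betas.get("lipid_ratio", 0.0) * lipid
                + a_i
                + rng.normal(0.0, residual_sd)
            )
            rows.append(
                {
                    "subject_id": subject,
                    "p1": float(phase == 1),
                    "p2": float(phase == 2),
                    "ga_birth_c": ga_c,
                    "enteral_proportion": enteral,
                    "kcal_per_kg_week": kcal,
                    "protein_ratio": protein,
                    "lipid_ratio": lipid,
                    "zscore": y,
                }
            )
    return pd.DataFrame(rows)
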