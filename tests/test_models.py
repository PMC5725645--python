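import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutphase.models import (
    RegressionDesign,
    build_model_A,
    build_model_B,
    fit_lmm,
    fit_logistic_mixed,
    fit_phase_logistic,
    likelihood_ratio_test,
    per_taxon_screen,
    regress_growth_on_time_to_p3,
    regress_stool_transition,
    stepwise_aic,
)
from gutphase.periods import Period
from gutphase.phases import PhaseLabel
from gutphase.simulate import simulate_regression_dataset


def _design_from(df, cols, outcome="zscore", groups="subject_id"):
    X = pd.DataFrame({"const": 1.0}, index=df.index)
    for c in cols:
        X[c] = df[c]
    return RegressionDesign(
        y=df[outcome], X=X, groups=df[groups], terms={c: [c] for c in cols}
    )


class TestLMMEngine:
    def test_reduces_to_ols_when_no_subject_variance(self, rng):
        df = simulate_regression_dataset(
            40, 5, {"p2": -0.7766, "ga_birth_c": 0.06}, 0.0, 0.4, rng
        )
        # center the noise within each subject so the REML estimate of the
        # between-subject variance sits exactly at the zero boundary
        resid = df["zscore"] - df.groupby("subject_id")["zscore"].transform("mean")
        fitted_mean = df.groupby("subject_id")["zscore"].transform("mean")
        df["zscore"] = fitted_mean * 0 + resid + df["zscore"].mean()
        cols = ["p1", "p2", "ga_birth_c"]
        fit = fit_lmm(_design_from(df, cols))
        assert fit.sigma2_subject <= 1e-8
        X = np.column_stack([np.ones(len(df))] + [df[c] for c in cols])
        beta_ols = np.linalg.lstsq(X, df["zscore"], rcond=None)[0]
        np.testing.assert_allclose(fit.params.to_numpy(), beta_ols, atol=1e-6)

    def test_matches_reference_mixed_model_fit(self, rng):
        """Cross-check against the statsmodels REML fit on data with a
        real random-intercept component."""
        import statsmodels.formula.api as smf

        df = simulate_regression_dataset(
            50, 5, {"p2": -0.7766, "enteral_proportion": -0.5566}, 0.6, 0.35, rng
        )
        fit = fit_lmm(_design_from(df, ["p2", "enteral_proportion"]))
        ref = smf.mixedlm(
            "zscore ~ p2 + enteral_proportion", df, groups=df["subject_id"]
        ).fit(reml=True)
        np.testing.assert_allclose(
            fit.params.to_numpy(),
            ref.params[["Intercept", "p2", "enteral_proportion"]].to_numpy(),
            atol=1e-5,
        )
        assert fit.sigma2_resid == pytest.approx(ref.scale, rel=1e-4)
        assert fit.sigma2_subject == pytest.approx(ref.cov_re.iloc[0, 0], rel=1e-3)
        assert fit.loglik_reml == pytest.approx(ref.llf, abs=1e-4)

    def test_aic_identity(self, rng):
        df = simulate_regression_dataset(30, 4, {"p2": -0.5}, 0.3, 0.3, rng)
        fit = fit_lmm(_design_from(df, ["p2"]))
        n_par = 2 + 2  # const + p2 + two variance components
        assert fit.aic == pytest.approx(-2 * fit.loglik_ml + 2 * n_par)

    def test_singular_design_drops_aliased_and_warns(self, rng):
        df = simulate_regression_dataset(20, 4, {"p2": -0.5}, 0.3, 0.3, rng)
        df["dup"] = df["p2"] * 2.0
        with pytest.warns(UserWarning, match="aliased"):
            fit = fit_lmm(_design_from(df, ["p2", "dup"]))
        # one of the two collinear columns is dropped and reported
        assert len(fit.dropped) == 1 and fit.dropped[0] in {"p2", "dup"}

    def test_needs_two_subjects(self, rng):
        df = simulate_regression_dataset(1, 6, {"p2": -0.5}, 0.3, 0.3, rng)
        with pytest.raises(ValueError, match="2 subjects"):
            fit_lmm(_design_from(df, ["p2"]))

    def test_recovers_generating_coefficient_within_2se(self, rng):
        """Quick coverage check of the reference phase-2 coefficient;
        the full replicate study runs in the acceptance suite."""
        hits = 0
        for _ in range(20):
            df = simulate_regression_dataset(
                80, 5, {"p2": -0.7766, "ga_birth_c": 0.059}, 0.45, 0.3, rng
            )
            fit = fit_lmm(_design_from(df, ["p1", "p2", "ga_birth_c"]))
            if abs(fit.params["p2"] - (-0.7766)) < 2 * fit.bse["p2"]:
                hits += 1
        assert hits >= 18


class TestModelDesigns:
    def _cohort_pieces(self, rng, n=30):
        df = simulate_regression_dataset(n, 4, {"p2": -0.7766}, 0.4, 0.3, rng)
        df["sample_id"] = [f"x{i}" for i in range(len(df))]
        for med in ("antibiotics", "diuretics", "corticosteroids", "motility", "ppi", "h2ra"):
            df[med] = rng.integers(0, 2, len(df)).astype(float)
        df["carb_ratio"] = rng.uniform(0.1, 0.3, len(df))
        phases = pd.Series(
            [
                PhaseLabel.P1 if r.p1 else PhaseLabel.P2 if r.p2 else PhaseLabel.P3
                for r in df.itertuples()
            ],
            index=df["sample_id"],
            dtype=object,
        )
        z = pd.Series(df["zscore"].to_numpy(), index=df["sample_id"])
        ga = pd.Series(df["ga_birth_c"].to_numpy() + 29.0, index=df["sample_id"])
        return df, phases, z, ga

    def test_interaction_count_is_phases_times_covariates(self, rng):
        df, phases, z, ga = self._cohort_pieces(rng)
        names = [
            "kcal_per_kg_week", "enteral_proportion", "protein_ratio", "lipid_ratio",
            "antibiotics", "diuretics", "corticosteroids", "motility", "ppi", "h2ra",
        ]
        design = build_model_B(df, phases, z, ga, covariate_names=names)
        inters = [t for t in design.terms if ":" in t]
        assert len(inters) == 2 * 10
        assert all(design.hierarchy[t] for t in inters)

    def test_all_p3_aliases_phase_indicators(self, rng):
        df, phases, z, ga = self._cohort_pieces(rng)
        phases[:] = PhaseLabel.P3
        design = build_model_B(df, phases, z, ga, covariate_names=["enteral_proportion"])
        with pytest.warns(UserWarning, match="aliased"):
            fit = fit_lmm(design)
        assert "p1" in fit.dropped and "p2" in fit.dropped

    def test_missing_covariate_column_is_error(self, rng):
        df, phases, z, ga = self._cohort_pieces(rng)
        with pytest.raises(KeyError, match="no_such"):
            build_model_B(df, phases, z, ga, covariate_names=["no_such"])

    def test_model_a_uses_early_indicator(self, rng):
        df, phases, z, ga = self._cohort_pieces(rng)
        periods = pd.Series(
            [Period.EARLY if i % 2 else Period.LATE for i in range(len(df))],
            index=df["sample_id"],
        )
        design = build_model_A(df, periods, z, ga, covariate_names=["enteral_proportion"])
        assert set(design.X["early"].unique()) == {0.0, 1.0}


class TestStepwise:
    def test_noise_covariate_usually_removed(self, rng):
        removed = 0
        reps = 30
        for _ in range(reps):
            df = simulate_regression_dataset(
                60, 4, {"p2": -0.7766, "ga_birth_c": 0.059}, 0.3, 0.3, rng
            )
            df["noise"] = rng.normal(size=len(df))
            design = _design_from(df, ["p2", "ga_birth_c", "noise"])
            _, kept = stepwise_aic(design)
            removed += "noise" not in kept
        # AIC retains a single null covariate with probability
        # P(chi2_1 > 2) ~ 0.157, so removal should sit near 84%
        assert removed >= 0.7 * reps

    def test_returns_initial_model_when_nothing_improves(self, rng):
        df = simulate_regression_dataset(
            80, 4, {"p2": -0.9, "ga_birth_c": 0.3}, 0.2, 0.2, rng
        )
        design = _design_from(df, ["p2", "ga_birth_c"])
        fit, kept = stepwise_aic(design)
        assert kept == ["ga_birth_c", "p2"]

    def test_forced_in_terms_respected(self, rng):
        df = simulate_regression_dataset(40, 4, {"p2": -0.8}, 0.3, 0.3, rng)
        df["noise"] = rng.normal(size=len(df))
        design = _design_from(df, ["p2", "noise"])
        _, kept = stepwise_aic(design, forced_in=("noise",))
        assert "noise" in kept

    def test_hierarchy_keeps_mains_under_interactions(self, rng):
        df = simulate_regression_dataset(60, 4, {}, 0.3, 0.3, rng)
        df["a"] = rng.normal(size=len(df))
        df["b"] = rng.normal(size=len(df))
        df["a:b"] = df["a"] * df["b"]
        # outcome driven purely by the interaction
        df["zscore"] = 1.5 * df["a:b"] + rng.normal(0, 0.3, len(df))
        design = _design_from(df, ["a", "b", "a:b"])
        design.hierarchy = {"a:b": ("a", "b")}
        _, kept = stepwise_aic(design)
        assert "a:b" in kept
        assert "a" in kept and "b" in kept

    def test_invariant_to_term_order(self, rng):
        df = simulate_regression_dataset(
            50, 4, {"p2": -0.7, "ga_birth_c": 0.06}, 0.3, 0.3, rng
        )
        df["noise"] = rng.normal(size=len(df))
        d1 = _design_from(df, ["p2", "ga_birth_c", "noise"])
        d2 = _design_from(df, ["noise", "ga_birth_c", "p2"])
        _, k1 = stepwise_aic(d1)
        _, k2 = stepwise_aic(d2)
        assert k1 == k2


def _logistic_data(rng, n_groups=40, n_obs=4, beta_x=0.0, sigma=0.8):
    rows = []
    for i in range(n_groups):
        a = rng.normal(0, sigma)
        for _ in range(n_obs):
            x = rng.normal()
            p = 1.0 / (1.0 + np.exp(-(-0.3 + beta_x * x + a)))
            rows.append((f"g{i}", x, float(rng.random() < p)))
    return pd.DataFrame(rows, columns=["g", "x", "y"])


class TestLogisticMixed:
    def test_lrt_type_i_error_calibrated(self, rng):
        """Null covariate: LRT rejection rate close to alpha, and the
        p-value distribution consistent with uniformity."""
        pvals = []
        for _ in range(400):
            df = _logistic_data(rng, beta_x=0.0)
            X = pd.DataFrame({"const": 1.0, "x": df.x})
            full = fit_logistic_mixed(df.y, X, df.g)
            red = fit_logistic_mixed(df.y, X[["const"]], df.g)
            pvals.append(likelihood_ratio_test(full, red)[1])
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.025 <= rate <= 0.08
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_effect_sign_recovered(self, rng):
        for _ in range(15):
            df = _logistic_data(rng, n_groups=60, beta_x=1.2)
            X = pd.DataFrame({"const": 1.0, "x": df.x})
            fit = fit_logistic_mixed(df.y, X, df.g)
            assert fit.params["x"] > 0

    def test_separation_is_flagged_and_penalized(self, rng):
        df = _logistic_data(rng, n_groups=20, n_obs=3)
        df["y"] = (df["x"] > 0).astype(float)  # perfectly separable
        X = pd.DataFrame({"const": 1.0, "x": df.x})
        fit = fit_logistic_mixed(df.y, X, df.g)
        assert fit.separation and fit.penalized

    def test_phase_model_errors_without_outcome_samples(self, rng):
        df = simulate_regression_dataset(10, 3, {}, 0.3, 0.3, rng)
        df["sample_id"] = [f"x{i}" for i in range(len(df))]
        phases = pd.Series([PhaseLabel.P3] * len(df), index=df["sample_id"], dtype=object)
        meta = pd.DataFrame(
            {
                "sample_id": df["sample_id"],
                "subject_id": df["subject_id"],
                "pma": 30.0,
                "ga_birth": 28.0,
            }
        )
        with pytest.raises(ValueError, match="no P1 samples"):
            fit_phase_logistic(
                df, phases, meta, Period.EARLY,
                covariate_names=["enteral_proportion"],
            )


class TestSimpleRegressions:
    def test_exact_lag_free_relation_gives_r2_one(self):
        df = pd.DataFrame(
            {
                "last_p1_dol": [7.0, 14, 21, 28, 35],
                "ga_birth": [24.0, 31, 26, 33, 25],
                "stool_dol": [7.0, 14, 21, 28, 35],
            }
        )
        fit = regress_stool_transition(df)
        assert fit.rsquared == pytest.approx(1.0)
        assert fit.params["last_p1_dol"] == pytest.approx(1.0)

    def test_normal_lag_recovers_slope_intercept_and_null_ga(self, rng):
        n = 200
        last_p1 = rng.uniform(7, 42, n)
        ga = rng.uniform(23, 34, n)
        stool = last_p1 + rng.normal(4.7, 2.0, n)
        fit = regress_stool_transition(
            pd.DataFrame({"last_p1_dol": last_p1, "ga_birth": ga, "stool_dol": stool})
        )
        assert abs(fit.params["last_p1_dol"] - 1.0) < 2 * fit.bse["last_p1_dol"]
        assert abs(fit.params["const"] - 4.7) < 2.5 * fit.bse["const"]
        assert abs(fit.params["ga_birth"]) < 2.5 * fit.bse["ga_birth"]

    def test_permuted_outcome_kills_r2(self, rng):
        n = 100
        last_p1 = rng.uniform(7, 42, n)
        stool = rng.permutation(last_p1 + rng.normal(4.7, 2.0, n))
        fit = regress_stool_transition(
            pd.DataFrame(
                {"last_p1_dol": last_p1, "ga_birth": rng.uniform(23, 34, n),
                 "stool_dol": stool}
            )
        )
        assert fit.rsquared < 0.1

    def test_zero_variance_predictor_named(self):
        df = pd.DataFrame(
            {"last_p1_dol": [7.0, 14, 21], "ga_birth": [28.0, 28, 28],
             "stool_dol": [10.0, 18, 26]}
        )
        with pytest.raises(ValueError, match="ga_birth"):
            regress_stool_transition(df)

    def test_too_few_subjects_is_error(self):
        df = pd.DataFrame(
            {"last_p1_dol": [7.0, 14], "ga_birth": [24.0, 30], "stool_dol": [10.0, 20]}
        )
        with pytest.raises(ValueError, match="3 usable"):
            regress_stool_transition(df)

    def test_growth_vs_time_to_p3_negative_slope(self, rng):
        n = 120
        first_p3 = rng.uniform(14, 80, n)
        ga = rng.uniform(23, 34, n)
        dz = -0.02 * first_p3 + rng.normal(0, 0.3, n)
        fit = regress_growth_on_time_to_p3(
            pd.DataFrame({"first_p3_dol": first_p3, "ga_birth": ga, "delta_z": dz})
        )
        assert abs(fit.params["first_p3_dol"] - (-0.02)) < 2 * fit.bse["first_p3_dol"]
        assert fit.params["first_p3_dol"] < 0

    def test_censored_subjects_excluded(self, rng):
        df = pd.DataFrame(
            {
                "first_p3_dol": [20.0, 30, np.nan, 50, 60],
                "ga_birth": [24.0, 26, 28, 30, 32],
                "delta_z": [-0.4, -0.6, -0.2, -1.0, -1.2],
            }
        )
        fit = regress_growth_on_time_to_p3(df)
        assert fit.n_obs == 4


class TestPerTaxonScreen:
    def test_detects_planted_effects_and_controls_nulls(self, rng):
        n_subj, n_obs = 40, 5
        n_taxa, n_hot = 24, 6
        rows_meta, values, cov = [], {}, {}
        effect = 0.8
        for i in range(n_subj):
            a = rng.normal(0, 0.4)
            ga = rng.uniform(24, 34)
            for j in range(n_obs):
                sid = f"s{i}_{j}"
                pma = ga + (j + 1)
                x = rng.normal()
                rows_meta.append(
                    {"sample_id": sid, "subject_id": f"s{i}", "ga_birth": ga, "pma": pma}
                )
                cov[sid] = x
                row = rng.normal(0, 0.5, n_taxa) + a
                row[:n_hot] += effect * x
                values[sid] = row
        meta = pd.DataFrame(rows_meta)
        vdf = pd.DataFrame.from_dict(values, orient="index",
                                     columns=[f"taxon{k}" for k in range(n_taxa)])
        res = per_taxon_screen(vdf, pd.Series(cov), meta)
        hot = res.iloc[:n_hot]
        null = res.iloc[n_hot:]
        assert (hot["q_covariate"] < 0.05).sum() >= n_hot - 1
        assert (null["q_covariate"] < 0.05).mean() <= 0.1
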