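"""Association models: linear and logistic mixed-effects regressions.

The growth models regress weight Z-score on developmental stage plus
nutrition/medication covariates and their interactions, with a subject
random intercept:

    Model A:  z_ij = Period_i(t_j) b_period + sum_k NutriMed_ik(t_j) b_k
                      + interactions + a_i + e_ij
    Model B:  z_ij = Phase_i(t_j)  b_phase  + sum_k NutriMed_ik(t_j) b_k
                      + interactions + a_i + e_ij

with P3 (resp. LATE) as the reference level coded 0, P1/P2 as separate
binaries (EARLY coded 1).  Fixed effects are estimated by REML with a
dedicated profiled solver for the single-variance-component model;
fixed-effect tests use t statistics with Satterthwaite degrees of
freedom (numeric gradients of the coefficient variance with respect to
the variance components, against the inverse REML information — the
same recipe lmerTest applies to lme4 fits).  Model search is greedy
bidirectional stepwise on AIC (ML likelihood), with interactions never
retained without their main effects.

Phase prediction uses a mixed-effects logistic regression (subject
random intercept, Gauss-Hermite quadrature) with likelihood-ratio tests
per covariate, fitted separately in the EARLY and LATE periods with P1
and P2 as separate binary outcomes against the P3 baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import qr as _qr
from scipy.special import expit, logsumexp
from statsmodels.stats.multitest import multipletests

from gutphase.config import MED_CLASSES
from gutphase.phases import PhaseLabel
from gutphase.periods import Period

NUTRITION_TERMS = [
    "kcal_per_kg_week",
    "enteral_proportion",
    "protein_ratio",
    "lipid_ratio",
    "carb_ratio",
]


# ---------------------------------------------------------------------------
# Design containers
# ---------------------------------------------------------------------------


@dataclass
class RegressionDesign:
    """Outcome, fixed-effect matrix and random-intercept grouping.

    ``terms`` maps a term name to its design columns; ``hierarchy`` maps
    an interaction term to the main-effect terms it depends on.
    """

    y: pd.Series
    X: pd.DataFrame
    groups: pd.Series
    terms: dict[str, list[str]] = field(default_factory=dict)
    hierarchy: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def subset(self, keep_terms: list[str]) -> "RegressionDesign":
        cols = ["const"] + [c for t in keep_terms for c in self.terms[t]]
        return RegressionDesign(
            y=self.y,
            X=self.X[cols],
            groups=self.groups,
            terms={t: self.terms[t] for t in keep_terms},
            hierarchy={t: p for t, p in self.hierarchy.items() if t in keep_terms},
        )


@dataclass
class FitResult:
    """Coefficients, variance components and fit statistics of one model."""

    table: pd.DataFrame  # term, estimate, se, tvalue, df, pvalue
    sigma2_subject: float
    sigma2_resid: float
    loglik_reml: float
    loglik_ml: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    dropped: list[str] = field(default_factory=list)
    flags: dict = field(default_factory=dict)

    @property
    def params(self) -> pd.Series:
        return self.table.set_index("term")["estimate"]

    @property
    def bse(self) -> pd.Series:
        return self.table.set_index("term")["se"]

    @property
    def pvalues(self) -> pd.Series:
        return self.table.set_index("term")["pvalue"]


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model (profiled REML)
# ---------------------------------------------------------------------------


class _GroupedData:
    """Per-group sufficient statistics for the one-way random-intercept model."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        g = groups[order]
        _, starts = np.unique(g, return_index=True)
        self.starts = starts
        self.sizes = np.diff(np.append(starts, len(g)))
        self.n, self.p = X.shape
        self.n_groups = len(self.sizes)
        self.Sx = np.add.reduceat(self.X, starts, axis=0)  # per-group column sums
        self.Sy = np.add.reduceat(self.y, starts)
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def gls(self, c: np.ndarray):
        """GLS pieces for V_i^-1 = I - c_i J: returns (beta, A, rss)."""
        A = self.XtX - (self.Sx.T * c) @ self.Sx
        b = self.Xty - self.Sx.T @ (c * self.Sy)
        q = self.yty - float(c @ self.Sy**2)
        beta = np.linalg.solve(A, b)
        rss = q - float(beta @ b)
        return beta, A, rss


def _reml_neg2_profiled(log_lam: float, gd: _GroupedData) -> float:
    lam = np.exp(log_lam)
    c = lam / (1.0 + lam * gd.sizes)
    try:
        _, A, rss = gd.gls(c)
    except np.linalg.LinAlgError:
        return np.inf
    if rss <= 0:
        return np.inf
    dfres = gd.n - gd.p
    sigma2 = rss / dfres
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return (
        dfres * (np.log(2 * np.pi * sigma2) + 1.0)
        + float(np.sum(np.log1p(lam * gd.sizes)))
        + logdetA
    )


def _ml_neg2_profiled(log_lam: float, gd: _GroupedData) -> float:
    lam = np.exp(log_lam)
    c = lam / (1.0 + lam * gd.sizes)
    try:
        _, _, rss = gd.gls(c)
    except np.linalg.LinAlgError:
        return np.inf
    if rss <= 0:
        return np.inf
    sigma2 = rss / gd.n
    return gd.n * (np.log(2 * np.pi * sigma2) + 1.0) + float(
        np.sum(np.log1p(lam * gd.sizes))
    )


def _reml_neg2_theta(theta: np.ndarray, gd: _GroupedData) -> float:
    """Unprofiled REML deviance as a function of (sigma2_subject, sigma2_resid)."""
    s2a, s2e = theta
    if s2e <= 0 or s2a < 0:
        return np.inf
    c_full = s2a / (s2e + gd.sizes * s2a)  # V_i^-1 = (1/s2e)(I - c_i J)
    A = (gd.XtX - (gd.Sx.T * c_full) @ gd.Sx) / s2e
    b = (gd.Xty - gd.Sx.T @ (c_full * gd.Sy)) / s2e
    q = (gd.yty - float(c_full @ gd.Sy**2)) / s2e
    beta = np.linalg.solve(A, b)
    rVr = q - float(beta @ b)
    logdetV = float(np.sum((gd.sizes - 1) * np.log(s2e) + np.log(s2e + gd.sizes * s2a)))
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return logdetV + logdetA + rVr + (gd.n - gd.p) * np.log(2 * np.pi)


def _coef_var_theta(theta: np.ndarray, gd: _GroupedData) -> np.ndarray:
    """Diagonal of cov(beta_hat) at variance components ``theta``."""
    s2a, s2e = theta
    c_full = s2a / (s2e + gd.sizes * s2a)
    A = (gd.XtX - (gd.Sx.T * c_full) @ gd.Sx) / s2e
    return np.diag(np.linalg.inv(A))


def _satterthwaite_df(gd: _GroupedData, theta: np.ndarray) -> np.ndarray:
    """Per-coefficient denominator df by the Satterthwaite recipe."""
    dfres = max(gd.n - gd.p, 1)
    steps = np.maximum(1e-4 * np.maximum(np.abs(theta), 1e-3), 1e-8)

    def _cvar(t):
        return _coef_var_theta(t, gd)

    grads = np.zeros((gd.p, 2))
    for k in range(2):
        hi = theta.copy()
        lo = theta.copy()
        hi[k] += steps[k]
        lo[k] -= steps[k]
        if lo[k] < 0:  # one-sided at the boundary
            lo[k] = theta[k]
            grads[:, k] = (_cvar(hi) - _cvar(lo)) / steps[k]
        else:
            grads[:, k] = (_cvar(hi) - _cvar(lo)) / (2 * steps[k])
    # observed information of the REML deviance, central differences
    H = np.zeros((2, 2))
    f0 = _reml_neg2_theta(theta, gd)
    for i in range(2):
        for j in range(i, 2):
            hi, hj = steps[i], steps[j]
            ti = theta.copy()
            if i == j:
                tp, tm = theta.copy(), theta.copy()
                tp[i] += hi
                tm[i] = max(theta[i] - hi, 0.0 if i == 0 else 1e-12)
                denom = (tp[i] - theta[i]) * (theta[i] - tm[i])
                if denom <= 0:
                    H[i, j] = np.inf
                else:
                    H[i, j] = (
                        _reml_neg2_theta(tp, gd) - 2 * f0 + _reml_neg2_theta(tm, gd)
                    ) / denom
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[[i, j]] += [hi, hj]
                tpm[i] += hi
                tpm[j] = max(theta[j] - hj, 1e-12)
                tmp[i] = max(theta[i] - hi, 0.0)
                tmp[j] += hj
                tmm[i] = max(theta[i] - hi, 0.0)
                tmm[j] = max(theta[j] - hj, 1e-12)
                H[i, j] = H[j, i] = (
                    _reml_neg2_theta(tpp, gd)
                    - _reml_neg2_theta(tpm, gd)
                    - _reml_neg2_theta(tmp, gd)
                    + _reml_neg2_theta(tmm, gd)
                ) / (4 * hi * hj)
    cvar = _coef_var_theta(theta, gd)
    df = np.full(gd.p, float(dfres))
    try:
        vtheta = 2.0 * np.linalg.inv(H)  # asymptotic cov of the variance components
    except np.linalg.LinAlgError:
        return df
    for k in range(gd.p):
        g = grads[k]
        denom = float(g @ vtheta @ g)
        if denom > 0 and np.isfinite(denom):
            df[k] = np.clip(2.0 * cvar[k] ** 2 / denom, 1.0, dfres)
    return df


def _drop_aliased(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    mat = X.to_numpy(dtype=float)
    _, R, piv = _qr(mat, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(mat.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [X.columns[i] for i in sorted(piv[rank:])]
    return X.iloc[:, keep], dropped


def fit_lmm(design: RegressionDesign, satterthwaite: bool = True) -> FitResult:
    """REML fit of a linear mixed model with a subject random intercept.

    Aliased (rank-deficient) columns are dropped and reported; fixed
    effects are tested with Satterthwaite-df t tests.  When the
    between-subject variance estimate is zero the fit coincides with
    ordinary least squares.
    """
    X, dropped = _drop_aliased(design.X)
    if dropped:
        warnings.warn(f"dropping aliased design columns: {dropped}")
    y = design.y.to_numpy(dtype=float)
    groups = pd.factorize(design.groups)[0]
    if len(np.unique(groups)) < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    gd = _GroupedData(y, X.to_numpy(dtype=float), groups)

    res = optimize.minimize_scalar(
        _reml_neg2_profiled, args=(gd,), bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    # the boundary lambda -> 0 (OLS) is checked explicitly
    cand = [(res.fun, res.x)]
    cand.append((_reml_neg2_profiled(-30.0, gd), -30.0))
    fval, log_lam = min(cand)
    lam = np.exp(log_lam)
    c = lam / (1.0 + lam * gd.sizes)
    beta, A, rss = gd.gls(c)
    dfres = gd.n - gd.p
    sigma2_e = rss / dfres
    sigma2_a = lam * sigma2_e
    cov = sigma2_e * np.linalg.inv(A / 1.0)
    se = np.sqrt(np.diag(cov))
    loglik_reml = -0.5 * fval

    res_ml = optimize.minimize_scalar(
        _ml_neg2_profiled, args=(gd,), bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    fml = min(res_ml.fun, _ml_neg2_profiled(-30.0, gd))
    loglik_ml = -0.5 * fml
    n_par = gd.p + 2  # fixed effects + two variance components
    aic = -2.0 * loglik_ml + 2.0 * n_par

    theta = np.array([sigma2_a, sigma2_e])
    if satterthwaite:
        df = _satterthwaite_df(gd, theta)
    else:
        df = np.full(gd.p, float(dfres))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    table = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": beta,
            "se": se,
            "tvalue": tvals,
            "df": df,
            "pvalue": pvals,
        }
    )
    return FitResult(
        table=table,
        sigma2_subject=float(sigma2_a),
        sigma2_resid=float(sigma2_e),
        loglik_reml=float(loglik_reml),
        loglik_ml=float(loglik_ml),
        aic=float(aic),
        n_obs=gd.n,
        n_groups=gd.n_groups,
        converged=bool(res.success and res_ml.success),
        dropped=dropped,
        flags={"satterthwaite": satterthwaite},
    )


# ---------------------------------------------------------------------------
# Model A / Model B designs
# ---------------------------------------------------------------------------


def _assemble(
    covariates: pd.DataFrame,
    stage_cols: dict[str, pd.Series],
    outcome: pd.Series,
    ga_birth: pd.Series,
    covariate_names: list[str],
) -> RegressionDesign:
    df = covariates.set_index("sample_id")
    idx = outcome.index.intersection(df.index)
    missing_cov = [c for c in covariate_names if c not in df.columns]
    if missing_cov:
        raise KeyError(f"missing covariate columns: {missing_cov}")
    X = pd.DataFrame(index=idx)
    X["const"] = 1.0
    terms: dict[str, list[str]] = {}
    hierarchy: dict[str, tuple[str, ...]] = {}
    for name, col in stage_cols.items():
        X[name] = col.loc[idx].astype(float)
        terms[name] = [name]
    X["ga_birth"] = ga_birth.loc[idx].astype(float)
    terms["ga_birth"] = ["ga_birth"]
    for c in covariate_names:
        X[c] = df.loc[idx, c].astype(float)
        terms[c] = [c]
    for stage in stage_cols:
        for c in covariate_names:
            col = f"{c}:{stage}"
            X[col] = X[c] * X[stage]
            terms[col] = [col]
            hierarchy[col] = (c, stage)
    keep = X.notna().all(axis=1) & outcome.loc[idx].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} rows with missing covariates (listwise)")
    idx = idx[keep]
    return RegressionDesign(
        y=outcome.loc[idx],
        X=X.loc[idx],
        groups=df.loc[idx, "subject_id"],
        terms=terms,
        hierarchy=hierarchy,
    )


def build_model_B(
    covariates: pd.DataFrame,
    phases: pd.Series,
    weight_z: pd.Series,
    ga_birth: pd.Series,
    covariate_names: list[str] | None = None,
) -> RegressionDesign:
    """Phase-based growth design: P1/P2 indicators (P3 baseline), gaBirth,
    nutrition/medication covariates, and all phase x covariate products."""
    names = covariate_names if covariate_names is not None else NUTRITION_TERMS + MED_CLASSES
    stage = {
        "p1": phases.map(lambda p: float(p == PhaseLabel.P1)),
        "p2": phases.map(lambda p: float(p == PhaseLabel.P2)),
    }
    return _assemble(covariates, stage, weight_z, ga_birth, names)


def build_model_A(
    covariates: pd.DataFrame,
    periods: pd.Series,
    weight_z: pd.Series,
    ga_birth: pd.Series,
    covariate_names: list[str] | None = None,
) -> RegressionDesign:
    """Period-based growth design: EARLY indicator (LATE baseline), gaBirth,
    covariates, and period x covariate products."""
    names = covariate_names if covariate_names is not None else NUTRITION_TERMS + MED_CLASSES
    stage = {"early": periods.map(lambda p: float(p == Period.EARLY))}
    return _assemble(covariates, stage, weight_z, ga_birth, names)


# ---------------------------------------------------------------------------
# Stepwise AIC
# ---------------------------------------------------------------------------


def stepwise_aic(
    design: RegressionDesign,
    fit_fn=fit_lmm,
    forced_in: tuple[str, ...] = (),
    max_steps: int = 100,
) -> tuple[FitResult, list[str]]:
    """Greedy bidirectional stepwise selection of fixed-effect terms.

    Starts from the full term set, at each step evaluating every legal
    single-term removal or re-addition and taking the one that lowers
    AIC most; stops when nothing improves.  Interactions are never
    retained without their main effects, and a main effect cannot leave
    while one of its interactions is present.  Deterministic: candidates
    are scanned in sorted order and ties keep the first.
    """
    all_terms = sorted(design.terms)
    current = list(all_terms)
    best_fit = fit_fn(design.subset(current))
    best_aic = best_fit.aic
    for _ in range(max_steps):
        moves: list[tuple[str, str]] = []
        parents_in_use = {
            p for t in current for p in design.hierarchy.get(t, ())
        }
        for t in sorted(current):
            if t in forced_in or t in parents_in_use:
                continue
            moves.append(("drop", t))
        for t in sorted(set(all_terms) - set(current)):
            if all(p in current for p in design.hierarchy.get(t, ())):
                moves.append(("add", t))
        best_move = None
        for action, t in moves:
            trial = [x for x in current if x != t] if action == "drop" else sorted(current + [t])
            fit = fit_fn(design.subset(trial))
            if fit.aic < best_aic - 1e-9:
                if best_move is None or fit.aic < best_move[0] - 1e-9:
                    best_move = (fit.aic, action, t, fit, trial)
        if best_move is None:
            break
        best_aic, _, _, best_fit, current = best_move
    return best_fit, sorted(current)


# ---------------------------------------------------------------------------
# Mixed-effects logistic regression (Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------


@dataclass
class LogisticMixedFit:
    params: pd.Series
    loglik: float
    sigma_subject: float
    n_obs: int
    n_groups: int
    converged: bool
    separation: bool = False
    penalized: bool = False


def _gh_loglik_grad(theta, y, X, group_idx, starts, nodes, logw, penalty):
    p = X.shape[1]
    beta, log_sigma = theta[:p], theta[p]
    sigma = np.exp(log_sigma)
    eta0 = X @ beta
    offs = np.sqrt(2.0) * sigma * nodes  # (Q,)
    eta = eta0[:, None] + offs[None, :]  # (n, Q)
    # per-observation bernoulli loglik at each node
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    s = np.add.reduceat(ll_obs, starts, axis=0)  # (G, Q)
    a = s + logw[None, :]
    li = logsumexp(a, axis=1)  # (G,)
    loglik = float(li.sum()) - penalty * float(beta @ beta)
    pi = np.exp(a - li[:, None])  # posterior node weights per group
    resid = y[:, None] - expit(eta)  # (n, Q)
    w_obs = pi[group_idx]  # (n, Q)
    grad_beta = X.T @ (resid * w_obs).sum(axis=1) - 2.0 * penalty * beta
    rg = np.add.reduceat(resid, starts, axis=0)  # (G, Q) residual sums
    grad_logsig = float(((pi * rg) @ (np.sqrt(2.0) * sigma * nodes)).sum())
    return -loglik, -np.concatenate([grad_beta, [grad_logsig]])


def fit_logistic_mixed(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    n_quad: int = 25,
    penalty: float = 0.0,
) -> LogisticMixedFit:
    """Random-intercept logistic regression via Gauss-Hermite quadrature.

    Maximizes the marginal likelihood over (beta, log sigma) with
    analytic gradients.  Suspected complete separation (runaway
    coefficients) is flagged and the model refitted with a small L2
    penalty, which is recorded on the result.
    """
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    gidx_raw = pd.factorize(pd.Series(np.asarray(groups)))[0]
    order = np.argsort(gidx_raw, kind="stable")
    y, Xm, gidx = y[order], Xm[order], gidx_raw[order]
    _, starts = np.unique(gidx, return_index=True)
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(weights) - 0.5 * np.log(np.pi)

    theta0 = np.zeros(Xm.shape[1] + 1)
    theta0[0] = np.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3)) if "const" in cols else 0.0
    theta0[-1] = np.log(0.5)
    res = optimize.minimize(
        _gh_loglik_grad,
        theta0,
        args=(y, Xm, gidx, starts, nodes, logw, penalty),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    beta = res.x[: Xm.shape[1]]
    separation = bool(np.max(np.abs(beta)) > 15.0)
    if separation and penalty == 0.0:
        refit = fit_logistic_mixed(
            pd.Series(y), pd.DataFrame(Xm, columns=cols), pd.Series(gidx),
            n_quad=n_quad, penalty=1e-3,
        )
        return LogisticMixedFit(
            params=refit.params,
            loglik=refit.loglik,
            sigma_subject=refit.sigma_subject,
            n_obs=len(y),
            n_groups=len(starts),
            converged=refit.converged,
            separation=True,
            penalized=True,
        )
    return LogisticMixedFit(
        params=pd.Series(beta, index=cols),
        loglik=float(-res.fun),
        sigma_subject=float(np.exp(res.x[-1])),
        n_obs=len(y),
        n_groups=len(starts),
        converged=bool(res.success),
        separation=separation,
        penalized=penalty > 0,
    )


def likelihood_ratio_test(full: LogisticMixedFit, reduced: LogisticMixedFit) -> tuple[float, float]:
    """LRT statistic and p-value for nested logistic mixed models."""
    df = len(full.params) - len(reduced.params)
    if df <= 0:
        raise ValueError("full model must have more parameters than the reduced one")
    stat = 2.0 * (full.loglik - reduced.loglik)
    return float(stat), float(stats.chi2.sf(max(stat, 0.0), df))


def fit_phase_logistic(
    covariates: pd.DataFrame,
    phases: pd.Series,
    metadata: pd.DataFrame,
    period: Period,
    cutoff: float = 34.0,
    outcome_phase: PhaseLabel = PhaseLabel.P1,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Phase-prediction model for one period and one binary outcome.

    Restricts to samples in the requested period (PMA relative to the
    cutoff), codes ``outcome_phase`` as 1 versus everything else, and
    fits the mixed logistic model with gaBirth and PMA as controls.
    Each covariate's significance is a likelihood-ratio test of the full
    model against the model without it.  Returns a term table with beta
    and LRT p-value.
    """
    names = covariate_names if covariate_names is not None else NUTRITION_TERMS + ["antibiotics", "diuretics"]
    meta = metadata.set_index("sample_id")
    cov = covariates.set_index("sample_id")
    idx = phases.index.intersection(cov.index)
    pma = meta.loc[idx, "pma"].astype(float)
    in_period = pma < cutoff if period == Period.EARLY else pma >= cutoff
    idx = idx[in_period]
    y = pd.Series([float(phases[s] == outcome_phase) for s in idx], index=idx)
    if y.sum() == 0:
        raise ValueError(
            f"no {outcome_phase.name} samples in the {period.value} period; "
            "cannot fit the outcome model"
        )
    X = pd.DataFrame(index=idx)
    X["const"] = 1.0
    X["ga_birth"] = meta.loc[idx, "ga_birth"].astype(float)
    X["pma"] = pma.loc[idx]
    for c in names:
        X[c] = cov.loc[idx, c].astype(float)
    keep = X.notna().all(axis=1)
    X, y = X.loc[keep], y.loc[keep]
    groups = meta.loc[X.index, "subject_id"]
    full = fit_logistic_mixed(y, X, groups)
    rows = []
    for c in names:
        reduced = fit_logistic_mixed(y, X.drop(columns=[c]), groups)
        stat, pval = likelihood_ratio_test(full, reduced)
        rows.append(
            {
                "term": c,
                "beta": float(full.params[c]),
                "lrt_stat": stat,
                "pvalue": pval,
                "separation": full.separation,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simple linear regressions (stool transition, time to P3)
# ---------------------------------------------------------------------------


@dataclass
class OLSResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    n_obs: int


def _ols(df: pd.DataFrame, outcome: str, predictors: list[str]) -> OLSResult:
    import statsmodels.api as sm

    if len(df) < 3:
        raise ValueError(f"need at least 3 usable subjects, got {len(df)}")
    for c in predictors:
        if df[c].nunique() <= 1:
            raise ValueError(f"predictor {c!r} has zero variance")
    X = sm.add_constant(df[predictors].astype(float))
    fit = sm.OLS(df[outcome].astype(float), X).fit()
    return OLSResult(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        rsquared=float(fit.rsquared),
        n_obs=int(fit.nobs),
    )


def regress_stool_transition(subjects: pd.DataFrame) -> OLSResult:
    """Regress stool-transition DOL on last-P1 DOL and gestational age.

    ``subjects`` needs columns stool_dol, last_p1_dol, ga_birth, one row
    per subject observed in P1 at first sample with both events seen.
    """
    df = subjects.dropna(subset=["stool_dol", "last_p1_dol", "ga_birth"])
    return _ols(df, "stool_dol", ["last_p1_dol", "ga_birth"])


def regress_growth_on_time_to_p3(subjects: pd.DataFrame) -> OLSResult:
    """Regress the birth-to-discharge weight Z-score change on the DOL of
    the first P3 sample and gestational age (subjects reaching P3 only)."""
    df = subjects.dropna(subset=["delta_z", "first_p3_dol", "ga_birth"])
    return _ols(df, "delta_z", ["first_p3_dol", "ga_birth"])


# ---------------------------------------------------------------------------
# Per-taxon covariate screen
# ---------------------------------------------------------------------------


def per_taxon_screen(
    values: pd.DataFrame,
    covariate: pd.Series,
    metadata: pd.DataFrame,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Initial mixed-model screen of one covariate against every taxon.

    Per taxon: normalized abundance ~ gaBirth + PMA + covariate +
    covariate x PMA with a subject random intercept; Satterthwaite
    p-values for the covariate and interaction terms are BH-adjusted
    across taxa at ``fdr_level``.
    """
    meta = metadata.set_index("sample_id")
    idx = values.index.intersection(covariate.index)
    X = pd.DataFrame(index=idx)
    X["const"] = 1.0
    X["ga_birth"] = meta.loc[idx, "ga_birth"].astype(float)
    X["pma"] = meta.loc[idx, "pma"].astype(float)
    X["covariate"] = covariate.loc[idx].astype(float)
    # center PMA in the product term: with raw PMA (mean >> spread) the
    # interaction column is nearly collinear with the main effect
    X["covariate:pma"] = X["covariate"] * (X["pma"] - X["pma"].mean())
    groups = meta.loc[idx, "subject_id"]
    rows = []
    for taxon in values.columns:
        design = RegressionDesign(
            y=values.loc[idx, taxon],
            X=X,
            groups=groups,
            terms={c: [c] for c in X.columns if c != "const"},
        )
        fit = fit_lmm(design)
        pv = fit.pvalues
        rows.append(
            {
                "taxon": taxon,
                "beta_covariate": float(fit.params.get("covariate", np.nan)),
                "p_covariate": float(pv.get("covariate", np.nan)),
                "p_interaction": float(pv.get("covariate:pma", np.nan)),
            }
        )
    out = pd.DataFrame(rows)
    for col in ("p_covariate", "p_interaction"):
        mask = out[col].notna()
        q = np.full(len(out), np.nan)
        if mask.any():
            q[mask.to_numpy()] = multipletests(
                out.loc[mask, col], alpha=fdr_level, method="fdr_bh"
            )[1]
        out[col.replace("p_", "q_")] = q
    return out
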