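"""Concurrent-validity statistics.

The analysis layer asks three questions of a scored cohort table: can
the directional offsets of the two slowest complex trajectories
(spiralA, zigzagA) predict an external motor score (cross-sectionally
by OLS, longitudinally by a random-intercept linear mixed model); how
does each offset metric relate to the score per trajectory once age
and age squared are controlled; and how do the offsets relate to age.

Mixed models are random-intercept LMMs, y = X b + Z u + e with one
intercept per participant, fitted by profiled maximum likelihood (ML
when models with different fixed effects are compared, REML for final
variance-component reports).  Fixed-effect F tests use the
Satterthwaite approximation for denominator degrees of freedom.
Variance explained is decomposed the standard way for mixed models:

    R2_marginal    = var(Xb) / (var(Xb) + s2_u + s2_e)
    R2_conditional = (var(Xb) + s2_u) / (var(Xb) + s2_u + s2_e)

and part (semi-partial) R2 of a focal predictor set is the drop in R2
when the focal set is removed with controls retained, with parametric
bootstrap confidence intervals for the LMM variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelReport",
    "fit_ols_prediction",
    "part_r2_ols",
    "fit_lmm",
    "marginal_conditional_r2",
    "part_r2_lmm",
    "adjusted_r",
    "effect_size_d",
    "weighted_mae",
    "run_paper_analysis",
    "cohort_table",
]


class ConvergenceError(RuntimeError):
    """Raised when an LMM fit fails to converge."""


class SpecificationError(ValueError):
    """Raised for invalid model specifications (collinearity, overlap)."""


@dataclass
class ModelReport:
    """Summary of one fitted prediction model."""

    kind: str  # "ols" | "lmm"
    response: str
    predictors: list[str]
    coefficients: dict[str, float]
    se: dict[str, float]
    f_tests: dict[str, dict[str, float]]  # term -> {F, df_num, df_den, p}
    df_method: str
    n_obs: int
    n_participants: int | None = None
    r_squared: float | None = None
    marginal_r2: float | None = None
    conditional_r2: float | None = None
    sigma_u: float | None = None
    sigma_e: float | None = None
    method: str | None = None  # "OLS" | "ML" | "REML"
    loglik: float | None = None
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def _design(table: pd.DataFrame, predictors: Sequence[str], response: str):
    cols = list(predictors) + [response]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise SpecificationError(f"columns not in table: {missing}")
    sub = table.dropna(subset=cols)
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(float) for c in predictors]
    )
    y = sub[response].to_numpy(float)
    names = ["intercept"] + list(predictors)
    return sub, X, y, names


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def fit_ols_prediction(
    table: pd.DataFrame,
    predictors: Sequence[str],
    response: str = "external_score",
) -> ModelReport:
    """Ordinary least squares prediction of the external score.

    Complete-case analysis; reports the overall F, a per-predictor F
    (classical, 1 and n-p-1 df), R-squared, and retains predictions
    and residuals for error summaries and plots.
    """
    import statsmodels.api as sm

    sub, X, y, names = _design(table, predictors, response)
    if len(sub) < len(predictors) + 2:
        raise SpecificationError(
            f"need at least {len(predictors) + 2} complete rows, have {len(sub)}"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        raise SpecificationError(
            f"rank-deficient design; predictor correlations:\n{corr}"
        )
    res = sm.OLS(y, X).fit()
    f_tests = {
        "overall": {
            "F": float(res.fvalue),
            "df_num": float(res.df_model),
            "df_den": float(res.df_resid),
            "p": float(res.f_pvalue),
        }
    }
    for i, name in enumerate(names[1:], start=1):
        t = res.tvalues[i]
        f_tests[name] = {
            "F": float(t**2),
            "df_num": 1.0,
            "df_den": float(res.df_resid),
            "p": float(res.pvalues[i]),
        }
    return ModelReport(
        kind="ols",
        response=response,
        predictors=list(predictors),
        coefficients=dict(zip(names, map(float, res.params))),
        se=dict(zip(names, map(float, res.bse))),
        f_tests=f_tests,
        df_method="classical",
        n_obs=int(res.nobs),
        n_participants=(
            sub["participant_id"].nunique() if "participant_id" in sub else None
        ),
        r_squared=float(res.rsquared),
        method="OLS",
        loglik=float(res.llf),
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        extras={"index": sub.index.to_numpy()},
    )


def part_r2_ols(
    table: pd.DataFrame,
    focal: Sequence[str],
    controls: Sequence[str],
    response: str = "external_score",
) -> float:
    """Semi-partial R2 of the focal predictors over the controls.

    ``part R2 = R2(full) - R2(controls only)`` with the controls always
    retained — the incremental variance uniquely attributable to the
    focal set.
    """
    overlap = set(focal) & set(controls)
    if overlap:
        raise SpecificationError(f"focal and control sets overlap: {sorted(overlap)}")
    sub = table.dropna(subset=list(focal) + list(controls) + [response])
    full = fit_ols_prediction(sub, list(controls) + list(focal), response)
    reduced = fit_ols_prediction(sub, list(controls), response)
    return float(full.r_squared - reduced.r_squared)


# ---------------------------------------------------------------------------
# Random-intercept LMM: profiled (RE)ML
# ---------------------------------------------------------------------------

def _profile_fit(y, X, group_idx, n_groups, reml):
    """Profiled deviance optimization over the variance ratio.

    With lam = s2_u / s2_e, each group block of V is s2_e (I + lam J),
    whose inverse and determinant are closed-form, so the generalized
    least squares step is O(n) per candidate lam.
    """
    n, p = X.shape
    group_sizes = np.bincount(group_idx, minlength=n_groups).astype(float)

    def gls(lam):
        c = lam / (1.0 + lam * group_sizes)  # per-group rank-1 correction
        Sx = np.zeros((n_groups, p))
        Sy = np.zeros(n_groups)
        for j in range(p):
            Sx[:, j] = np.bincount(group_idx, weights=X[:, j], minlength=n_groups)
        Sy = np.bincount(group_idx, weights=y, minlength=n_groups)
        XtWX = X.T @ X - (Sx * c[:, None]).T @ Sx
        XtWy = X.T @ y - (Sx * c[:, None]).T @ Sy
        beta = np.linalg.solve(XtWX, XtWy)
        resid = y - X @ beta
        Sr = np.bincount(group_idx, weights=resid, minlength=n_groups)
        rss = resid @ resid - c @ Sr**2
        return beta, XtWX, rss

    logdet_v = lambda lam: float(np.sum(np.log1p(lam * group_sizes)))

    def neg2ll(loglam):
        lam = np.exp(loglam)
        beta, XtWX, rss = gls(lam)
        if reml:
            dof = n - p
            s2 = rss / dof
            sign, ld_xtwx = np.linalg.slogdet(XtWX)
            return dof * np.log(s2) + logdet_v(lam) + ld_xtwx + dof
        s2 = rss / n
        return n * np.log(s2) + logdet_v(lam) + n

    res = optimize.minimize_scalar(
        neg2ll, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise ConvergenceError(f"profiled LMM optimization failed: {res}")
    lam = float(np.exp(res.x))
    # boundary check: sigma_u = 0
    eps = 1e-10
    if neg2ll(np.log(eps)) <= res.fun + 1e-9:
        lam = 0.0
    beta, XtWX, rss = gls(lam)
    dof = (n - p) if reml else n
    s2e = rss / dof
    s2u = lam * s2e
    cov_beta = s2e * np.linalg.inv(XtWX)
    ll = -0.5 * (neg2ll(np.log(max(lam, eps))) + (dof if reml else n) * np.log(2 * np.pi))
    return beta, cov_beta, s2u, s2e, ll


def _satterthwaite_df(L, X, group_idx, n_groups, s2u, s2e):
    """Satterthwaite denominator df for the contrast L' beta.

    nu = 2 (L' C L)^2 / Var(L' C L), with Var via the delta method:
    the gradient of L' C(th) L in th = (s2_u, s2_e) paired with the
    inverse expected (REML) information of the variance components.
    Dense O(n^2) linear algebra; cohort tables are small.
    """
    n, p = X.shape
    Z = np.zeros((n, n_groups))
    Z[np.arange(n), group_idx] = 1.0
    V = s2u * (Z @ Z.T) + s2e * np.eye(n)
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    C = np.linalg.inv(XtVinv @ X)
    P = Vinv - XtVinv.T @ C @ XtVinv
    dV = [Z @ Z.T, np.eye(n)]
    # gradient of L C L'
    grad = np.empty(2)
    for j, dVj in enumerate(dV):
        dC = C @ (XtVinv @ dVj @ XtVinv.T) @ C
        grad[j] = L @ dC @ L
    info = np.empty((2, 2))
    for j in range(2):
        for k in range(j, 2):
            info[j, k] = info[k, j] = 0.5 * np.trace(P @ dV[j] @ P @ dV[k])
    cov_theta = np.linalg.pinv(info)
    lcl = float(L @ C @ L)
    var_lcl = float(grad @ cov_theta @ grad)
    if var_lcl <= 0:
        return float(n - p)
    return float(2.0 * lcl**2 / var_lcl)


def fit_lmm(
    table: pd.DataFrame,
    predictors: Sequence[str],
    response: str = "external_score",
    groups: str = "participant_id",
    method: str = "REML",
) -> ModelReport:
    """Random-intercept linear mixed model.

    One random intercept per participant captures the repeated-measures
    dependence of sessions.  Per-predictor F tests (each 1 numerator
    df) use Satterthwaite-approximated denominator df; the df method is
    recorded in the report.  Marginal and conditional R2 are computed
    from the fitted variance components.
    """
    if method not in ("REML", "ML"):
        raise ValueError(f"method must be REML or ML, got {method!r}")
    sub, X, y, names = _design(table, predictors, response)
    if groups not in sub.columns:
        raise SpecificationError(f"grouping column {groups!r} not in table")
    codes, uniques = pd.factorize(sub[groups])
    if len(uniques) < 2:
        raise SpecificationError("need at least 2 participants for a mixed model")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SpecificationError("rank-deficient fixed-effects design")
    beta, cov_beta, s2u, s2e, ll = _profile_fit(
        y, X, codes, len(uniques), reml=(method == "REML")
    )
    se = np.sqrt(np.diag(cov_beta))
    f_tests: dict[str, dict[str, float]] = {}
    for i, name in enumerate(names):
        if name == "intercept":
            continue
        L = np.zeros(X.shape[1])
        L[i] = 1.0
        F = float((beta[i] / se[i]) ** 2)
        ddf = _satterthwaite_df(L, X, codes, len(uniques), s2u, s2e)
        f_tests[name] = {
            "F": F,
            "df_num": 1.0,
            "df_den": ddf,
            "p": float(stats.f.sf(F, 1, ddf)),
        }
    fitted_fixed = X @ beta
    var_fixed = float(np.var(fitted_fixed))
    denom = var_fixed + s2u + s2e
    r2m = var_fixed / denom if denom > 0 else np.nan
    r2c = (var_fixed + s2u) / denom if denom > 0 else np.nan
    # conditional (BLUP) residuals for error summaries
    resid_fixed = y - fitted_fixed
    group_sizes = np.bincount(codes).astype(float)
    shrink = s2u / (s2u + s2e / group_sizes) if s2u > 0 else np.zeros(len(uniques))
    group_means = np.bincount(codes, weights=resid_fixed) / group_sizes
    blup = shrink * group_means
    fitted = fitted_fixed + blup[codes]
    return ModelReport(
        kind="lmm",
        response=response,
        predictors=list(predictors),
        coefficients=dict(zip(names, map(float, beta))),
        se=dict(zip(names, map(float, se))),
        f_tests=f_tests,
        df_method="satterthwaite",
        n_obs=len(y),
        n_participants=len(uniques),
        marginal_r2=float(r2m),
        conditional_r2=float(r2c),
        sigma_u=float(np.sqrt(s2u)),
        sigma_e=float(np.sqrt(s2e)),
        method=method,
        loglik=float(ll),
        fitted=fitted,
        residuals=y - fitted,
        extras={
            "fitted_fixed": fitted_fixed,
            "group_codes": codes,
            "group_labels": list(uniques),
            "index": sub.index.to_numpy(),
            "y": y,
            "X": X,
        },
    )


def marginal_conditional_r2(report: ModelReport) -> tuple[float, float]:
    """Nakagawa-style variance decomposition of a fitted LMM.

    Returns (marginal, conditional) R2.  Raises if the total variance
    is degenerate (constant response, no variance components).
    """
    if report.kind != "lmm":
        raise ValueError("marginal/conditional R2 is defined for LMM reports")
    if report.marginal_r2 is None or not np.isfinite(report.marginal_r2):
        raise ValueError("degenerate model: total variance is zero")
    return report.marginal_r2, report.conditional_r2


def part_r2_lmm(
    table: pd.DataFrame,
    focal: Sequence[str],
    controls: Sequence[str],
    response: str = "external_score",
    groups: str = "participant_id",
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Part R2 of a focal predictor set in a random-intercept LMM.

    The marginal (resp. conditional) part R2 is the reduction in
    marginal (conditional) R2 when the focal predictors are removed
    with the controls retained.  Models differing in fixed effects are
    fitted by ML.  Confidence intervals come from a seeded parametric
    bootstrap: responses are simulated from the full model's estimates
    and both models refitted.  Set ``n_boot=0`` to skip the bootstrap.
    """
    overlap = set(focal) & set(controls)
    if overlap:
        raise SpecificationError(f"focal and control sets overlap: {sorted(overlap)}")
    cols = list(controls) + list(focal)
    sub = table.dropna(subset=cols + [response]).copy()
    full = fit_lmm(sub, cols, response, groups, method="ML")
    if controls:
        reduced = fit_lmm(sub, list(controls), response, groups, method="ML")
        red_m, red_c = reduced.marginal_r2, reduced.conditional_r2
    else:
        red_m, red_c = 0.0, full.conditional_r2 - full.marginal_r2
    out = {
        "part_r2_marginal": float(full.marginal_r2 - red_m),
        "part_r2_conditional": float(full.conditional_r2 - red_c),
        "full": full,
    }
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        X = full.extras["X"]
        codes = full.extras["group_codes"]
        n_groups = len(full.extras["group_labels"])
        mu = X @ np.array(list(full.coefficients.values()))
        boot_m = np.empty(n_boot)
        boot_c = np.empty(n_boot)
        sim = sub.copy()
        for b in range(n_boot):
            u = rng.normal(0.0, full.sigma_u, size=n_groups)
            ystar = mu + u[codes] + rng.normal(0.0, full.sigma_e, size=len(mu))
            sim[response] = ystar
            f = fit_lmm(sim, cols, response, groups, method="ML")
            if controls:
                r = fit_lmm(sim, list(controls), response, groups, method="ML")
                boot_m[b] = f.marginal_r2 - r.marginal_r2
                boot_c[b] = f.conditional_r2 - r.conditional_r2
            else:
                boot_m[b] = f.marginal_r2
                boot_c[b] = f.marginal_r2  # removing all fixed effects
        alpha = (1.0 - ci_level) / 2.0
        out["ci_marginal"] = tuple(np.quantile(boot_m, [alpha, 1 - alpha]))
        out["ci_conditional"] = tuple(np.quantile(boot_c, [alpha, 1 - alpha]))
        out["n_boot"] = n_boot
    return out


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------

def adjusted_r(r: float, n: int, p: int) -> float:
    """Correlation adjusted for the number of predictors (Howell).

    ``r_adj = sqrt(max(0, 1 - (1 - r^2)(n - 1)/(n - p - 1)))`` with the
    sign of ``r`` preserved; e.g. r = 0.90 with n = 11 observations and
    p = 2 predictors adjusts to 0.87.
    """
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    adj = 1.0 - (1.0 - r * r) * (n - 1) / (n - p - 1)
    return float(np.sign(r) * np.sqrt(max(0.0, adj)))


def effect_size_d(r: float) -> float:
    """Cohen's d equivalent of a correlation, ``d = 2r / sqrt(1 - r^2)``."""
    if abs(r) >= 1:
        raise ValueError(f"|r| must be < 1 for a finite d, got {r}")
    return float(2.0 * r / np.sqrt(1.0 - r * r))


def weighted_mae(predictions, actual, participant_ids) -> float:
    """Mean absolute error with equal weight per participant.

    Each participant's sessions are first averaged, so participants
    with more sessions do not dominate the error summary.
    """
    predictions = np.asarray(predictions, dtype=float)
    actual = np.asarray(actual, dtype=float)
    ids = np.asarray(participant_ids)
    if not (predictions.shape == actual.shape == ids.shape):
        raise ValueError(
            f"aligned vectors required, got shapes {predictions.shape}, "
            f"{actual.shape}, {ids.shape}"
        )
    if ids.size == 0:
        raise ValueError("need at least one participant")
    abs_err = np.abs(predictions - actual)
    per_participant = pd.Series(abs_err).groupby(pd.Series(ids)).mean()
    return float(per_participant.mean())


def per_participant_mae(predictions, actual, participant_ids) -> pd.Series:
    """Per-participant mean absolute residual (for range reporting)."""
    abs_err = np.abs(np.asarray(predictions, float) - np.asarray(actual, float))
    return pd.Series(abs_err).groupby(pd.Series(np.asarray(participant_ids))).mean()


# ---------------------------------------------------------------------------
# Cohort table and the full analysis
# ---------------------------------------------------------------------------

def cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a cohort table.

    Requires participant_id, session_index, age_years and at least one
    offset column (``dir_<label>`` / ``spa_<label>``); adds ``age_sq``
    and centered age covariates (centering reduces the collinearity of
    age and age squared; part R2 is invariant to it).
    """
    required = {"participant_id", "session_index", "age_years"}
    missing = required - set(df.columns)
    if missing:
        raise SpecificationError(f"cohort table missing columns: {sorted(missing)}")
    dup = df.duplicated(["participant_id", "session_index"])
    if dup.any():
        raise SpecificationError(
            f"duplicate participant-session rows: "
            f"{df.loc[dup, ['participant_id', 'session_index']].to_dict('records')}"
        )
    out = df.copy()
    out["age_sq"] = out["age_years"] ** 2
    out["age_c"] = out["age_years"] - out["age_years"].mean()
    out["age_sq_c"] = out["age_sq"] - out["age_sq"].mean()
    return out


AGE_CONTROLS = ["age_c", "age_sq_c"]
PRIMARY_PREDICTORS = ["dir_spiralA", "dir_zigzagA"]


def _offset_columns(table: pd.DataFrame) -> list[str]:
    return sorted(
        c for c in table.columns if c.startswith("dir_") or c.startswith("spa_")
    )


def run_paper_analysis(
    cohort: pd.DataFrame,
    response: str = "external_score",
    n_boot: int = 0,
    seed: int = 0,
) -> dict:
    """Run the full concurrent-validity analysis on a scored cohort.

    Returns a nested, JSON-serializable report:

    * ``rq1_initial`` — OLS on each participant's first session, score
      predicted from the spiralA and zigzagA directional offsets:
      R2, per-term F, part R2 over age controls, r / r_adj / d, MAE.
    * ``rq1_repeated`` — random-intercept LMM on all sessions with the
      same predictors: Satterthwaite F tests, marginal / conditional
      R2, part R2 of the offsets vs the age controls, participant-
      weighted MAE.
    * ``rq2`` — per trajectory and per metric, the LMM of the score on
      that single offset plus age controls; marginal and conditional
      part R2 of the offset.
    * ``rq3`` — per trajectory and per metric, the LMM of the offset on
      age + age squared; marginal / conditional R2 and per-term F.

    Raw p-values are reported without multiple-testing correction
    across the per-trajectory scans.
    """
    table = cohort_table(cohort)
    report: dict = {"n_rows": int(len(table))}

    # ---- RQ1, initial testing: one session per participant, OLS
    first = (
        table.dropna(subset=PRIMARY_PREDICTORS + [response])
        .sort_values("session_index")
        .groupby("participant_id", as_index=False)
        .first()
    )
    ols = fit_ols_prediction(first, PRIMARY_PREDICTORS, response)
    r = float(np.sqrt(ols.r_squared))
    rq1_init = {
        "n": ols.n_obs,
        "coefficients": ols.coefficients,
        "f_tests": ols.f_tests,
        "r_squared": ols.r_squared,
        "r": r,
        "r_adj": adjusted_r(r, ols.n_obs, len(PRIMARY_PREDICTORS)),
        "d": effect_size_d(min(r, 1 - 1e-12)),
        "mae": float(np.mean(np.abs(ols.residuals))),
        "part_r2_directional_over_age": part_r2_ols(
            first, PRIMARY_PREDICTORS, AGE_CONTROLS, response
        ),
        "predictions": pd.DataFrame(
            {
                "participant_id": first["participant_id"].to_numpy(),
                "actual": first[response].to_numpy(),
                "predicted": ols.fitted,
            }
        ).to_dict("records"),
    }
    report["rq1_initial"] = rq1_init

    # ---- RQ1, repeated testing: LMM on all sessions
    lmm = fit_lmm(table, PRIMARY_PREDICTORS, response)
    r_m = float(np.sqrt(max(lmm.marginal_r2, 0.0)))
    ids = table.dropna(subset=PRIMARY_PREDICTORS + [response])["participant_id"]
    pp_mae = per_participant_mae(lmm.fitted, lmm.extras["y"], ids.to_numpy())
    part_dir = part_r2_lmm(
        table, PRIMARY_PREDICTORS, AGE_CONTROLS, response, n_boot=n_boot, seed=seed
    )
    part_age = part_r2_lmm(
        table, AGE_CONTROLS, PRIMARY_PREDICTORS, response,
        n_boot=n_boot, seed=seed + 1,
    )
    report["rq1_repeated"] = {
        "n": lmm.n_obs,
        "n_participants": lmm.n_participants,
        "coefficients": lmm.coefficients,
        "f_tests": lmm.f_tests,
        "df_method": lmm.df_method,
        "marginal_r2": lmm.marginal_r2,
        "conditional_r2": lmm.conditional_r2,
        "sigma_u": lmm.sigma_u,
        "sigma_e": lmm.sigma_e,
        "r_from_marginal": r_m,
        "r_adj": adjusted_r(r_m, lmm.n_obs, len(PRIMARY_PREDICTORS)),
        "d": effect_size_d(min(r_m, 1 - 1e-12)),
        "d_conditional": effect_size_d(
            min(float(np.sqrt(max(lmm.conditional_r2, 0.0))), 1 - 1e-12)
        ),
        "weighted_mae": float(pp_mae.mean()),
        "mae_range": (float(pp_mae.min()), float(pp_mae.max())),
        "part_r2_directional_over_age": {
            "marginal": part_dir["part_r2_marginal"],
            "conditional": part_dir["part_r2_conditional"],
        },
        "part_r2_age_over_directional": {
            "marginal": part_age["part_r2_marginal"],
            "conditional": part_age["part_r2_conditional"],
        },
    }

    # ---- RQ2: score ~ single offset + age controls, per trajectory/metric
    rq2: dict[str, dict] = {}
    for col in _offset_columns(table):
        if table[col].notna().sum() < 6:
            continue
        try:
            part = part_r2_lmm(table, [col], AGE_CONTROLS, response, n_boot=0)
        except (SpecificationError, ConvergenceError, np.linalg.LinAlgError):
            continue
        full = part["full"]
        rq2[col] = {
            "part_r2_marginal": part["part_r2_marginal"],
            "part_r2_conditional": part["part_r2_conditional"],
            "f_test": full.f_tests[col],
        }
    report["rq2"] = rq2

    # ---- RQ3: offset ~ age + age^2, per trajectory/metric
    rq3: dict[str, dict] = {}
    for col in _offset_columns(table):
        if table[col].notna().sum() < 6:
            continue
        try:
            m = fit_lmm(table, AGE_CONTROLS, response=col)
        except (SpecificationError, ConvergenceError, np.linalg.LinAlgError):
            continue
        rq3[col] = {
            "marginal_r2": m.marginal_r2,
            "conditional_r2": m.conditional_r2,
            "f_tests": m.f_tests,
        }
    report["rq3"] = rq3
    return report
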