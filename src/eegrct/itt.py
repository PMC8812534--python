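"""Intent-to-treat estimation with site fixed effects and robust SEs.

The estimand is the effect of randomized assignment (high vs. low cash
gift) on a per-child EEG outcome, from OLS of the outcome on a treatment
indicator plus site indicators — optionally plus the baseline covariate
list (maternal demographics, health scales, household composition, child
birth characteristics) and the visit controls (child age at interview,
usable epoch count).  Standard errors are heteroskedasticity-consistent
(HC1 by default); the standardized effect size divides the covariate-
adjusted coefficient by the outcome SD within the low-cash analytic sample.

Missing baseline covariates are mean-imputed from the analytic sample
(categoricals get an explicit ``missing`` level); outcomes are never
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import BASELINE_COVARIATES, RACE_LEVELS

NUMERIC_COVARIATES: tuple[str, ...] = (
    "mother_age",
    "mother_educ",
    "hh_income",
    "net_worth",
    "general_health",
    "mental_health",
    "n_adults",
    "n_other_children",
    "birth_weight_g",
    "gestational_age_wk",
)
BINARY_COVARIATES: tuple[str, ...] = (
    "married",
    "smoked_pregnancy",
    "alcohol_pregnancy",
    "father_in_home",
    "child_female",
)
CATEGORICAL_COVARIATES: tuple[str, ...] = ("race_ethnicity",)
#: Measured at the age-1 visit; included as controls alongside baseline list.
VISIT_CONTROLS: tuple[str, ...] = ("child_age_months", "n_usable_epochs")

#: Reference level dropped when one-hot encoding race/ethnicity.
RACE_REFERENCE: str = RACE_LEVELS[0]


@dataclass
class ITTEstimate:
    """Treatment-effect summary for one outcome (mirrors one table row)."""

    outcome: str
    coef_unadjusted: float
    se_unadjusted: float
    coef_adjusted: float
    se_adjusted: float
    p_unadjusted: float
    effect_size: float
    sd_low: float
    n: int
    p_wy: float | None = None


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_covariates(cohort: pd.DataFrame, analytic_ids: np.ndarray | pd.Series) -> pd.DataFrame:
    """Mean-impute missing baseline covariates using the analytic sample.

    Numeric covariates get the analytic-sample mean (not the full-cohort
    mean — the two differ whenever attrition is covariate-dependent);
    categoricals get an explicit ``"missing"`` level.  Returns a copy of the
    full cohort with the imputed values.
    """
    analytic_ids = np.asarray(analytic_ids)
    if not np.isin(analytic_ids, cohort["id"].to_numpy()).all():
        raise ValueError("analytic_ids must be a subset of cohort ids")
    out = cohort.copy()
    analytic = out[out["id"].isin(analytic_ids)]
    for col in BASELINE_COVARIATES:
        if col not in out.columns:
            continue
        if col in CATEGORICAL_COVARIATES:
            if out[col].isna().any():
                out[col] = out[col].astype(object).where(out[col].notna(), "missing")
            continue
        vals = analytic[col]
        if vals.isna().all():
            raise ValueError(f"covariate {col!r} entirely missing in analytic sample")
        out[col] = out[col].fillna(float(vals.mean()))
    return out


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def design_matrix(analytic: pd.DataFrame, covariates: bool) -> tuple[pd.DataFrame, np.ndarray]:
    """Return ``(X0, treat)``: controls (with intercept and site dummies)
    and the 0/1 treatment indicator for the analytic rows.
    """
    n = len(analytic)
    treat = (analytic["arm"] == "high").to_numpy(float)
    cols: dict[str, np.ndarray] = {"const": np.ones(n)}
    sites = sorted(analytic["site"].unique())
    for s in sites[1:]:
        cols[f"site_{s}"] = (analytic["site"] == s).to_numpy(float)
    if covariates:
        for c in NUMERIC_COVARIATES + BINARY_COVARIATES + VISIT_CONTROLS:
            cols[c] = analytic[c].to_numpy(float)
        for c in CATEGORICAL_COVARIATES:
            levels = [lv for lv in pd.unique(analytic[c]) if lv != RACE_REFERENCE]
            for lv in sorted(map(str, levels)):
                cols[f"{c}_{lv}"] = (analytic[c].astype(str) == lv).to_numpy(float)
    X0 = pd.DataFrame(cols, index=analytic.index)
    # degenerate covariates (no variation in this sample) carry no
    # information and would be collinear with the intercept — drop them
    keep = ["const"] + [c for c in X0.columns[1:] if X0[c].nunique() > 1]
    X0 = X0[keep]
    _check_full_rank(pd.concat([X0, pd.Series(treat, index=analytic.index, name="treat")], axis=1))
    return X0, treat


def _check_full_rank(X: pd.DataFrame) -> None:
    from scipy.linalg import qr

    M = X.to_numpy(float)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # pivoted QR localizes the dependent columns
        _, _, piv = qr(M, pivoting=True)
        bad = [X.columns[p] for p in piv[rank:]]
        raise ValueError(f"design matrix is collinear; offending columns: {bad}")


# ---------------------------------------------------------------------------
# Fast treatment statistics (Frisch–Waugh–Lovell + sandwich)
# ---------------------------------------------------------------------------

def treatment_stats(
    y: np.ndarray, treat: np.ndarray, X0: np.ndarray, hc: str = "HC1"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Treatment coefficient, robust SE and t for one or many treatment columns.

    ``treat`` may be ``(n,)`` or ``(n, B)`` — e.g. B permuted assignments.
    Residualizing both ``y`` and the treatment column(s) on the controls
    gives the same coefficient as the full regression, and the (treat,
    treat) element of the HC sandwich equals
    ``sum(ttilde_i^2 e_i^2) / (ttilde' ttilde)^2`` with full-model
    residuals ``e`` — so the whole permutation batch reduces to matrix
    products.
    """
    T = np.atleast_2d(treat.T).T.astype(float)  # (n, B)
    n, p0 = X0.shape
    p = p0 + 1
    Q, _ = np.linalg.qr(X0)
    y_t = y - Q @ (Q.T @ y)
    T_t = T - Q @ (Q.T @ T)
    tt = np.einsum("ib,ib->b", T_t, T_t)
    if np.any(tt <= 1e-12):
        raise ValueError("treatment indicator is collinear with the controls")
    coef = (T_t * y_t[:, None]).sum(axis=0) / tt
    resid = y_t[:, None] - T_t * coef[None, :]
    meat = np.einsum("ib,ib->b", T_t**2, resid**2)
    if hc == "HC0":
        factor = 1.0
    elif hc == "HC1":
        factor = n / (n - p)
    else:
        raise ValueError("hc must be 'HC0' or 'HC1' on the fast path")
    se = np.sqrt(factor * meat) / tt
    t = coef / se
    if np.ndim(treat) == 1:
        return coef[0], se[0], t[0]
    return coef, se, t


# ---------------------------------------------------------------------------
# ITT fit
# ---------------------------------------------------------------------------

def fit_itt(
    outcome: pd.Series | np.ndarray,
    analytic: pd.DataFrame,
    covariates: bool = True,
    hc: str = "HC1",
    use_t: bool = False,
    outcome_name: str | None = None,
) -> ITTEstimate:
    """Fit the ITT regressions for one outcome on the analytic sample.

    Runs the site-fixed-effects-only model and (when ``covariates``) the
    fully adjusted model; the reported p-value and effect size belong to the
    adjusted model (or the FE-only model when covariates are off).  p comes
    from the normal approximation to the robust t by default; ``use_t``
    switches to the t distribution with residual df.
    """
    y = np.asarray(outcome, float)
    if np.isnan(y).any():
        raise ValueError("outcome contains missing values; outcomes are never imputed")
    name = outcome_name or (outcome.name if isinstance(outcome, pd.Series) else "outcome")

    def _one(with_cov: bool) -> tuple[float, float, float]:
        X0, treat = design_matrix(analytic, with_cov)
        X = pd.concat([pd.Series(treat, index=X0.index, name="treat"), X0], axis=1)
        res = sm.OLS(y, X.to_numpy(float)).fit(cov_type=hc, use_t=use_t)
        return float(res.params[0]), float(res.bse[0]), float(res.pvalues[0])

    coef_u, se_u, p_u = _one(False)
    if covariates:
        coef_a, se_a, p_a = _one(True)
    else:
        coef_a, se_a, p_a = coef_u, se_u, p_u

    low = y[(analytic["arm"] == "low").to_numpy()]
    sd_low = float(np.std(low, ddof=1))
    # degenerate outcome with no low-arm variation (e.g. the assignment
    # indicator itself): coef/SE are still meaningful, the standardized
    # effect is not — reported as NaN rather than an error
    es = effect_size(coef_a, sd_low) if sd_low > 0 else float("nan")
    return ITTEstimate(
        outcome=name,
        coef_unadjusted=coef_u,
        se_unadjusted=se_u,
        coef_adjusted=coef_a,
        se_adjusted=se_a,
        p_unadjusted=p_a,
        effect_size=es,
        sd_low=sd_low,
        n=len(y),
    )


def effect_size(coef_adjusted: float, sd_low: float) -> float:
    """Standardized effect: adjusted coefficient over the low-arm outcome SD."""
    if not sd_low > 0:
        raise ValueError("sd_low must be positive")
    return coef_adjusted / sd_low


# ---------------------------------------------------------------------------
# Balance table
# ---------------------------------------------------------------------------

#: (column, label, kind) rows of the default balance table.
BALANCE_VARIABLES: tuple[tuple[str, str, str], ...] = (
    ("child_female", "Child is female (%)", "binary"),
    ("child_age_months", "Child age at visit (mo)", "continuous"),
    ("mother_educ", "Mother education (y)", "continuous"),
    ("hh_income", "Household combined income at baseline ($)", "continuous"),
    ("n_usable_epochs", "Number of artifact-free EEG epochs", "continuous"),
)


def balance_table(
    cohort: pd.DataFrame,
    analytic_ids: np.ndarray | pd.Series,
    variables: tuple[tuple[str, str, str], ...] = BALANCE_VARIABLES,
    include_race: bool = True,
) -> pd.DataFrame:
    """Per-arm descriptives with unadjusted group-difference p-values.

    Continuous variables: mean (SD) per arm and a two-sided Welch t-test.
    Binary variables (and each race/ethnicity level): percentage per arm and
    a two-proportion z-test.  Missing values are dropped per variable (the
    per-arm ``n`` columns report what remained).
    """
    analytic = cohort[cohort["id"].isin(np.asarray(analytic_ids))]
    rows = []

    def _binary_row(label: str, x: pd.Series) -> dict:
        lo = x[analytic["arm"] == "low"].dropna()
        hi = x[analytic["arm"] == "high"].dropna()
        c = np.array([hi.sum(), lo.sum()], float)
        nobs = np.array([len(hi), len(lo)], float)
        p = two_proportion_z(c[0], nobs[0], c[1], nobs[1])
        return {
            "variable": label,
            "low_mean": 100 * lo.mean(),
            "low_sd": np.nan,
            "low_n": len(lo),
            "high_mean": 100 * hi.mean(),
            "high_sd": np.nan,
            "high_n": len(hi),
            "p_value": p,
        }

    for col, label, kind in variables:
        x = analytic[col]
        if kind == "binary":
            rows.append(_binary_row(label, x.astype(float)))
        else:
            lo = x[analytic["arm"] == "low"].dropna()
            hi = x[analytic["arm"] == "high"].dropna()
            _, p = stats.ttest_ind(hi, lo, equal_var=False)
            rows.append(
                {
                    "variable": label,
                    "low_mean": lo.mean(),
                    "low_sd": lo.std(ddof=1),
                    "low_n": len(lo),
                    "high_mean": hi.mean(),
                    "high_sd": hi.std(ddof=1),
                    "high_n": len(hi),
                    "p_value": float(p),
                }
            )
    if include_race and "race_ethnicity" in analytic.columns:
        for level in RACE_LEVELS:
            ind = (analytic["race_ethnicity"] == level).astype(float)
            ind[analytic["race_ethnicity"].isna()] = np.nan
            rows.append(_binary_row(f"Race/ethnicity: {level}", ind))
    return pd.DataFrame(rows)


def two_proportion_z(x1: float, n1: float, x2: float, n2: float) -> float:
    """Two-sided pooled two-proportion z-test p-value.

    Identical proportions give z = 0, p = 1; degenerate pooled proportions
    (0 or 1) give p = 1.
    """
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 1.0
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return float(2 * stats.norm.sf(abs(z)))
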