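"""Covariate-adjusted association surfaces.

Linear models relate z-scored lipid exposures (class totals, species, or
ratios) to z-scored continuous biomarkers; binary logistic models relate
them to MetS and its components. Both adjust for sex, age, race, and
education (linear models optionally also for MetS diagnosis). Coefficients
are per 1 SD of the exposure; logistic effects are reported as odds ratios
with Wald 95% confidence intervals. Matrices are significance-masked at
p < 0.05, matching the regression-coefficient heat-map convention.

Reference levels for the dummy coding: sex 'female', race 'White',
education 'high school or less'. Age enters linearly in years by default;
a 3-bin categorical version (<50, 50-65, >65) is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

REFERENCE_LEVELS = {"sex": "female", "race": "White", "education": "high school or less"}
DEFAULT_COVARIATES = ("sex", "age", "race", "education")

AGE_BINS = (-np.inf, 50.0, 65.0, np.inf)
AGE_LABELS = ("<50", "50-65", ">65")


class RankDeficientError(ValueError):
    """Design matrix is rank deficient (collinear columns)."""


class SeparationError(RuntimeError):
    """Logistic maximum likelihood failed to converge (e.g. perfect separation)."""


@dataclass(frozen=True)
class AssociationCell:
    exposure_id: str
    outcome_id: str
    beta: float
    se: float
    p_value: float
    or_point: float | None  # exp(beta), logistic only
    ci95: tuple[float, float] | None
    n: int
    adjusted_for: tuple[str, ...]
    model: str  # "linear" | "logistic"

    @property
    def masked_beta(self) -> float:
        """Coefficient for display matrices: zeroed when p >= 0.05."""
        return self.beta if self.p_value < 0.05 else 0.0


def build_design(
    data: pd.DataFrame,
    exposure: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    categorical_age: bool = False,
) -> pd.DataFrame:
    """Dummy-coded design matrix (constant + exposure + covariates).

    Categorical covariates are coded against the stated reference level;
    rows with any missing value are dropped (complete-case analysis).
    """
    cols = {"const": 1.0, exposure: data[exposure]}
    for cov in covariates:
        if cov == "age" and not categorical_age:
            cols["age"] = data["age"]
        elif cov == "age":
            binned = pd.cut(data["age"], AGE_BINS, labels=AGE_LABELS)
            for lvl in AGE_LABELS[1:]:
                cols[f"age[{lvl}]"] = (binned == lvl).astype(float)
        elif cov in REFERENCE_LEVELS:
            levels = [l for l in pd.unique(data[cov].dropna()) if l != REFERENCE_LEVELS[cov]]
            for lvl in sorted(map(str, levels)):
                cols[f"{cov}[{lvl}]"] = (data[cov].astype(str) == lvl).astype(float)
        else:
            cols[cov] = pd.to_numeric(data[cov])
    X = pd.DataFrame(cols, index=data.index).dropna()
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for c in X.columns[1:]:
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank:
                bad.append(c)
        raise RankDeficientError(f"collinear design columns: {bad or list(X.columns)}")
    return X


def fit_linear(
    outcome: pd.Series,
    exposure: pd.Series,
    covariate_data: pd.DataFrame | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    categorical_age: bool = False,
) -> AssociationCell:
    """OLS coefficient of the exposure on the outcome, covariate-adjusted."""
    exposure = exposure.rename(exposure.name or "exposure")
    data = pd.DataFrame({exposure.name: exposure})
    if covariate_data is not None:
        data = data.join(covariate_data)
    else:
        covariates = ()
    X = build_design(data, exposure.name, covariates, categorical_age)
    y = pd.Series(outcome).reindex(X.index)
    ok = y.notna()
    X, y = X[ok], y[ok]
    if len(y) <= X.shape[1]:
        raise ValueError("fewer observations than parameters")
    fit = sm.OLS(y, X).fit()
    return AssociationCell(
        exposure_id=str(exposure.name),
        outcome_id=str(outcome.name or "outcome"),
        beta=float(fit.params[exposure.name]),
        se=float(fit.bse[exposure.name]),
        p_value=float(fit.pvalues[exposure.name]),
        or_point=None,
        ci95=None,
        n=int(fit.nobs),
        adjusted_for=tuple(covariates),
        model="linear",
    )


def fit_logistic(
    outcome: pd.Series,
    exposure: pd.Series,
    covariate_data: pd.DataFrame | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    categorical_age: bool = False,
) -> AssociationCell:
    """Binary logistic regression; per-1-SD odds ratio with Wald 95% CI.

    Fit by iteratively reweighted least squares (tolerance 1e-8, at most
    100 iterations); non-convergence — e.g. under perfect separation —
    raises :class:`SeparationError`.
    """
    exposure = exposure.rename(exposure.name or "exposure")
    data = pd.DataFrame({exposure.name: exposure})
    if covariate_data is not None:
        data = data.join(covariate_data)
    else:
        covariates = ()
    X = build_design(data, exposure.name, covariates, categorical_age)
    y = pd.Series(outcome).reindex(X.index).astype(float)
    ok = y.notna()
    X, y = X[ok], y[ok]
    if y.nunique() < 2:
        raise ValueError("outcome must have both levels present")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        fit = model.fit(maxiter=100, tol=1e-8)
    if not fit.converged or not np.isfinite(fit.bse[exposure.name]) or fit.bse[exposure.name] > 1e4:
        raise SeparationError(
            f"logistic fit for exposure {exposure.name!r} did not converge "
            "(possible perfect separation)"
        )
    beta = float(fit.params[exposure.name])
    se = float(fit.bse[exposure.name])
    return AssociationCell(
        exposure_id=str(exposure.name),
        outcome_id=str(outcome.name or "outcome"),
        beta=beta,
        se=se,
        p_value=float(fit.pvalues[exposure.name]),
        or_point=float(np.exp(beta)),
        ci95=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        n=int(fit.nobs),
        adjusted_for=tuple(covariates),
        model="logistic",
    )


def association_matrix(
    exposures: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariate_data: pd.DataFrame | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    model: str = "linear",
    categorical_age: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure x outcome association surface.

    Returns (long table with one row per cell, significance-masked beta
    matrix with exposures as rows). Cells with p >= 0.05 are masked to 0 in
    the matrix, mirroring the colored-coefficient heat maps.
    """
    fit = {"linear": fit_linear, "logistic": fit_logistic}.get(model)
    if fit is None:
        raise ValueError("model must be 'linear' or 'logistic'")
    cells = []
    for exp_id in exposures.columns:
        for out_id in outcomes.columns:
            cells.append(
                fit(outcomes[out_id], exposures[exp_id], covariate_data, covariates, categorical_age)
            )
    long = pd.DataFrame(
        [
            {
                "exposure": c.exposure_id,
                "outcome": c.outcome_id,
                "beta": c.beta,
                "se": c.se,
                "p_value": c.p_value,
                "odds_ratio": c.or_point,
                "ci_low": c.ci95[0] if c.ci95 else None,
                "ci_high": c.ci95[1] if c.ci95 else None,
                "n": c.n,
            }
            for c in cells
        ]
    )
    masked = long.assign(masked=[c.masked_beta for c in cells]).pivot(
        index="exposure", columns="outcome", values="masked"
    ).reindex(index=exposures.columns, columns=outcomes.columns)
    return long, masked


def zscore(values: pd.Series | pd.DataFrame):
    """Standardize to mean 0, SD 1 over non-missing entries (sample SD)."""
    return (values - values.mean()) / values.std(ddof=1)
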