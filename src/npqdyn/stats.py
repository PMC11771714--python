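"""Genotype-by-environment ANOVA, stepwise-AIC environmental models, and
between-year genotype-mean correlations for the kinetic parameter tables."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.base import BaseEstimator

__all__ = [
    "anova_gxe",
    "StepwiseAICSelector",
    "stepwise_env_model",
    "genotype_mean_correlations",
]


def anova_gxe(
    pheno: pd.DataFrame, parameter: str, day_col: str = "date", genotype_col: str = "genotype"
) -> pd.DataFrame:
    """Sequential (type-I) ANOVA of ``parameter ~ Day + Genotype + Day:Genotype``.

    Expects plot-level (replicate-averaged) rows.  Returns a table with F
    statistics and p-values for the day (environment), genotype and
    interaction terms; an inestimable interaction (empty cells) yields NaN
    with a warning.
    """
    for col, label in ((day_col, "day"), (genotype_col, "genotype")):
        if pheno[col].nunique() < 2:
            raise ValueError(f"need >= 2 {label} levels")
    formula = f"Q('{parameter}') ~ C(Q('{day_col}')) + C(Q('{genotype_col}')) + C(Q('{day_col}')):C(Q('{genotype_col}'))"
    fit = smf.ols(formula, data=pheno).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(fit, typ=1)
    out = table.iloc[:-1][["df", "F", "PR(>F)"]].copy()
    out.index = ["day", "genotype", "day:genotype"][: len(out)]
    out.columns = ["df", "F", "p"]
    if out[["F", "p"]].isna().any().any():
        warnings.warn("interaction inestimable (empty cells); reported as NaN", stacklevel=2)
    return out


def _ols_aic(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Gaussian-likelihood AIC of an OLS fit (matches statsmodels' OLS aic)."""
    n = y.size
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        rss = np.finfo(float).tiny
    llf = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    return -2 * llf + 2 * (X.shape[1] + 1), beta


class StepwiseAICSelector(BaseEstimator):
    """Both-direction stepwise covariate selection by AIC over OLS models.

    Starting from the full model (all covariates), each step evaluates every
    single-covariate removal and re-inclusion and applies the change that
    most lowers the AIC, stopping at a local minimum.  Ties (|dAIC| below
    ``tie_tol``) resolve in favor of the smaller model.  Covariates are
    centered and scaled internally, so coefficients are standardized.

    Attributes after ``fit``: ``selected_`` (covariate names), ``coef_``
    (standardized coefficients, pandas Series incl. intercept), ``aic_``,
    ``r2_``, ``aic_null_`` (intercept-only AIC).
    """

    def __init__(self, start: str = "full", tie_tol: float = 1e-6, max_condition: float = 1e8):
        self.start = start
        self.tie_tol = tie_tol
        self.max_condition = max_condition

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float).ravel()
        names = list(X.columns)
        Z = X.to_numpy(dtype=float)
        mu, sd = Z.mean(axis=0), Z.std(axis=0, ddof=0)
        if np.any(sd == 0):
            dead = [n for n, s in zip(names, sd) if s == 0]
            raise ValueError(f"constant covariates cannot be scaled: {dead}")
        Z = (Z - mu) / sd
        cond = np.linalg.cond(Z)
        if cond > self.max_condition:
            raise ValueError(
                f"covariate condition number {cond:.2e} > {self.max_condition:.0e}; remove collinear covariates"
            )
        n = y.size

        def design(sel):
            cols = [names.index(s) for s in sel]
            return np.column_stack([np.ones(n), Z[:, cols]]) if cols else np.ones((n, 1))

        current = list(names) if self.start == "full" else []
        aic, _ = _ols_aic(design(current), y)
        improved = True
        while improved:
            improved = False
            candidates = []  # (aic, size, selection)
            for s in current:
                sel = [c for c in current if c != s]
                a, _ = _ols_aic(design(sel), y)
                candidates.append((a, len(sel), sel))
            for s in names:
                if s not in current:
                    sel = current + [s]
                    a, _ = _ols_aic(design(sel), y)
                    candidates.append((a, len(sel), sel))
            if not candidates:
                break
            # prefer lower AIC; within tie tolerance, the smaller model
            best = min(candidates, key=lambda c: (c[0], c[1]))
            if best[0] < aic - self.tie_tol or (abs(best[0] - aic) <= self.tie_tol and best[1] < len(current)):
                aic, current = best[0], best[2]
                improved = True

        Xd = design(current)
        aic, beta = _ols_aic(Xd, y)
        resid = y - Xd @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        self.selected_ = list(current)
        self.coef_ = pd.Series(beta, index=["intercept", *current])
        self.aic_ = float(aic)
        self.aic_null_, _ = _ols_aic(np.ones((n, 1)), y)
        self.r2_ = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
        return self


def stepwise_env_model(pheno: pd.DataFrame, parameter: str, covariates) -> StepwiseAICSelector:
    """Select the minimum-adequate environmental model for one parameter.

    ``covariates`` are column names of per-day environmental features joined
    onto the phenotype rows; rows with missing covariates are dropped.
    """
    cols = list(covariates)
    data = pheno[[parameter, *cols]].dropna()
    return StepwiseAICSelector().fit(data[cols], data[parameter])


def genotype_mean_correlations(table_a: pd.DataFrame, table_b: pd.DataFrame, parameters=None) -> pd.DataFrame:
    """Pearson correlation of per-genotype means between two tables.

    Both tables are indexed by genotype (e.g. one per year, or one a trait
    table such as yield estimates).  Returns r, R^2 and the two-sided p per
    shared numeric parameter, computed over shared genotypes.
    """
    shared = table_a.index.intersection(table_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genotypes; need >= 3")
    if parameters is None:
        parameters = [c for c in table_a.columns if c in table_b.columns]
    rows = []
    for p in parameters:
        r, pval = sps.pearsonr(table_a.loc[shared, p], table_b.loc[shared, p])
        rows.append({"parameter": p, "r": r, "r2": r * r, "p": pval, "n": len(shared)})
    return pd.DataFrame(rows).set_index("parameter")
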