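"""Canonical correlation of kinetic parameters against environmental
covariates, with Wilks' Lambda significance, and per-day principal component
analysis with group tests and outlier labeling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

__all__ = ["CanonicalCorrelation", "run_cca", "wilks_lambda", "pca_by_day", "DayPCAResult"]


def _standardize(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (M - M.mean(axis=0)) / sd


class CanonicalCorrelation(BaseEstimator):
    """Canonical correlation analysis via QR + SVD.

    Finds pairs of linear combinations (one per block) with maximal
    correlation; successive pairs are uncorrelated with earlier ones.
    Blocks are centered and scaled internally.  Rank-deficient directions
    (singular values of a block below ``rcond`` times the largest) are
    dropped with a warning.

    Attributes after ``fit``: ``correlations_`` (non-increasing, in [0, 1]),
    ``x_weights_``/``y_weights_`` (coefficients on standardized variables),
    ``x_loadings_``/``y_loadings_`` (correlations of the original variables
    with their own canonical variates), ``wilks_`` (per-axis Wilks' Lambda
    table with Rao's F approximation).
    """

    def __init__(self, n_components: int | None = None, rcond: float = 1e-10):
        self.n_components = n_components
        self.rcond = rcond

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        n, p = X.shape
        q = Y.shape[1]
        if Y.shape[0] != n:
            raise ValueError("X and Y must have the same number of rows")
        if n <= p + q:
            raise ValueError(f"need n > p + q (got n={n}, p={p}, q={q})")
        Xs, Ys = _standardize(X), _standardize(Y)

        def thin_qr(M):
            Q, R, piv = _pivoted_qr(M)
            diag = np.abs(np.diag(R))
            rank = int((diag > self.rcond * diag.max()).sum()) if diag.size else 0
            if rank < M.shape[1]:
                warnings.warn(f"block rank {rank} < {M.shape[1]}; dropping deficient dimensions", stacklevel=3)
            return Q[:, :rank], R[:rank], piv

        Qx, Rx, px = thin_qr(Xs)
        Qy, Ry, py = thin_qr(Ys)
        U, s, Vt = np.linalg.svd(Qx.T @ Qy)
        k = min(len(s), self.n_components or len(s))
        s = np.clip(s[:k], 0.0, 1.0)

        # back-solve weights on the standardized (pivot-ordered) variables
        wx = np.zeros((p, k))
        wx_p = np.linalg.solve(Rx[:, : Rx.shape[0]], U[:, :k]) if Rx.shape[0] else np.zeros((0, k))
        wx[px[: Rx.shape[0]]] = wx_p
        wy = np.zeros((q, k))
        wy_p = np.linalg.solve(Ry[:, : Ry.shape[0]], Vt.T[:, :k]) if Ry.shape[0] else np.zeros((0, k))
        wy[py[: Ry.shape[0]]] = wy_p

        self.n_, self.p_, self.q_ = n, p, q
        self.correlations_ = s
        self.x_weights_, self.y_weights_ = wx, wy
        self._x_mean, self._x_sd = X.mean(axis=0), np.where(X.std(axis=0, ddof=1) == 0, 1, X.std(axis=0, ddof=1))
        self._y_mean, self._y_sd = Y.mean(axis=0), np.where(Y.std(axis=0, ddof=1) == 0, 1, Y.std(axis=0, ddof=1))
        Uv, Vv = self.transform(X, Y)
        self.x_loadings_ = _corr_columns(Xs, Uv)
        self.y_loadings_ = _corr_columns(Ys, Vv)
        self.wilks_ = wilks_lambda(s, n, Rx.shape[0], Ry.shape[0])
        return self

    def transform(self, X, Y):
        X = (np.asarray(X, dtype=float) - self._x_mean) / self._x_sd
        Y = (np.asarray(Y, dtype=float) - self._y_mean) / self._y_sd
        return X @ self.x_weights_, Y @ self.y_weights_


def _pivoted_qr(M):
    from scipy.linalg import qr

    Q, R, piv = qr(M, mode="economic", pivoting=True)
    return Q, R, piv


def _corr_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    out = np.empty((A.shape[1], B.shape[1]))
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            sa, sb = A[:, i].std(), B[:, j].std()
            out[i, j] = 0.0 if sa == 0 or sb == 0 else np.corrcoef(A[:, i], B[:, j])[0, 1]
    return out


def wilks_lambda(correlations: np.ndarray, n: int, p: int, q: int) -> pd.DataFrame:
    """Wilks' Lambda and Rao's F approximation for each canonical axis.

    Axis k tests the null that canonical correlations k..end are all zero:
    Lambda_k = prod_{i>=k} (1 - r_i^2).
    """
    r2 = np.asarray(correlations, dtype=float) ** 2
    rows = []
    for k in range(len(r2)):
        lam = float(np.prod(1.0 - r2[k:]))
        pp, qq = p - k, q - k
        m = n - 1.5 - (pp + qq) / 2.0
        denom = pp * pp + qq * qq - 5
        s = np.sqrt((pp * pp * qq * qq - 4) / denom) if denom > 0 else 1.0
        df1 = pp * qq
        df2 = m * s - pp * qq / 2.0 + 1.0
        lam_s = lam ** (1.0 / s) if lam > 0 else 0.0
        with np.errstate(divide="ignore", over="ignore"):
            F = np.inf if lam_s == 0 else (1.0 - lam_s) / lam_s * df2 / df1
        pval = sps.f.sf(F, df1, df2) if df2 > 0 else np.nan
        rows.append({"axis": k + 1, "wilks_lambda": lam, "F": F, "df1": df1, "df2": df2, "p": pval})
    return pd.DataFrame(rows).set_index("axis")


@dataclass
class CCAResult:
    correlations: np.ndarray
    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame
    wilks: pd.DataFrame
    scores: pd.DataFrame
    centroids: pd.DataFrame | None
    estimator: CanonicalCorrelation


def run_cca(
    pheno: pd.DataFrame,
    pheno_cols,
    env_cols,
    exclude=("morning_Ta",),
    group_col: str | None = None,
    day_col: str | None = None,
    n_components: int | None = None,
) -> CCAResult:
    """CCA of the kinetic-parameter block against the environmental block.

    ``exclude`` removes covariates kept out to limit collinearity (morning
    air temperature by default).  When ``group_col``/``day_col`` are given,
    per-group-per-day centroids of the canonical scores are returned for
    ordination plots.
    """
    env_cols = [c for c in env_cols if c not in set(exclude)]
    data = pheno.dropna(subset=[*pheno_cols, *env_cols])
    est = CanonicalCorrelation(n_components=n_components).fit(data[list(pheno_cols)], data[env_cols])
    U, V = est.transform(data[list(pheno_cols)], data[env_cols])
    k = U.shape[1]
    scores = pd.DataFrame(
        {**{f"CC{i + 1}_x": U[:, i] for i in range(k)}, **{f"CC{i + 1}_y": V[:, i] for i in range(k)}},
        index=data.index,
    )
    centroids = None
    if group_col and day_col:
        joined = scores.join(data[[group_col, day_col]])
        centroids = joined.groupby([group_col, day_col], observed=True).mean().reset_index()
    return CCAResult(
        correlations=est.correlations_,
        x_loadings=pd.DataFrame(est.x_loadings_, index=list(pheno_cols)),
        y_loadings=pd.DataFrame(est.y_loadings_, index=env_cols),
        wilks=est.wilks_,
        scores=scores,
        centroids=centroids,
        estimator=est,
    )


@dataclass
class DayPCAResult:
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # variables x PCs
    scores: pd.DataFrame  # per input row
    genotype_means: pd.DataFrame
    outliers: pd.DataFrame  # genotype, PC, z
    group_anova_p: pd.Series  # one-way group p per PC


def pca_by_day(
    pheno: pd.DataFrame,
    day,
    parameter_cols,
    day_col: str = "date",
    genotype_col: str = "genotype",
    group_col: str | None = "group",
    n_components: int = 3,
    z_threshold: float = 2.5,
) -> DayPCAResult:
    """PCA of one sampling day's plot-level rows on centered/scaled parameters.

    Genotype-mean coordinates are z-scored per retained PC and genotypes with
    |z| > ``z_threshold`` on any PC are labeled as outliers.  When a group
    column is present, a one-way ANOVA of group on each PC coordinate is
    reported.
    """
    day_df = pheno[pheno[day_col] == day]
    if day_df[genotype_col].nunique() < 3:
        raise ValueError("need >= 3 genotypes on the day")
    X = day_df[list(parameter_cols)].to_numpy(dtype=float)
    k = min(n_components, X.shape[1], X.shape[0])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(_standardize(X))
    pc_cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(scores, columns=pc_cols, index=day_df.index)
    loadings = pd.DataFrame(pca.components_.T, index=list(parameter_cols), columns=pc_cols)

    means = scores.join(day_df[[genotype_col]]).groupby(genotype_col, observed=True).mean()
    z = (means - means.mean()) / means.std(ddof=0).replace(0.0, 1.0)
    flag = z.abs() > z_threshold
    outliers = (
        z[flag].stack().rename("z").reset_index().rename(columns={"level_1": "PC", genotype_col: "genotype"})
    )

    anova_p = pd.Series(np.nan, index=pc_cols)
    if group_col and group_col in day_df.columns and day_df[group_col].nunique() >= 2:
        joined = scores.join(day_df[[group_col]])
        for pc in pc_cols:
            fit = smf.ols(f"{pc} ~ C(Q('{group_col}'))", data=joined).fit()
            tbl = sm.stats.anova_lm(fit, typ=1)
            anova_p[pc] = tbl["PR(>F)"].iloc[0]
    return DayPCAResult(
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings,
        scores=scores,
        genotype_means=means,
        outliers=outliers,
        group_anova_p=anova_p,
    )
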