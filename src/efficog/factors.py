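"""Psychometric scoring: z-normalization, outlier screens, maximum-likelihood
exploratory factor analysis (EFA) with Horn-style parallel analysis, fit
indices, regression factor scores, and nuisance residualization.

The EFA is the classic profile-likelihood reduction for the normal-theory
factor model Sigma = Lambda Lambda' + Psi: the loadings are profiled out
analytically and the likelihood discrepancy is minimized over the
uniquenesses alone (the algorithm behind R's ``factanal``).  Fit is judged
by the Bartlett-corrected likelihood-ratio chi-square and the derived RMSR,
RMSEA and Tucker-Lewis indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FactorSolution",
    "zscore",
    "screen_outliers",
    "ml_efa",
    "parallel_analysis",
    "fit_indices",
    "factor_scores",
    "bootstrap_loading_ci",
    "residualize",
    "MLFactorAnalysis",
]

#: lower bound on uniquenesses; estimates at the bound are Heywood cases
PSI_FLOOR = 0.005


def zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, SD 1 with the n-1 denominator)."""
    sd = table.std(ddof=1)
    constant = sd[~(sd > 0)].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) cannot be z-scored: {constant}")
    return (table - table.mean()) / sd


def screen_outliers(
    table: pd.DataFrame, z_cut: float = 3.0, alpha: float = 0.001
) -> tuple[pd.Series, pd.Series]:
    """Univariate (|z| > 3) and multivariate (Mahalanobis) outlier flags.

    The multivariate cutoff is the chi-square quantile at ``1 - alpha`` with
    one degree of freedom per measure.  Flags are returned, nothing is
    deleted.
    """
    x = table.to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError("need more subjects than measures for a Mahalanobis screen")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    uni = pd.Series(np.any(np.abs(z) > z_cut, axis=1), index=table.index)
    cov = np.cov(x, rowvar=False)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular covariance matrix; drop collinear columns before screening"
        ) from err
    centred = x - x.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centred, cov_inv, centred)
    cutoff = stats.chi2.ppf(1 - alpha, df=p)
    multi = pd.Series(d2 > cutoff, index=table.index)
    return uni, multi


@dataclass
class FactorSolution:
    """Fitted factor model on a correlation matrix."""

    n_factors: int
    loadings: np.ndarray  # (p, k)
    uniquenesses: np.ndarray  # (p,)
    chi_square: float
    df: int
    p_value: float
    rmsr: float
    rmsea: float
    tli: float
    var_explained: float
    n_obs: int
    converged: bool
    heywood: np.ndarray  # boolean per measure
    eigenvalues_observed: np.ndarray | None = None
    eigenvalue_null: np.ndarray | None = None
    loading_ci: np.ndarray | None = None  # (p, k, 2) 5-95% bounds
    scores: np.ndarray | None = None
    gradient_norm: float = field(default=np.nan)


def _orient(loadings: np.ndarray) -> np.ndarray:
    """Flip factor signs so each factor's largest-magnitude loading is positive."""
    lam = loadings.copy()
    for k in range(lam.shape[1]):
        j = np.argmax(np.abs(lam[:, k]))
        if lam[j, k] < 0:
            lam[:, k] = -lam[:, k]
    return lam


def _profile_objective(psi: np.ndarray, corr: np.ndarray, k: int) -> float:
    sc = 1.0 / np.sqrt(psi)
    sstar = corr * np.outer(sc, sc)
    theta = np.linalg.eigvalsh(sstar)[::-1]
    tail = theta[k:]
    return float(np.sum(tail - np.log(tail)) - (corr.shape[0] - k))


def _loadings_from_psi(psi: np.ndarray, corr: np.ndarray, k: int) -> np.ndarray:
    sc = 1.0 / np.sqrt(psi)
    sstar = corr * np.outer(sc, sc)
    theta, vec = np.linalg.eigh(sstar)
    theta, vec = theta[::-1], vec[:, ::-1]
    lam = vec[:, :k] * np.sqrt(np.maximum(theta[:k] - 1.0, 0.0))
    return _orient(lam * np.sqrt(psi)[:, None])


def ml_efa(
    corr_matrix: np.ndarray,
    n_factors: int,
    n_obs: int,
    max_iter: int = 1000,
) -> FactorSolution:
    """Maximum-likelihood EFA of a correlation matrix.

    Uniquenesses start at ``1 - SMC`` (squared multiple correlations,
    ``1 / diag(R^-1)``) and are optimized by L-BFGS-B with a floor of
    0.005; estimates on the floor are flagged as Heywood cases.
    """
    corr = np.asarray(corr_matrix, dtype=float)
    p = corr.shape[0]
    if corr.ndim != 2 or corr.shape[1] != p:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if np.min(np.linalg.eigvalsh(corr)) < -1e-8:
        raise ValueError("correlation matrix must be positive semi-definite")
    if not 1 <= n_factors < p:
        raise ValueError(f"n_factors must be in [1, {p - 1}], got {n_factors}")

    corr = (corr + corr.T) / 2.0
    try:
        psi0 = 1.0 / np.diag(np.linalg.inv(corr))
    except np.linalg.LinAlgError:
        psi0 = np.full(p, 0.5)
    psi0 = np.clip(psi0, PSI_FLOOR, 1.0)

    res = optimize.minimize(
        _profile_objective,
        psi0,
        args=(corr, n_factors),
        method="L-BFGS-B",
        bounds=[(PSI_FLOOR, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    psi = np.asarray(res.x)
    lam = _loadings_from_psi(psi, corr, n_factors)
    heywood = psi <= PSI_FLOOR + 1e-12

    chi2, df, p_value = _lr_statistic(res.fun, p, n_factors, n_obs)
    resid = corr - (lam @ lam.T + np.diag(psi))
    if df > 0:
        rmsr, rmsea, tli = fit_indices(chi2, df, n_obs, resid, corr=corr)
    else:
        # just-identified model: RMSR is still defined, the LR-based indices are not
        off = resid[np.triu_indices(p, k=1)]
        rmsr, rmsea, tli = float(np.sqrt(np.mean(off**2))), np.nan, np.nan
    var_explained = float(np.mean(np.sum(lam**2, axis=1)))
    grad_norm = float(np.linalg.norm(res.jac)) if res.jac is not None else np.nan
    return FactorSolution(
        n_factors=n_factors,
        loadings=lam,
        uniquenesses=psi,
        chi_square=chi2,
        df=df,
        p_value=p_value,
        rmsr=rmsr,
        rmsea=rmsea,
        tli=tli,
        var_explained=var_explained,
        n_obs=n_obs,
        converged=bool(res.success),
        heywood=heywood,
        gradient_norm=grad_norm,
    )


def _lr_statistic(fmin: float, p: int, k: int, n_obs: int) -> tuple[float, int, float]:
    """Bartlett-corrected likelihood-ratio chi-square for the k-factor model."""
    df = ((p - k) ** 2 - (p + k)) // 2
    correction = n_obs - 1 - (2 * p + 5) / 6 - 2 * k / 3
    chi2 = max(correction, 0.0) * fmin
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    return float(chi2), int(df), p_value


def fit_indices(
    chi_square: float,
    df_model: int,
    n_obs: int,
    residual_matrix: np.ndarray,
    corr: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(RMSR, RMSEA, Tucker-Lewis) from the LR statistic and residuals.

    RMSR is the root mean square of the off-diagonal residual correlations;
    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))); TLI compares the fitted
    model's chi2/df ratio against the independence (null) model's.
    """
    if df_model <= 0:
        raise ValueError("fit indices are undefined for a saturated model (df <= 0)")
    resid = np.asarray(residual_matrix, dtype=float)
    p = resid.shape[0]
    off = resid[np.triu_indices(p, k=1)]
    rmsr = float(np.sqrt(np.mean(off**2)))
    rmsea = float(np.sqrt(max(chi_square - df_model, 0.0) / (df_model * (n_obs - 1))))
    if corr is None:
        tli = np.nan
    else:
        sign, logdet = np.linalg.slogdet(corr)
        null_chi2 = -(n_obs - 1 - (2 * p + 5) / 6) * logdet
        null_df = p * (p - 1) // 2
        null_ratio = null_chi2 / null_df
        tli = float((null_ratio - chi_square / df_model) / (null_ratio - 1.0))
    return rmsr, rmsea, tli


def parallel_analysis(
    data: pd.DataFrame | np.ndarray,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
    null_summary: str = "mean",
) -> int:
    """Horn-style parallel analysis on column-shuffled data.

    Each permutation independently shuffles every column's rows, destroying
    cross-column structure while preserving margins; eigenvalues come from
    the correlation matrix.  The retained count is the number of leading
    observed eigenvalues exceeding the null summary (``mean`` of the
    permutation distribution, or its ``p95`` percentile), stopping at the
    first eigenvalue that fails.
    """
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError("need more subjects than measures")
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    if null_summary not in ("mean", "p95"):
        raise ValueError("null_summary must be 'mean' or 'p95'")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    obs = np.linalg.eigvalsh(np.corrcoef(x, rowvar=False))[::-1]
    null = np.empty((n_permutations, p))
    shuffled = x.copy()
    for b in range(n_permutations):
        for j in range(p):
            rng.shuffle(shuffled[:, j])
        null[b] = np.linalg.eigvalsh(np.corrcoef(shuffled, rowvar=False))[::-1]
    ref = null.mean(axis=0) if null_summary == "mean" else np.percentile(null, 95, axis=0)
    retained = 0
    for lam_obs, lam_null in zip(obs, ref):
        if lam_obs > lam_null:
            retained += 1
        else:
            break
    return retained


def factor_scores(
    loadings: np.ndarray, corr: np.ndarray, z_data: np.ndarray, standardize: bool = True
) -> np.ndarray:
    """Thurstone regression-method factor scores: Z R^-1 Lambda, standardized."""
    try:
        weights = np.linalg.solve(corr, loadings)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular correlation matrix; cannot compute factor scores") from err
    scores = np.asarray(z_data, float) @ weights
    if standardize:
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        scores = (scores - scores.mean(axis=0)) / sd
    return scores


def bootstrap_loading_ci(
    data: pd.DataFrame | np.ndarray,
    n_factors: int,
    n_resamples: int = 10_000,
    seed: int | np.random.Generator = 0,
    quantiles: tuple[float, float] = (5.0, 95.0),
) -> np.ndarray:
    """Subject-resampling bootstrap 5-95% bounds per loading, shape (p, k, 2)."""
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    boots = np.empty((n_resamples, p, n_factors))
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        xb = x[idx]
        corr = np.corrcoef(xb, rowvar=False)
        boots[b] = ml_efa(corr, n_factors, n_obs=n).loadings
    lo = np.percentile(boots, quantiles[0], axis=0)
    hi = np.percentile(boots, quantiles[1], axis=0)
    return np.stack([lo, hi], axis=-1)


def residualize(
    scores: np.ndarray | pd.Series, age: np.ndarray, sex: np.ndarray, standardize: bool = True
) -> np.ndarray:
    """Remove linear age, quadratic age, and sex effects by OLS.

    Residuals are re-standardized so downstream path coefficients stay on
    the standardized scale.  Constant covariate columns (e.g. single-sex
    samples) are dropped with a warning rather than breaking the fit.
    """
    import warnings

    y = np.asarray(scores, dtype=float).ravel()
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if np.any(np.isnan(y)) or np.any(np.isnan(age)) or np.any(np.isnan(sex)):
        raise ValueError("missing values in scores or covariates")
    cols = [np.ones_like(y)]
    for name, col in (("age", age), ("age^2", age**2), ("sex", sex)):
        if np.ptp(col) == 0:
            warnings.warn(f"covariate '{name}' is constant and was dropped", stacklevel=2)
        else:
            cols.append(col)
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    if standardize:
        sd = resid.std(ddof=1)
        if sd > 0:
            resid = (resid - resid.mean()) / sd
    return resid


class MLFactorAnalysis(BaseEstimator, TransformerMixin):
    """Maximum-likelihood exploratory factor analysis with parallel analysis.

    Fits the one-or-more-factor normal-theory model to the correlation
    matrix of the (internally z-scored) input, optionally choosing the
    number of factors by parallel analysis, and produces regression-method
    factor scores via ``transform``.

    Parameters
    ----------
    n_factors : int or "parallel", default "parallel"
        Fixed factor count, or automatic retention by parallel analysis.
    n_permutations : int, default 10_000
        Column permutations for the parallel-analysis null.
    null_summary : {"mean", "p95"}, default "mean"
        Summary of the permutation eigenvalue distribution.
    n_bootstrap : int, default 0
        Subject resamples for 5-95% loading confidence bounds (0 disables).
    random_state : int, default 0

    Attributes
    ----------
    loadings_ : (p, k) array; uniquenesses_ : (p,) array
    n_factors_, var_explained_, rmsr_, rmsea_, tli_, chi_square_, df_
    eigenvalues_ / eigenvalue_null_ : observed and null scree
    loading_ci_ : (p, k, 2) array or None
    """

    def __init__(
        self,
        n_factors: int | str = "parallel",
        n_permutations: int = 10_000,
        null_summary: str = "mean",
        n_bootstrap: int = 0,
        random_state: int = 0,
    ):
        self.n_factors = n_factors
        self.n_permutations = n_permutations
        self.null_summary = null_summary
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, X: pd.DataFrame | np.ndarray, y=None) -> "MLFactorAnalysis":
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ValueError("EFA admits complete cases only; drop rows with missing values")
        z = zscore(X)
        zx = z.to_numpy(dtype=float)
        n, p = zx.shape
        corr = np.corrcoef(zx, rowvar=False)
        rng = np.random.default_rng(self.random_state)

        if self.n_factors == "parallel":
            k = parallel_analysis(zx, self.n_permutations, rng, self.null_summary)
            k = max(k, 1)  # a score is always produced for the best solution
        else:
            k = int(self.n_factors)
        sol = ml_efa(corr, k, n_obs=n)
        if self.n_bootstrap:
            sol.loading_ci = bootstrap_loading_ci(zx, k, self.n_bootstrap, rng)
        sol.eigenvalues_observed = np.linalg.eigvalsh(corr)[::-1]

        self.measure_names_ = list(X.columns)
        self.mean_ = X.mean().to_numpy(dtype=float)
        self.sd_ = X.std(ddof=1).to_numpy(dtype=float)
        self.corr_ = corr
        self.n_factors_ = k
        self.loadings_ = sol.loadings
        self.uniquenesses_ = sol.uniquenesses
        self.var_explained_ = sol.var_explained
        self.rmsr_ = sol.rmsr
        self.rmsea_ = sol.rmsea
        self.tli_ = sol.tli
        self.chi_square_ = sol.chi_square
        self.df_ = sol.df
        self.heywood_ = sol.heywood
        self.eigenvalues_ = sol.eigenvalues_observed
        self.loading_ci_ = sol.loading_ci
        self.solution_ = sol
        return self

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Regression-method factor scores, standardized, shape (n, k)."""
        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)
        z = (X.to_numpy(dtype=float) - self.mean_) / self.sd_
        return factor_scores(self.loadings_, self.corr_, z)
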