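"""Standardized regression, one-sample tests, bootstrap mediation, and
regional efficiency-association maps.

All path coefficients are standardized betas (variables z-scored before
fitting), so for a simple regression beta equals the Pearson correlation and
R^2 = beta^2.  The mediation decomposes the total effect c of network
efficiency on attainment into a direct part c' and an indirect part a*b
routed through the cognitive factor, with a percentile bootstrap over
subject resamples for the indirect effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "RegressionResult",
    "MediationResult",
    "one_sample_t",
    "simple_regression_standardized",
    "mediation",
    "MediationAnalysis",
    "regional_association",
    "nuisance_regressions",
]


def _z(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; cannot standardize")
    return (x - x.mean()) / sd


def one_sample_t(mean: float, sd: float, n: int) -> tuple[float, float]:
    """One-sample t against 0 from summary statistics: t = mean / (sd / sqrt n)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass
class RegressionResult:
    beta: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    boot_band: pd.DataFrame | None = None  # columns x, lo, hi of the fitted line


def simple_regression_standardized(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 500,
    seed: int | np.random.Generator = 0,
    band_points: int = 50,
) -> RegressionResult:
    """Simple regression after z-scoring both variables.

    beta is then the Pearson correlation, R^2 = beta^2, and
    F = R^2 (n-2) / (1 - R^2) on (1, n-2) df.  A 5-95% confidence band of
    the fitted line is obtained by subject resampling (default 500).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    zx, zy = _z(x), _z(y)
    beta = float(zx @ zy / (n - 1))
    r2 = beta**2
    df = (1, n - 2)
    if r2 >= 1.0:
        f, p = np.inf, 0.0
    else:
        f = r2 * df[1] / (1 - r2)
        p = float(stats.f.sf(f, *df))
    band = None
    if n_boot:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        idx = rng.integers(0, n, size=(n_boot, n))
        bx, by = zx[idx], zy[idx]
        bxc = bx - bx.mean(axis=1, keepdims=True)
        byc = by - by.mean(axis=1, keepdims=True)
        slope = (bxc * byc).sum(axis=1) / (bxc**2).sum(axis=1)
        intercept = by.mean(axis=1) - slope * bx.mean(axis=1)
        grid = np.linspace(zx.min(), zx.max(), band_points)
        lines = intercept[:, None] + slope[:, None] * grid[None, :]
        band = pd.DataFrame(
            {
                "x": grid,
                "lo": np.percentile(lines, 5, axis=0),
                "hi": np.percentile(lines, 95, axis=0),
            }
        )
    return RegressionResult(beta, r2, float(f), df, p, band)


@dataclass
class MediationResult:
    a: float  # x -> m
    b: float  # m -> y given x
    c: float  # total x -> y
    c_prime: float  # direct x -> y given m
    indirect: float  # a * b
    indirect_ci: tuple[float, float]
    proportion_mediated: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    partial_mediation: bool
    n_boot: int


def _paths_from_corr(r_xm, r_xy, r_my):
    """Standardized OLS paths from the three pairwise correlations."""
    denom = 1.0 - r_xm**2
    a = r_xm
    b = (r_my - r_xy * r_xm) / denom
    c_prime = (r_xy - r_my * r_xm) / denom
    c = r_xy
    return a, b, c, c_prime


def mediation(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_boot: int = 5000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> MediationResult:
    """Standardized OLS mediation with a percentile bootstrap for a*b.

    Paths: a from m ~ x; b and c' from y ~ x + m; c from y ~ x.  The
    identity c = c' + a*b holds exactly for OLS on the same sample.  The
    indirect-effect CI resamples subjects; mediation is flagged partial
    when the CI excludes 0 while c' stays significant at ``alpha``.
    """
    x, m, y = (np.asarray(v, float) for v in (x, m, y))
    if not (x.shape == m.shape == y.shape) or x.ndim != 1:
        raise ValueError("x, m, y must be aligned 1-d arrays")
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 complete triples")
    zx, zm, zy = _z(x), _z(m), _z(y)
    r_xm = float(zx @ zm / (n - 1))
    if abs(r_xm) > 0.999:
        raise ValueError("x and m are collinear (|r| > 0.999)")
    r_xy = float(zx @ zy / (n - 1))
    r_my = float(zm @ zy / (n - 1))
    a, b, c, c_prime = _paths_from_corr(r_xm, r_xy, r_my)

    p_a = _slope_p(r_xm, n, 1)
    p_c = _slope_p(r_xy, n, 1)
    p_b = _partial_p(b, zy, np.column_stack([zx, zm]), which=1)
    p_cp = _partial_p(c_prime, zy, np.column_stack([zx, zm]), which=0)

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.integers(0, n, size=(n_boot, n))
    indirect_boot = _boot_indirect(zx[idx], zm[idx], zy[idx])
    lo, hi = np.percentile(indirect_boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    indirect = a * b
    ci_excludes_zero = (lo > 0) or (hi < 0)
    prop = indirect / c if c != 0 else np.nan
    return MediationResult(
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=indirect,
        indirect_ci=(float(lo), float(hi)),
        proportion_mediated=float(prop),
        p_a=p_a,
        p_b=p_b,
        p_c=p_c,
        p_c_prime=p_cp,
        partial_mediation=bool(ci_excludes_zero and p_cp < alpha),
        n_boot=n_boot,
    )


def _boot_indirect(bx: np.ndarray, bm: np.ndarray, by: np.ndarray) -> np.ndarray:
    """Vectorized a*b over bootstrap resamples (rows)."""

    def corr(u, v):
        uc = u - u.mean(axis=1, keepdims=True)
        vc = v - v.mean(axis=1, keepdims=True)
        return (uc * vc).sum(axis=1) / np.sqrt((uc**2).sum(axis=1) * (vc**2).sum(axis=1))

    r_xm = corr(bx, bm)
    r_xy = corr(bx, by)
    r_my = corr(bm, by)
    denom = 1.0 - r_xm**2
    denom[denom == 0] = np.nan
    a = r_xm
    b = (r_my - r_xy * r_xm) / denom
    return a * b


def _slope_p(r: float, n: int, n_pred: int) -> float:
    df = n - n_pred - 1
    r2 = min(r**2, 1 - 1e-15)
    t = r * np.sqrt(df / (1 - r2))
    return float(2 * stats.t.sf(abs(t), df))


def _partial_p(beta: float, y: np.ndarray, x: np.ndarray, which: int) -> float:
    """t-test p-value for one coefficient of an OLS fit on standardized data."""
    n, p = x.shape
    design = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sigma2 = resid @ resid / (n - p - 1)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(cov[which + 1, which + 1])
    t = beta / se
    return float(2 * stats.t.sf(abs(t), n - p - 1))


class MediationAnalysis(BaseEstimator):
    """Estimator wrapper around :func:`mediation`.

    ``fit(X, y)`` expects ``X`` with columns (x, m) — predictor then
    mediator — and ``y`` the outcome.  Fitted attributes mirror
    :class:`MediationResult` with trailing underscores.
    """

    def __init__(self, n_boot: int = 5000, random_state: int = 0, alpha: float = 0.05):
        self.n_boot = n_boot
        self.random_state = random_state
        self.alpha = alpha

    def fit(self, X, y) -> "MediationAnalysis":
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have exactly two columns: predictor and mediator")
        res = mediation(
            X[:, 0], X[:, 1], np.asarray(y, float), self.n_boot, self.random_state, self.alpha
        )
        self.result_ = res
        self.a_, self.b_, self.c_, self.c_prime_ = res.a, res.b, res.c, res.c_prime
        self.indirect_ = res.indirect
        self.indirect_ci_ = res.indirect_ci
        self.proportion_mediated_ = res.proportion_mediated
        self.partial_mediation_ = res.partial_mediation
        return self


def regional_association(
    ej_auc: pd.DataFrame | np.ndarray,
    factor_scores: np.ndarray,
    volumes: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-node standardized beta of factor score on nodal-efficiency AUC.

    Returns one row per node with the uncorrected beta/p and, when regional
    grey-matter volumes are supplied, the beta/p with the node's volume as a
    covariate.  A volume column that is constant across subjects is dropped
    (the corrected model then equals the uncorrected one).
    """
    ej = pd.DataFrame(ej_auc)
    scores = np.asarray(factor_scores, float).ravel()
    if len(scores) != len(ej):
        raise ValueError("factor scores and E_j rows must align by subject")
    if volumes is not None:
        volumes = pd.DataFrame(np.asarray(volumes, float))
        if volumes.shape != ej.shape:
            raise ValueError(
                f"volume table shape {volumes.shape} does not match E_j shape {ej.shape}"
            )
    zy = _z(scores)
    rows = []
    for j, node in enumerate(ej.columns):
        ze = _z(ej.iloc[:, j].to_numpy())
        beta = float(ze @ zy / (len(zy) - 1))
        p = _slope_p(beta, len(zy), 1)
        beta_c, p_c = beta, p
        if volumes is not None:
            vol = volumes.iloc[:, j].to_numpy()
            if np.ptp(vol) > 0:
                zv = _z(vol)
                design = np.column_stack([ze, zv])
                r_ev = float(ze @ zv / (len(zy) - 1))
                r_ey = beta
                r_vy = float(zv @ zy / (len(zy) - 1))
                beta_c = (r_ey - r_vy * r_ev) / (1 - r_ev**2)
                p_c = _partial_p(beta_c, zy, design, which=0)
        rows.append((node, beta, p, beta_c, p_c))
    return pd.DataFrame(
        rows, columns=["node", "beta", "p", "beta_volume_corrected", "p_volume_corrected"]
    )


def nuisance_regressions(
    outcomes: pd.DataFrame, nuisance: pd.DataFrame
) -> pd.DataFrame:
    """Simple standardized regressions of every outcome on every nuisance variable.

    One row per (outcome, nuisance) pair with the standardized beta and its
    p-value — the screen for confounding by age, sex, motion and volume.
    """
    if len(outcomes) != len(nuisance):
        raise ValueError("outcome and nuisance tables must align by subject")
    rows = []
    for out_name in outcomes.columns:
        for nui_name in nuisance.columns:
            res = simple_regression_standardized(
                nuisance[nui_name].to_numpy(), outcomes[out_name].to_numpy(), n_boot=0
            )
            rows.append((out_name, nui_name, res.beta, res.p_value))
    return pd.DataFrame(rows, columns=["outcome", "nuisance", "beta", "p"])
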