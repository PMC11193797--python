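"""Baseline (non-network) logistic regressions and average marginal effects.

Maximum-likelihood logistic fits via iteratively reweighted least squares
(through statsmodels GLM), with collinear-column dropping, separation
detection and a flagged ridge-penalised fallback; average marginal effects
with delta-method confidence intervals; and the averaged predicted-
probability profile over the number of non-resident members (with the
interior maximiser when the quadratic term bends the curve into an inverted
U).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

NONRESIDENT_TOP_CODE = 15
HOUSEHOLD_SIZE_TOP_CODE = 20


@dataclass
class LogitFit:
    params: pd.Series
    cov: pd.DataFrame
    deviance: float
    converged: bool
    separation: bool
    dropped_columns: list
    X: pd.DataFrame  # design actually used (post-drop, with const)
    y: np.ndarray

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        X = self.X if X is None else X[self.params.index]
        eta = X.to_numpy(dtype=float) @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def build_covariates(
    attributes: pd.DataFrame,
    index: pd.DataFrame | None = None,
    tie_years: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the household covariate table used by models at both levels.

    Top-codes ``n_nonresidents`` at 15 and ``household_size`` at 20, merges
    the baseline wealth quintile from the wealth index and the mean
    shared-tie-years network covariate when provided.
    """
    cov = attributes.copy()
    if "n_nonresidents" in cov:
        cov["n_nonresidents"] = np.minimum(cov["n_nonresidents"], NONRESIDENT_TOP_CODE)
    if "household_size" in cov:
        cov["household_size"] = np.minimum(cov["household_size"], HOUSEHOLD_SIZE_TOP_CODE)
    if index is not None:
        cov["baseline_quintile"] = index["q_w1"].reindex(cov.index)
    if tie_years is not None:
        cov["mean_tie_years"] = tie_years.reindex(cov.index).fillna(0.0)
    return cov


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Greedily drop columns until the design is full rank."""
    dropped = []
    while X.shape[1] > 1:
        A = X.to_numpy(dtype=float)
        if np.linalg.matrix_rank(A) == X.shape[1]:
            break
        # drop the last column involved in the rank deficiency
        for j in range(X.shape[1] - 1, 0, -1):
            sub = np.delete(A, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(A):
                dropped.append(X.columns[j])
                X = X.drop(columns=[X.columns[j]])
                break
    if dropped:
        logger.warning("dropped collinear design columns: %s", dropped)
    return X, dropped


def _ridge_irls(
    X: np.ndarray, y: np.ndarray, penalty: float = 1e-6, tol: float = 1e-8, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray, float]:
    """Ridge-penalised IRLS fallback for separated data (intercept unpenalised)."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, penalty)
    pen[0] = 0.0  # first column is the intercept
    dev_old = np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X + np.diag(pen)
        beta = np.linalg.solve(H, XtW @ z)
        mu = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30)))
        dev = -2.0 * np.sum(y * np.log(np.clip(mu, 1e-12, 1)) + (1 - y) * np.log(np.clip(1 - mu, 1e-12, 1)))
        if abs(dev_old - dev) < tol:
            break
        dev_old = dev
    cov = np.linalg.inv(H)
    return beta, cov, dev


def fit_logit(
    y, design: pd.DataFrame, add_intercept: bool = True, ridge_penalty: float = 1e-6
) -> LogitFit:
    """Logistic regression of a binary outcome on a covariate design.

    Rows with missing outcome or covariates are dropped.  Collinear columns
    are removed with a warning.  Complete or quasi-complete separation is
    detected (non-convergence or runaway coefficients) and handled by a
    flagged ridge-penalised refit, mandatory for the 23-region regional
    baseline model.
    """
    y = pd.Series(y)
    df = design.copy()
    df = df.loc[y.index.intersection(df.index)] if not df.index.equals(y.index) else df
    keep = y.notna() & df.notna().all(axis=1)
    yv = y[keep].to_numpy(dtype=float)
    X = df[keep].astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    X, dropped = _drop_collinear(X)

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(yv, X, family=sm.families.Binomial())
        try:
            res = model.fit(tol=1e-8, maxiter=200)
            params = res.params.to_numpy()
            converged = bool(res.converged)
        except Exception:
            converged = False
            params = np.zeros(X.shape[1])
    mu = 1.0 / (1.0 + np.exp(-np.clip(X.to_numpy() @ params, -30, 30)))
    fitted_extreme = ((mu > 1 - 1e-6) | (mu < 1e-6)).mean()
    if (not converged) or np.abs(params).max() > 15 or fitted_extreme > 0.05:
        separation = True
        logger.warning("separation suspected; returning ridge-penalised fit (flagged)")
        beta, cov, dev = _ridge_irls(X.to_numpy(dtype=float), yv, penalty=ridge_penalty)
        return LogitFit(
            params=pd.Series(beta, index=X.columns),
            cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
            deviance=dev,
            converged=True,
            separation=True,
            dropped_columns=dropped,
            X=X,
            y=yv,
        )
    return LogitFit(
        params=pd.Series(res.params.to_numpy(), index=X.columns),
        cov=pd.DataFrame(res.cov_params().to_numpy(), index=X.columns, columns=X.columns),
        deviance=float(res.deviance),
        converged=converged,
        separation=False,
        dropped_columns=dropped,
        X=X,
        y=yv,
    )


@dataclass
class MarginalEffect:
    variable: str
    ame: float
    std_err: float
    ci_low: float
    ci_high: float
    kind: str  # "discrete" or "derivative"


def average_marginal_effect(fit: LogitFit, variable: str) -> MarginalEffect:
    """Average marginal effect of one design variable, delta-method CI.

    Binary variables (values in {0,1}) get the average discrete change in
    predicted probability from 0 to 1; continuous variables the average
    derivative beta * p * (1 - p).
    """
    if variable not in fit.params.index:
        raise KeyError(f"{variable!r} not in the fitted design")
    X = fit.X.to_numpy(dtype=float)
    cols = list(fit.params.index)
    j = cols.index(variable)
    beta = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    vals = np.unique(X[:, j])
    binary = np.isin(vals, (0.0, 1.0)).all()
    if binary:
        X1, X0 = X.copy(), X.copy()
        X1[:, j], X0[:, j] = 1.0, 0.0
        p1 = 1.0 / (1.0 + np.exp(-X1 @ beta))
        p0 = 1.0 / (1.0 + np.exp(-X0 @ beta))
        ame = float(np.mean(p1 - p0))
        grad = (p1 * (1 - p1))[:, None] * X1 - (p0 * (1 - p0))[:, None] * X0
        g = grad.mean(axis=0)
        kind = "discrete"
    else:
        p = 1.0 / (1.0 + np.exp(-X @ beta))
        w = p * (1 - p)
        ame = float(np.mean(beta[j] * w))
        g = (beta[j] * w * (1 - 2 * p))[:, None] * X
        g = g.mean(axis=0)
        g[j] += float(np.mean(w))
        kind = "derivative"
    se = float(np.sqrt(g @ V @ g))
    return MarginalEffect(
        variable=variable,
        ame=ame,
        std_err=se,
        ci_low=ame - 1.96 * se,
        ci_high=ame + 1.96 * se,
        kind=kind,
    )


@dataclass
class NonresidentProfile:
    table: pd.DataFrame  # columns: m, probability
    maximiser: float | None  # interior argmax -b1/(2 b2) when b2 < 0


def nonresident_profile(
    fit: LogitFit,
    linear: str = "n_nonresidents",
    quadratic: str = "n_nonresidents_sq",
    m_max: int = NONRESIDENT_TOP_CODE,
) -> NonresidentProfile:
    """Averaged predicted probability at each non-resident count m = 0..m_max.

    Requires both the linear and quadratic non-resident terms in the design.
    When the quadratic coefficient is negative the curve is an inverted U and
    the interior maximiser -b1 / (2 b2) is reported.
    """
    for v in (linear, quadratic):
        if v not in fit.params.index:
            raise KeyError(f"{v!r} not in the fitted design")
    X = fit.X.to_numpy(dtype=float)
    cols = list(fit.params.index)
    jl, jq = cols.index(linear), cols.index(quadratic)
    beta = fit.params.to_numpy()
    rows = []
    for m in range(m_max + 1):
        Xm = X.copy()
        Xm[:, jl] = m
        Xm[:, jq] = m * m
        p = 1.0 / (1.0 + np.exp(-Xm @ beta))
        rows.append({"m": m, "probability": float(p.mean())})
    b1, b2 = beta[jl], beta[jq]
    maximiser = float(-b1 / (2.0 * b2)) if b2 < 0 else None
    return NonresidentProfile(table=pd.DataFrame(rows), maximiser=maximiser)
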