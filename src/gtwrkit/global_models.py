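"""Global (non-spatial) baseline models and predictor screening.

OLS is the stationary benchmark the local model is judged against; VIF and
cross-validated LASSO screen the covariates for redundancy, and the
Breusch-Pagan statistic checks residual homoscedasticity.  Fitting is
delegated to statsmodels / scikit-learn; this module fixes the conventions
(t statistics on n-p-1 df, RMSE = sqrt(SSR/n), AICc in the hat-trace form
with tr(S) = p+1 so it is directly comparable to the local smoother).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .errors import InvalidArgumentError, SingularDesignError

__all__ = ["OlsFit", "LassoFit", "ols_fit", "vif", "breusch_pagan", "lasso_cv"]


@dataclass(frozen=True)
class OlsFit:
    params: np.ndarray  # beta_0 .. beta_k (intercept first)
    bse: np.ndarray
    tvalues: np.ndarray  # t statistics, n - p - 1 df
    pvalues: np.ndarray  # two-sided
    r2: float
    adj_r2: float
    residuals: np.ndarray
    fitted: np.ndarray
    rmse: float
    aicc: float
    names: tuple[str, ...]


@dataclass(frozen=True)
class LassoFit:
    alpha: float
    intercept: float
    coefs: np.ndarray
    cv_rmse: float
    zeroed: tuple[str, ...]
    names: tuple[str, ...]


def hat_trace_aicc(n: int, sigma: float, trace_s: float) -> float:
    """AICc = 2n ln(sigma) + n ln(2pi) + n (n + tr(S)) / (n - 2 - tr(S))."""
    from .errors import AICcUndefinedError

    if n - 2 - trace_s <= 0:
        raise AICcUndefinedError("n - 2 - tr(S) <= 0: effective df exhausted")
    return 2 * n * np.log(sigma) + n * np.log(2 * np.pi) + n * (n + trace_s) / (
        n - 2 - trace_s
    )


def _offending_columns(X: np.ndarray, names) -> list[str]:
    """Columns involved in an exact linear dependence (R^2 on the others ~ 1)."""
    bad = []
    for k in range(X.shape[1]):
        others = np.delete(X, k, axis=1)
        resid = X[:, k] - others @ np.linalg.lstsq(others, X[:, k], rcond=None)[0]
        denom = np.sum((X[:, k] - X[:, k].mean()) ** 2)
        if denom == 0 or np.sum(resid**2) / denom < 1e-10:
            bad.append(names[k])
    return bad


def ols_fit(X: np.ndarray, y, names: tuple[str, ...] | None = None) -> OlsFit:
    """Ordinary least squares on a design that already includes the
    intercept column (first)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p1 = X.shape
    names = tuple(names) if names else ("const", *(f"x{k}" for k in range(1, p1)))
    if n <= p1:
        raise InvalidArgumentError(f"need n > p + 1 (n={n}, columns={p1})")
    if np.linalg.matrix_rank(X) < p1:
        raise SingularDesignError(
            "design matrix is rank deficient", columns=_offending_columns(X, names)
        )
    res = sm.OLS(y, X).fit()
    ssr = float(np.sum(res.resid**2))
    sigma = np.sqrt(ssr / n)
    aicc = hat_trace_aicc(n, max(sigma, 1e-300), float(p1))
    return OlsFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        residuals=res.resid,
        fitted=res.fittedvalues,
        rmse=float(sigma),
        aicc=float(aicc),
        names=names,
    )


def vif(X: np.ndarray, names: tuple[str, ...] | None = None) -> dict[str, float]:
    """Variance inflation factor per covariate column (no intercept in X).

    VIF_k = 1 / (1 - R^2_k) where R^2_k comes from regressing column k on
    all other columns plus an intercept.  Perfect collinearity yields +inf.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = tuple(names) if names else tuple(f"x{k}" for k in range(1, p + 1))
    out = {}
    for k in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, k, axis=1)])
        beta = np.linalg.lstsq(others, X[:, k], rcond=None)[0]
        resid = X[:, k] - others @ beta
        sst = float(np.sum((X[:, k] - X[:, k].mean()) ** 2))
        if sst == 0:
            raise InvalidArgumentError(f"column {names[k]} is constant")
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        if r2 >= 1.0 - 1e-12:
            import warnings

            warnings.warn(f"perfect collinearity: VIF of {names[k]} is infinite")
            out[names[k]] = np.inf
        else:
            out[names[k]] = 1.0 / (1.0 - r2)
    return out


def breusch_pagan(fit: OlsFit, X: np.ndarray) -> tuple[float, float]:
    """Lagrange-multiplier heteroscedasticity test: LM = n * R^2 of the
    auxiliary regression of squared residuals on the design; p from
    chi-square with k (number of covariates) degrees of freedom."""
    X = np.asarray(X, dtype=float)
    u2 = fit.residuals**2
    scale = max(1.0, float(np.max(np.abs(fit.fitted))))
    sq_spread = float(np.max(u2) - np.min(u2))
    # squared residuals (numerically) constant: no detectable heteroscedasticity
    if sq_spread <= (1e-10 * scale) ** 2:
        return 0.0, 1.0
    lm, lm_p, _, _ = sm.stats.diagnostic.het_breuschpagan(fit.residuals, X)
    return float(lm), float(lm_p)


def lasso_cv(
    X: np.ndarray,
    y,
    alpha_grid,
    folds: int = 5,
    seed: int = 0,
    names: tuple[str, ...] | None = None,
) -> LassoFit:
    """L1-penalized regression with seeded k-fold selection of alpha.

    Objective (scikit-learn convention): (1/2n)||y - b0 - Xb||^2 + alpha ||b||_1
    with the intercept unpenalized.  alpha = 0 reduces to OLS slopes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    alpha_grid = list(alpha_grid)
    if not alpha_grid:
        raise InvalidArgumentError("alpha_grid must be nonempty")
    if folds < 2:
        raise InvalidArgumentError("need at least 2 folds")
    names = tuple(names) if names else tuple(f"x{k}" for k in range(1, X.shape[1] + 1))

    def _fit(alpha, Xtr, ytr):
        if alpha == 0:
            beta = np.linalg.lstsq(
                np.column_stack([np.ones(len(ytr)), Xtr]), ytr, rcond=None
            )[0]
            return beta[0], beta[1:]
        m = Lasso(alpha=alpha, max_iter=100_000).fit(Xtr, ytr)
        return m.intercept_, m.coef_

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    cv_mse = []
    for alpha in alpha_grid:
        errs = []
        for tr, te in splits:
            b0, b = _fit(alpha, X[tr], y[tr])
            errs.append(np.mean((y[te] - b0 - X[te] @ b) ** 2))
        cv_mse.append(np.mean(errs))
    best = int(np.argmin(cv_mse))
    alpha_star = alpha_grid[best]
    b0, b = _fit(alpha_star, X, y)
    zeroed = tuple(nm for nm, c in zip(names, b) if c == 0.0)
    return LassoFit(
        alpha=float(alpha_star),
        intercept=float(b0),
        coefs=np.asarray(b),
        cv_rmse=float(np.sqrt(cv_mse[best])),
        zeroed=zeroed,
        names=names,
    )
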