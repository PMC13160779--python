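"""Geographically and temporally weighted regression (GTWR).

The model lets every region-year observation carry its own coefficient
vector,

    y_i(t) = beta_i0(t) + sum_k beta_ik(t) x_ik + eps_i,

estimated at each observation by weighted least squares,

    beta_hat_i = (X' W_i X)^{-1} X' W_i y,

where W_i is diagonal with entries formed as the product of a fixed
Gaussian spatial kernel and an exponential temporal decay:

    w_ij = exp(-d_ij^2 / (2 b^2)) * exp(-|t_i - t_j| / h),

with d_ij the centroid distance in km, b the spatial bandwidth (km) and
h the temporal bandwidth (years).  Bandwidths are chosen by minimizing
the corrected AIC

    AICc = 2n ln(sigma) + n ln(2pi) + n (n + tr(S)) / (n - 2 - tr(S)),

where S is the hat matrix of the fitted linear smoother and
sigma = sqrt(SSR / n).  As b, h -> infinity every local fit collapses to
the global OLS solution and tr(S) -> p + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AICcUndefinedError,
    InvalidArgumentError,
    SelectionFailureError,
    SingularLocalFitError,
)
from .global_models import hat_trace_aicc
from .moran import GlobalMoranResult, global_moran
from .weights import SpatialWeightMatrix

__all__ = [
    "GTWRConfig",
    "GTWRFit",
    "spatial_weight",
    "temporal_weight",
    "combined_weights",
    "local_fit",
    "fit",
    "select_bandwidths",
    "coefficient_summary",
    "classify_strength",
    "residual_moran",
]


@dataclass(frozen=True)
class GTWRConfig:
    """Kernel bandwidths: spatial b in km, temporal h in years."""

    b: float
    h: float

    def __post_init__(self):
        if self.b <= 0 or self.h <= 0:
            raise InvalidArgumentError("bandwidths must be strictly positive")


@dataclass(frozen=True)
class GTWRFit:
    beta: np.ndarray  # n x (p+1), intercept first
    se: np.ndarray
    tvalues: np.ndarray  # pseudo-t = beta / se
    fitted: np.ndarray
    residuals: np.ndarray
    hat_diag: np.ndarray
    trace_s: float
    r2: float
    adj_r2: float
    rmse: float
    aicc: float
    sigma2: float  # residual variance on effective df, used for SEs
    config: GTWRConfig
    names: tuple[str, ...]
    region_ids: tuple[str, ...] = ()
    years: tuple[int, ...] = ()

    def local_table(self) -> pd.DataFrame:
        """Long-form table (region_id, year, predictor, beta, se, t)."""
        rows = []
        for i in range(len(self.fitted)):
            for k, nm in enumerate(self.names):
                rows.append(
                    {
                        "region_id": self.region_ids[i] if self.region_ids else str(i),
                        "year": self.years[i] if self.years else 0,
                        "predictor": nm,
                        "beta": self.beta[i, k],
                        "se": self.se[i, k],
                        "t": self.tvalues[i, k],
                    }
                )
        return pd.DataFrame(rows)


def spatial_weight(d, b: float):
    """Fixed Gaussian kernel exp(-d^2 / (2 b^2)); 1 at d = 0."""
    if b <= 0:
        raise InvalidArgumentError("spatial bandwidth must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise InvalidArgumentError("distances must be nonnegative")
    return np.exp(-(d**2) / (2.0 * b**2))


def temporal_weight(t_i, t_j, h: float):
    """Exponential decay exp(-|t_i - t_j| / h); 1 at equal times."""
    if h <= 0:
        raise InvalidArgumentError("temporal bandwidth must be positive")
    return np.exp(-np.abs(np.asarray(t_i, dtype=float) - np.asarray(t_j, dtype=float)) / h)


def combined_weights(
    i: int, coords: np.ndarray, times: np.ndarray, config: GTWRConfig
) -> np.ndarray:
    """Product kernel weight of every observation relative to observation i."""
    d = np.hypot(coords[:, 0] - coords[i, 0], coords[:, 1] - coords[i, 1])
    return spatial_weight(d, config.b) * temporal_weight(times, times[i], config.h)


def local_fit(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, i: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One weighted least-squares solve.

    Returns (beta_i, unscaled covariance diag(C C'), hat row s_i) where
    C = (X' W X)^{-1} X' W; the caller multiplies by sigma^2 for SEs.
    """
    Xw = X * w[:, None]
    A = X.T @ Xw
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise SingularLocalFitError(
            f"weighted design singular at observation {i} (weights too concentrated)",
            obs_index=i,
        ) from exc
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularLocalFitError(
            f"weighted design near-singular at observation {i} (cond={cond:.2e})",
            obs_index=i,
        )
    C = Ainv @ Xw.T
    beta = C @ y
    cov_unscaled = np.einsum("kj,kj->k", C, C)
    s_row = X[i] @ C if i is not None else None
    return beta, cov_unscaled, s_row


def fit(
    X: np.ndarray,
    y,
    coords: np.ndarray,
    times,
    config: GTWRConfig,
    names: tuple[str, ...] | None = None,
    region_ids: tuple[str, ...] = (),
) -> GTWRFit:
    """Fit the local model at every observation.

    ``X`` must include the intercept column first; ``coords`` are planar
    centroids in km; ``times`` numeric years.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    times = np.asarray(times, dtype=float)
    n, p1 = X.shape
    names = tuple(names) if names else ("const", *(f"x{k}" for k in range(1, p1)))
    beta = np.empty((n, p1))
    cov = np.empty((n, p1))
    hat = np.empty(n)
    for i in range(n):
        w = combined_weights(i, coords, times, config)
        b_i, cov_i, s_i = local_fit(X, y, w, i)
        beta[i] = b_i
        cov[i] = cov_i
        hat[i] = s_i[i]
    fitted = np.einsum("ik,ik->i", X, beta)
    resid = y - fitted
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    trace_s = float(hat.sum())
    r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - trace_s) if n > trace_s else np.nan
    sigma = np.sqrt(ssr / n)
    aicc = hat_trace_aicc(n, max(sigma, 1e-300), trace_s)
    eff_df = n - trace_s
    sigma2 = ssr / eff_df if eff_df > 0 else np.nan
    se = np.sqrt(sigma2 * cov)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    return GTWRFit(
        beta=beta,
        se=se,
        tvalues=tvals,
        fitted=fitted,
        residuals=resid,
        hat_diag=hat,
        trace_s=trace_s,
        r2=r2,
        adj_r2=adj_r2,
        rmse=float(sigma),
        aicc=float(aicc),
        sigma2=float(sigma2),
        config=config,
        names=names,
        region_ids=tuple(region_ids),
        years=tuple(int(t) for t in times),
    )


def _golden_section(f, lo: float, hi: float, tol: float = 1e-3, max_iter: int = 40) -> float:
    """Minimize a unimodal 1-D function on [lo, hi] (log-scale caller)."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if abs(b - a) < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def select_bandwidths(
    X: np.ndarray,
    y,
    coords: np.ndarray,
    times,
    b_grid=None,
    h_grid=None,
    refine: bool = True,
) -> tuple[float, float, pd.DataFrame]:
    """AICc-minimizing bandwidth search.

    Exhaustive evaluation on a log-spaced grid (default 15 x 15 spanning
    [0.1, 10] x the maximum pairwise distance and [0.25, 10 x time span]),
    then optional golden-section refinement around the grid minimum, one
    axis at a time.  Returns (b*, h*, full AICc surface).
    """
    coords = np.asarray(coords, dtype=float)
    times = np.asarray(times, dtype=float)
    if b_grid is None:
        dmax = max(
            float(
                np.hypot(
                    coords[:, 0].max() - coords[:, 0].min(),
                    coords[:, 1].max() - coords[:, 1].min(),
                )
            ),
            1e-6,
        )
        b_grid = np.geomspace(0.1 * dmax, 10 * dmax, 15)
    if h_grid is None:
        span = max(float(times.max() - times.min()), 1.0)
        h_grid = np.geomspace(0.25, 10 * span, 15)
    b_grid, h_grid = np.asarray(b_grid, float), np.asarray(h_grid, float)
    if b_grid.size == 0 or h_grid.size == 0:
        raise InvalidArgumentError("bandwidth grids must be nonempty")

    def aicc_at(b, h):
        try:
            return fit(X, y, coords, times, GTWRConfig(b=b, h=h)).aicc
        except (AICcUndefinedError, SingularLocalFitError):
            return np.inf

    rows = []
    for b in b_grid:
        for h in h_grid:
            rows.append({"b": b, "h": h, "aicc": aicc_at(b, h)})
    surface = pd.DataFrame(rows)
    if not np.isfinite(surface["aicc"]).any():
        raise SelectionFailureError("AICc undefined at every grid point")
    best = surface.loc[surface["aicc"].idxmin()]
    b_star, h_star = float(best["b"]), float(best["h"])
    if refine and len(b_grid) > 1 and len(h_grid) > 1:
        ib = int(np.argmin(np.abs(b_grid - b_star)))
        ih = int(np.argmin(np.abs(h_grid - h_star)))
        b_lo = np.log(b_grid[max(ib - 1, 0)])
        b_hi = np.log(b_grid[min(ib + 1, len(b_grid) - 1)])
        b_star = float(np.exp(_golden_section(lambda lb: aicc_at(np.exp(lb), h_star), b_lo, b_hi)))
        h_lo = np.log(h_grid[max(ih - 1, 0)])
        h_hi = np.log(h_grid[min(ih + 1, len(h_grid) - 1)])
        h_star = float(np.exp(_golden_section(lambda lh: aicc_at(b_star, np.exp(lh)), h_lo, h_hi)))
        if aicc_at(b_star, h_star) > best["aicc"]:
            b_star, h_star = float(best["b"]), float(best["h"])  # never worse than grid
    return b_star, h_star, surface


def coefficient_summary(fit_result: GTWRFit, t_cutoff: float = 1.96) -> pd.DataFrame:
    """Per-predictor distribution of the local estimates: mean, sd, min, max
    and the percent of observations with |pseudo-t| at or above the cutoff."""
    rows = []
    for k, nm in enumerate(fit_result.names):
        b = fit_result.beta[:, k]
        rows.append(
            {
                "predictor": nm,
                "mean": float(b.mean()),
                "sd": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
                "min": float(b.min()),
                "max": float(b.max()),
                "pct_significant": 100.0
                * float(np.mean(np.abs(fit_result.tvalues[:, k]) >= t_cutoff)),
            }
        )
    return pd.DataFrame(rows)


#: strength bins for mapping local coefficients; right-open on the positive
#: side, mirrored for negatives, exactly zero means no local association.
_BINS = [
    (0.25, "weak"),
    (0.5, "moderate"),
    (1.0, "strong"),
    (np.inf, "very strong"),
]


def classify_strength(beta: float) -> str:
    """Label a local coefficient by magnitude bin and sign."""
    if not np.isfinite(beta):
        raise InvalidArgumentError("coefficient must be finite")
    if beta == 0:
        return "none"
    mag = abs(beta)
    sign = "positive" if beta > 0 else "negative"
    for hi, label in _BINS:
        if mag < hi:
            return f"{label} {sign}"
    return f"very strong {sign}"


def residual_moran(
    fit_result: GTWRFit,
    W: SpatialWeightMatrix,
    by_year: bool = False,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, GlobalMoranResult]:
    """Global Moran's I of the fit residuals.

    Pooled mode averages each region's residuals across years before the
    test (one value per region); ``by_year`` adds a test per year.
    """
    df = pd.DataFrame(
        {
            "region_id": fit_result.region_ids,
            "year": fit_result.years,
            "resid": fit_result.residuals,
        }
    )
    order = list(W.ids)
    out: dict[str, GlobalMoranResult] = {}
    pooled = df.groupby("region_id")["resid"].mean().reindex(order).to_numpy()
    out["pooled"] = global_moran(pooled, W, n_perm=n_perm, seed=seed)
    if by_year:
        for year in sorted(set(fit_result.years)):
            x = (
                df[df["year"] == year]
                .set_index("region_id")["resid"]
                .reindex(order)
                .to_numpy()
            )
            out[str(year)] = global_moran(x, W, n_perm=n_perm, seed=seed)
    return out
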