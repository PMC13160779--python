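"""Rate construction and variable scaling.

Outcome counts are converted to incidence rates per ``scale`` population
before modelling, and every model variable is brought to a common scale,
by default the z-score z = (x - mu) / sigma.  A min-max [0, 1] rescaling
is provided as an alternative.  The z-score uses the sample standard
deviation (n - 1 denominator); the convention is recorded on the returned
object so the transform is invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = ["StandardizedVector", "compute_rate", "zscore", "minmax"]


@dataclass(frozen=True)
class StandardizedVector:
    """A z-scored vector together with the location/scale that produced it."""

    values: np.ndarray
    mu: float
    sigma: float
    ddof: int = 1

    def inverse(self) -> np.ndarray:
        """Map the standardized values back to the original scale."""
        return self.values * self.sigma + self.mu


def compute_rate(cases, population, scale: float = 1e4) -> np.ndarray:
    """Incidence rate = scale * cases / population, elementwise.

    Parameters
    ----------
    cases : array-like of nonnegative counts
    population : array-like of positive counts
    scale : positive real, population base of the rate (default per 10,000)
    """
    cases = np.asarray(cases, dtype=float)
    population = np.asarray(population, dtype=float)
    if scale <= 0:
        raise InvalidArgumentError("scale must be positive")
    if np.any(cases < 0):
        raise InvalidArgumentError("case counts must be nonnegative")
    if np.any(population <= 0):
        raise InvalidArgumentError("population must be strictly positive")
    return scale * cases / population


def zscore(x, ddof: int = 1) -> StandardizedVector:
    """Standardize x to mean 0, sd 1.

    Raises :class:`DegenerateInputError` on a constant vector.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 values to standardize")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=ddof))
    if sigma == 0 or not np.isfinite(sigma):
        raise DegenerateInputError("constant vector cannot be z-scored")
    return StandardizedVector(values=(x - mu) / sigma, mu=mu, sigma=sigma, ddof=ddof)


def minmax(x) -> np.ndarray:
    """Rescale x linearly onto [0, 1]; endpoints map to 0 and 1 exactly."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise DegenerateInputError("constant vector cannot be min-max scaled")
    return (x - lo) / (hi - lo)
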