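"""Composite isolation index.

The index contrasts residential against non-residential activity on a log
scale.  With three metric families — mobility M, electricity E, movement
range R — each contributing a residential stream (sign +1) and a
commercial/non-residential stream (sign -1):

    I(t) = ln X_M^R + ln X_E^R + ln X_R^R - ln X_M^C - ln X_E^C - ln X_R^C

Streams arrive as percent change from a pre-crisis baseline and are mapped
to strictly positive levels X = 1 + p/100 before the logarithm, so a
baseline month contributes exactly zero.  A large positive I means the
population is at home (residential activity up, public activity down) —
the signature of a lockdown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidArgumentError
from .synth import COMMERCIAL_STREAMS, RESIDENTIAL_STREAMS, STREAM_NAMES, ComponentSeries

__all__ = [
    "IsolationIndexSeries",
    "to_level",
    "isolation_index",
    "component_consistency",
    "correlate_with_outcome",
    "yearly_mean",
]


@dataclass(frozen=True)
class IsolationIndexSeries:
    months: np.ndarray
    index: np.ndarray
    contributions: pd.DataFrame  # one signed ln-level column per stream

    def __post_init__(self):
        total = self.contributions.sum(axis=1).to_numpy()
        if not np.allclose(total, self.index):
            raise ValueError("index must equal the sum of signed contributions")


def to_level(p) -> np.ndarray:
    """Percent change -> positive level: X = 1 + p/100."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= -100):
        raise InvalidArgumentError("percent change <= -100 has no positive level form")
    return 1.0 + p / 100.0


def isolation_index(components: ComponentSeries) -> IsolationIndexSeries:
    """Evaluate the signed log-level sum at every month."""
    contrib = {}
    for name in STREAM_NAMES:
        sign = 1.0 if name in RESIDENTIAL_STREAMS else -1.0
        contrib[name] = sign * np.log(to_level(components.streams[name]))
    contributions = pd.DataFrame(contrib, index=components.months)
    return IsolationIndexSeries(
        months=np.asarray(components.months),
        index=contributions.sum(axis=1).to_numpy(),
        contributions=contributions,
    )


def component_consistency(components: ComponentSeries) -> pd.DataFrame:
    """Pairwise Pearson correlations of the standardized streams.

    Internal-consistency check: the residential streams should co-move with
    one another and against the commercial streams.
    """
    first = next(iter(components.streams.values()))
    if len(first) < 3:
        raise InvalidArgumentError("need at least 3 time points for correlations")
    for name, v in components.streams.items():
        if np.std(v) == 0:
            raise DegenerateInputError(f"stream {name} is constant")
    df = pd.DataFrame({k: components.streams[k] for k in STREAM_NAMES})
    z = (df - df.mean()) / df.std(ddof=1)
    return z.corr()


def correlate_with_outcome(index, cases) -> tuple[float, float]:
    """Pearson correlation of the monthly index with monthly case counts.

    Returns (r, two-sided p) with p from the t reference distribution on
    n - 2 degrees of freedom.
    """
    index = np.asarray(index, dtype=float)
    cases = np.asarray(cases, dtype=float)
    if len(index) != len(cases) or len(index) < 3:
        raise InvalidArgumentError("series must have equal length >= 3")
    if np.std(index) == 0 or np.std(cases) == 0:
        raise DegenerateInputError("zero-variance input")
    r, p = stats.pearsonr(index, cases)
    return float(r), float(p)


def yearly_mean(series: IsolationIndexSeries, months_per_year: int = 12) -> np.ndarray:
    """Aggregate the monthly index to calendar-year means.

    Used when the island-wide monthly index enters an annual regression as
    a covariate: every region of a given year receives the same value.
    """
    n = len(series.index)
    if n % months_per_year != 0:
        raise InvalidArgumentError("series length must be a whole number of years")
    return series.index.reshape(-1, months_per_year).mean(axis=1)
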