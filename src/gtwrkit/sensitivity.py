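"""Underreporting scenarios and standardized offset calculus.

Police-reported counts understate true incidence.  If the observed outcome
Y represents only a fraction (1 - x) of the underlying volume, the
adjusted outcome is Y(x) = Y / (1 - x).  Refitting any linear smoother
with unchanged weights on c*y multiplies every coefficient by c exactly,
so coefficient signs are necessarily stable and scenario magnitudes equal
baseline / (1 - x); the scenario machinery verifies that the models behave
this way rather than assuming it.

The offset calculus converts fitted local coefficients into an
interpretable scale: a change delta_x in a standardized predictor moves
the modeled outcome by approximately beta * delta_x, so the standardized
shift needed to counterbalance a modeled outcome change dY is
-dY / beta, in SD units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedOffsetError
from .gtwr import GTWRConfig, GTWRFit
from .gtwr import fit as gtwr_fit

__all__ = [
    "ScenarioResult",
    "OffsetRow",
    "adjust_outcome",
    "scenario_analysis",
    "predicted_change",
    "offset_table",
]


@dataclass(frozen=True)
class ScenarioResult:
    x: float
    adjusted_y: np.ndarray
    table: pd.DataFrame  # per predictor: baseline_mean, scenario_mean, pct_same_sign


@dataclass(frozen=True)
class OffsetRow:
    predictor: str
    mean_beta: float
    mean_pred_change: float
    median_offset: float
    p25: float
    p75: float
    n_excluded_zero_beta: int


def adjust_outcome(y, x: float) -> np.ndarray:
    """Scale observed counts up to the assumed underlying volume: y / (1 - x)."""
    if not 0 <= x < 1:
        raise InvalidArgumentError("underreporting fraction must be in [0, 1)")
    return np.asarray(y, dtype=float) / (1.0 - x)


def scenario_analysis(
    X: np.ndarray,
    y,
    coords: np.ndarray,
    times,
    config: GTWRConfig,
    xs=(0.10, 0.25, 0.40),
    names: tuple[str, ...] | None = None,
    region_ids: tuple[str, ...] = (),
) -> tuple[GTWRFit, list[ScenarioResult]]:
    """Baseline fit plus one refit per underreporting fraction.

    Bandwidths are frozen at the baseline values for every scenario (the
    weighting scheme is part of the model specification being stress-tested,
    not a quantity to re-tune per scenario).  Reports, per predictor, the
    baseline and scenario mean local coefficients and the percent of
    observations whose local coefficient keeps its baseline sign.
    """
    for x in xs:
        if not 0 <= x < 1:
            raise InvalidArgumentError(f"underreporting fraction {x} outside [0, 1)")
    baseline = gtwr_fit(X, y, coords, times, config, names=names, region_ids=region_ids)
    results = []
    for x in xs:
        y_adj = adjust_outcome(y, x)
        refit = gtwr_fit(X, y_adj, coords, times, config, names=names, region_ids=region_ids)
        rows = []
        for k, nm in enumerate(baseline.names):
            b0, b1 = baseline.beta[:, k], refit.beta[:, k]
            same = np.sign(b0) == np.sign(b1)
            rows.append(
                {
                    "predictor": nm,
                    "pct_same_sign": 100.0 * float(np.mean(same)),
                    "underreporting": x,
                    "baseline_mean": float(b0.mean()),
                    "scenario_mean": float(b1.mean()),
                }
            )
        results.append(ScenarioResult(x=x, adjusted_y=y_adj, table=pd.DataFrame(rows)))
    return baseline, results


def predicted_change(beta_mean: float, delta_x: float = 0.5) -> float:
    """Modeled outcome change for a delta_x SD shift: beta * delta_x."""
    if not (np.isfinite(beta_mean) and np.isfinite(delta_x)):
        raise InvalidArgumentError("inputs must be finite")
    return beta_mean * delta_x


def offset_table(
    fit_result: GTWRFit,
    delta_x: float = 0.5,
    delta_y_per_predictor: dict[str, float] | None = None,
    include_intercept: bool = False,
) -> list[OffsetRow]:
    """Standardized offsets per predictor from the local coefficients.

    By default the counterbalanced outcome change for predictor k is its
    mean predicted change mean(beta_k) * delta_x; per-region offsets are
    -dY / beta_ik, excluding regions with beta exactly zero, summarized by
    median and quartiles.
    """
    rows = []
    for k, nm in enumerate(fit_result.names):
        if nm == "const" and not include_intercept:
            continue
        b = fit_result.beta[:, k]
        mean_beta = float(b.mean())
        dy = (
            delta_y_per_predictor[nm]
            if delta_y_per_predictor and nm in delta_y_per_predictor
            else predicted_change(mean_beta, delta_x)
        )
        nonzero = b != 0
        if not nonzero.any():
            raise UndefinedOffsetError(f"all local coefficients are zero for {nm}")
        offsets = -dy / b[nonzero]
        p25, med, p75 = np.percentile(offsets, [25, 50, 75])
        rows.append(
            OffsetRow(
                predictor=nm,
                mean_beta=mean_beta,
                mean_pred_change=float(dy),
                median_offset=float(med),
                p25=float(p25),
                p75=float(p75),
                n_excluded_zero_beta=int((~nonzero).sum()),
            )
        )
    return rows
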