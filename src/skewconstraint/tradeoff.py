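"""Trade-off preprocessing: performance-limit lines and deviation scores.

Two-trait display data (e.g. note duration vs gap duration in trilled
song) often show a forbidden region: combinations beyond a limit line do
not occur. The limit is estimated as a low-quantile regression line
(default tau = 0.05, i.e. the line below which ~5% of points fall), and
each observation's performance is summarized as its signed orthogonal
distance from that line — the *deviation score*. Deviations are negative
below the line, so lower values indicate higher performance (closer to or
beyond the estimated limit).

When a grouping label is supplied (repeated measures per individual), the
quantile fit includes fixed per-group intercept offsets, and the returned
line is the population line with the offsets reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._exceptions import DataError

__all__ = ["QuantileLine", "quantile_fit", "orthogonal_deviation"]


@dataclass(frozen=True)
class QuantileLine:
    """A fitted quantile-regression line y = intercept + slope * x."""

    slope: float
    intercept: float
    tau: float
    n: int
    group_offsets: dict[str, float] = field(default_factory=dict)


def quantile_fit(x, y, tau: float = 0.05, group=None) -> QuantileLine:
    """Fit a straight line at quantile ``tau`` by pinball-loss regression.

    Uses iteratively reweighted least squares (statsmodels ``QuantReg``).
    With ``group`` labels, per-group intercept offsets absorb individual
    variation; the population intercept is the mean of the per-group
    intercepts and the offsets are reported relative to it.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    if x.size < 20:
        raise DataError(f"quantile_fit requires n >= 20, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("quantile_fit inputs must be finite")
    if not (0.0 < tau < 1.0):
        raise DataError(f"tau must be in (0, 1), got {tau!r}")
    if np.std(x) == 0:
        raise DataError("x has zero variance; cannot fit a line")

    if group is None:
        X = sm.add_constant(x)
        res = sm.QuantReg(y, X).fit(q=tau)
        intercept, slope = float(res.params[0]), float(res.params[1])
        return QuantileLine(slope=slope, intercept=intercept, tau=tau, n=x.size)

    labels = pd.Series(group).astype(str).to_numpy()
    if labels.size != x.size:
        raise DataError("group labels must match the data length")
    levels = list(pd.unique(labels))
    cols = [np.ones_like(x), x]
    for lev in levels[1:]:
        cols.append((labels == lev).astype(float))
    X = np.column_stack(cols)
    res = sm.QuantReg(y, X).fit(q=tau)
    base = float(res.params[0])
    slope = float(res.params[1])
    effects = {levels[0]: 0.0}
    for lev, b in zip(levels[1:], res.params[2:]):
        effects[lev] = float(b)
    per_group = {lev: base + e for lev, e in effects.items()}
    pop_intercept = float(np.mean(list(per_group.values())))
    offsets = {lev: v - pop_intercept for lev, v in per_group.items()}
    return QuantileLine(
        slope=slope,
        intercept=pop_intercept,
        tau=tau,
        n=x.size,
        group_offsets=offsets,
    )


def orthogonal_deviation(x, y, line: QuantileLine) -> np.ndarray:
    """Signed orthogonal distance of each point from the limit line.

    ``(y - intercept - slope*x) / sqrt(1 + slope^2)``: exactly zero on the
    line, negative below it. For a limit estimated from below (low tau),
    lower deviation means higher performance.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    return (y - line.intercept - line.slope * x) / math.sqrt(1.0 + line.slope**2)
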