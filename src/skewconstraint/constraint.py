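"""Constraint curves: inverted, normalized CDF components.

A fitted skew normal implies a sigmoidal "challenge" profile over the
trait axis. The CDF factor of the density, V_CDF(y) in [0, 2], rises (or
falls, for negative shape) across the trait range; inverting and min-max
normalizing it,

    V_constraint = (max(V_CDF) - V_CDF) / (max(V_CDF) - min(V_CDF)),

yields constraint values in [0, 1] where 1 marks the most constrained end
of the trait axis — always the short-tail side of the distribution, since
the long tail points away from the constraint. The y-value of the curve at
an observed behaviour is that behaviour's *challenge score*.

The extrema are taken over an evaluation grid (default 512 points spanning
the mean +/- 4 SD) rather than over observed data, so curves from
different groups are comparable regardless of each group's observed range.
A symmetric fit (shape exactly 0) has a constant V_CDF and therefore no
defined constraint curve; that is treated as an error rather than a flat
curve, which would assert "no constraint" with false precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._exceptions import DataError, DegenerateConstraintError
from .distribution import SkewNormalParams, cdf_component, direct_to_centered

__all__ = ["ConstraintCurve", "constraint_from_params", "challenge_score"]


@dataclass
class ConstraintCurve:
    """A normalized constraint curve on a trait grid.

    ``grid`` is strictly increasing in trait units; ``constraint`` holds
    V_constraint in [0, 1], attaining both endpoints of that range over the
    grid and monotone (non-increasing for positive shape, non-decreasing
    for negative shape).
    """

    grid: np.ndarray
    constraint: np.ndarray
    params: SkewNormalParams
    grid_halfwidth_sds: float
    label: dict[str, Any] = field(default_factory=dict)

    def midpoint_crossing(self) -> float:
        """Trait value where the curve crosses constraint = 0.5."""
        c, g = self.constraint, self.grid
        if c[0] > c[-1]:  # decreasing curve: flip for interpolation
            c, g = c[::-1], g[::-1]
        return float(np.interp(0.5, c, g))

    def max_abs_slope(self) -> float:
        """Steepness: maximum |dV_constraint/dy| over the grid."""
        return float(np.max(np.abs(np.gradient(self.constraint, self.grid))))


def constraint_from_params(
    params: SkewNormalParams,
    grid_points: int = 512,
    grid_halfwidth_sds: float = 4.0,
) -> ConstraintCurve:
    """Build the constraint curve implied by skew-normal parameters.

    Raises
    ------
    DegenerateConstraintError
        If the shape is exactly 0 (V_CDF constant; normalization divides
        by zero).
    """
    if params.shape == 0.0:
        raise DegenerateConstraintError(
            "shape alpha = 0: the CDF component is constant and the "
            "constraint curve is undefined"
        )
    if grid_points < 16:
        raise DataError(f"grid_points must be >= 16, got {grid_points}")
    if grid_halfwidth_sds <= 0:
        raise DataError(
            f"grid_halfwidth_sds must be positive, got {grid_halfwidth_sds!r}"
        )
    c = direct_to_centered(params)
    grid = np.linspace(
        c.location - grid_halfwidth_sds * c.scale,
        c.location + grid_halfwidth_sds * c.scale,
        grid_points,
    )
    v = cdf_component(grid, params)
    vmax, vmin = float(v.max()), float(v.min())
    constraint = (vmax - v) / (vmax - vmin)
    return ConstraintCurve(
        grid=grid,
        constraint=constraint,
        params=params,
        grid_halfwidth_sds=float(grid_halfwidth_sds),
    )


def challenge_score(y, curve: ConstraintCurve) -> np.ndarray:
    """Challenge of each observation: the constraint curve evaluated at y.

    Linear interpolation on the curve's grid; values outside the grid are
    clamped to the nearer endpoint (with a warning), which is safe because
    the curve has already plateaued there.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if y.size == 0:
        raise DataError("challenge_score requires at least one observation")
    if not np.all(np.isfinite(y)):
        raise DataError("observations must be finite")
    lo, hi = curve.grid[0], curve.grid[-1]
    if np.any(y < lo) or np.any(y > hi):
        warnings.warn(
            "observations outside the curve grid were clamped to the "
            "endpoint constraint values",
            stacklevel=2,
        )
    return np.interp(y, curve.grid, curve.constraint)
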