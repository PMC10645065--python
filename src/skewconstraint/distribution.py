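"""Skew-normal distribution core.

Density, CDF component, sampling, moments, and conversions between the two
standard parameterizations of the skew normal:

* **direct** — location xi, scale omega, shape alpha; the density is
  ``2/omega * phi((y - xi)/omega) * Phi(alpha * (y - xi)/omega)``.
* **centered** — population mean mu, population SD sigma, shape alpha.
  This is the user-facing form throughout the package because fitted
  intercepts are then interpretable as means and SDs.

The two are linked through ``delta = alpha / sqrt(1 + alpha^2)``: the mean
offset of the direct form is ``omega * delta * sqrt(2/pi)`` and its SD is
``omega * sqrt(1 - 2 delta^2 / pi)``.

Population skewness of the skew normal is bounded by ~0.9952717 in absolute
value (the ``delta -> 1`` limit), so the centered form cannot represent a
more skewed shape than that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.special import erf, log_ndtr, ndtr

from ._exceptions import DataError

__all__ = [
    "MAX_SKEWNESS",
    "SkewNormalParams",
    "density",
    "log_density",
    "cdf_component",
    "centered_to_direct",
    "direct_to_centered",
    "skewness_from_alpha",
    "alpha_from_skewness",
    "sample",
]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)

#: Supremum of |population skewness| attainable by a skew normal (delta -> 1).
MAX_SKEWNESS = 0.5 * (4.0 - math.pi) * _SQRT_2_OVER_PI**3 / (1.0 - 2.0 / math.pi) ** 1.5


@dataclass(frozen=True)
class SkewNormalParams:
    """Parameter triple for a univariate skew normal.

    Parameters
    ----------
    location
        xi in the direct form; the population mean mu in the centered form.
    scale
        omega (direct) or the population SD sigma (centered). Must be > 0.
    shape
        alpha, the magnitude and direction of skew. Finite.
    parameterization
        Which convention ``location``/``scale`` follow.
    """

    location: float
    scale: float
    shape: float
    parameterization: Literal["direct", "centered"] = "centered"

    def __post_init__(self) -> None:
        for name in ("location", "scale", "shape"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise DataError(f"{name} must be finite, got {v!r}")
        if self.scale <= 0:
            raise DataError(f"scale must be positive, got {self.scale!r}")
        if self.parameterization not in ("direct", "centered"):
            raise DataError(
                f"parameterization must be 'direct' or 'centered', got "
                f"{self.parameterization!r}"
            )

    @property
    def delta(self) -> float:
        """alpha / sqrt(1 + alpha^2), the correlation in the hidden-truncation
        representation."""
        return self.shape / math.hypot(1.0, self.shape)


def _as_direct(params: SkewNormalParams) -> SkewNormalParams:
    if params.parameterization == "direct":
        return params
    return centered_to_direct(params)


def centered_to_direct(params: SkewNormalParams) -> SkewNormalParams:
    """Convert centered (mean, SD, alpha) to direct (xi, omega, alpha)."""
    if params.parameterization == "centered":
        d = params.delta
        mz = d * _SQRT_2_OVER_PI  # mean of the standardized skew normal
        omega = params.scale / math.sqrt(1.0 - mz * mz)
        xi = params.location - omega * mz
        return SkewNormalParams(xi, omega, params.shape, "direct")
    return params


def direct_to_centered(params: SkewNormalParams) -> SkewNormalParams:
    """Convert direct (xi, omega, alpha) to centered (mean, SD, alpha)."""
    if params.parameterization == "direct":
        d = params.delta
        mz = d * _SQRT_2_OVER_PI
        mu = params.location + params.scale * mz
        sigma = params.scale * math.sqrt(1.0 - mz * mz)
        return SkewNormalParams(mu, sigma, params.shape, "centered")
    return params


def density(y, params: SkewNormalParams):
    """Skew-normal probability density at ``y`` (scalar or array)."""
    return np.exp(log_density(y, params))


def log_density(y, params: SkewNormalParams):
    """Log density; numerically safe deep in the thin tail via ``log_ndtr``."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise DataError("density evaluation points must be finite")
    p = _as_direct(params)
    z = (y - p.location) / p.scale
    return (
        math.log(2.0 / p.scale)
        - 0.5 * math.log(2.0 * math.pi)
        - 0.5 * z * z
        + log_ndtr(p.shape * z)
    )


def cdf(y, params: SkewNormalParams):
    """Cumulative distribution function (Owen's T form via scipy)."""
    from scipy.stats import skewnorm

    p = _as_direct(params)
    return skewnorm.cdf(np.asarray(y, dtype=float), p.shape, loc=p.location, scale=p.scale)


def cdf_component(y, params: SkewNormalParams):
    """The sigmoidal CDF factor of the skew-normal density,
    ``V_CDF(y) = 1 + erf(alpha * (y - xi) / (omega * sqrt(2)))``, in [0, 2].

    This is the ingredient the constraint curve inverts and normalizes:
    monotone increasing in ``y`` for alpha > 0, decreasing for alpha < 0,
    and identically 1 for alpha = 0.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise DataError("cdf_component evaluation points must be finite")
    p = _as_direct(params)
    z = (y - p.location) / p.scale
    return 1.0 + erf(p.shape * z / math.sqrt(2.0))


def skewness_from_alpha(alpha: float) -> float:
    """Closed-form population skewness gamma_1 of a skew normal with shape
    ``alpha``; odd in alpha and bounded by :data:`MAX_SKEWNESS`."""
    if not np.isfinite(alpha):
        raise DataError("alpha must be finite")
    d = alpha / math.hypot(1.0, alpha)
    mz = d * _SQRT_2_OVER_PI
    return 0.5 * (4.0 - math.pi) * mz**3 / (1.0 - mz * mz) ** 1.5


def alpha_from_skewness(gamma1: float) -> float:
    """Shape alpha whose population skewness equals ``gamma1``.

    Closed-form inverse: with ``m = delta * sqrt(2/pi)`` the skewness is
    ``c * (m / sqrt(1 - m^2))^3`` for ``c = (4 - pi)/2``, so the cube root
    unwinds it exactly.

    Raises
    ------
    DataError
        If ``|gamma1|`` meets or exceeds the attainable bound ~0.9953.
    """
    if abs(gamma1) >= MAX_SKEWNESS:
        raise DataError(
            f"|skewness| must be below the skew-normal bound {MAX_SKEWNESS:.6f}, "
            f"got {gamma1!r}"
        )
    if gamma1 == 0.0:
        return 0.0
    c = 0.5 * (4.0 - math.pi)
    t = math.copysign(abs(gamma1 / c) ** (1.0 / 3.0), gamma1)
    m = t / math.sqrt(1.0 + t * t)  # = delta * sqrt(2/pi)
    d = m / _SQRT_2_OVER_PI
    return d / math.sqrt(1.0 - d * d)


def sample(params: SkewNormalParams, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` variates, exactly, via the conditioning representation.

    A bivariate standard-normal pair (u0, u1) with correlation delta is
    generated and u1 is reflected on the sign of u0; the result is a
    standardized skew normal, then shifted and scaled to the direct form.
    """
    if n < 1:
        raise DataError(f"sample size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = _as_direct(params)
    d = p.delta
    u0 = rng.standard_normal(n)
    v = rng.standard_normal(n)
    u1 = d * u0 + math.sqrt(1.0 - d * d) * v
    z = np.where(u0 >= 0.0, u1, -u1)
    return p.location + p.scale * z


def _mean_sd(params: SkewNormalParams) -> tuple[float, float]:
    c = direct_to_centered(params)
    return c.location, c.scale
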