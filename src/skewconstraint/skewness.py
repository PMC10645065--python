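"""Sample skewness (Fisher's moment coefficient) and bootstrap intervals.

Skewness here is the third central moment over the cubed SD, mu_3/sigma^3.
Three finite-sample estimator variants are offered, matching the numbering
used by the R ``e1071`` package:

* type 1 — g1 = m3 / m2^(3/2) with population moments (divide by n);
* type 2 — the bias-adjusted G1 = g1 * sqrt(n(n-1)) / (n-2);
* type 3 — b1 = g1 * ((n-1)/n)^(3/2), the ``e1071`` default and the
  default here.

Uncertainty is quantified by a seeded percentile bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from ._exceptions import DataError

logger = logging.getLogger(__name__)

__all__ = ["SkewnessEstimate", "fisher_skewness", "bootstrap_ci"]


@dataclass(frozen=True)
class SkewnessEstimate:
    """Point estimate of skewness with a percentile-bootstrap interval."""

    value: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int
    level: float
    estimator_type: int = 3

    def __post_init__(self) -> None:
        if self.n_boot > 0 and not (self.ci_low <= self.ci_high):
            raise DataError("bootstrap interval is not ordered")


def _check(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise DataError(f"skewness requires n >= 3, got n = {x.size}")
    if not np.all(np.isfinite(x)):
        raise DataError("skewness input must be finite")
    if np.all(x == x[0]):
        raise DataError("skewness undefined for zero-variance input")
    return x


def fisher_skewness(x, estimator_type: int = 3) -> float:
    """Fisher's moment coefficient of skewness of a sample."""
    x = _check(x)
    n = x.size
    g1 = float(scipy.stats.skew(x, bias=True))
    if estimator_type == 1:
        return g1
    if estimator_type == 2:
        if n < 4:
            raise DataError("type-2 skewness requires n >= 4")
        return g1 * math.sqrt(n * (n - 1)) / (n - 2)
    if estimator_type == 3:
        return g1 * ((n - 1) / n) ** 1.5
    raise DataError(f"estimator_type must be 1, 2 or 3, got {estimator_type!r}")


def bootstrap_ci(
    x,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    estimator_type: int = 3,
) -> SkewnessEstimate:
    """Percentile-bootstrap confidence interval for the sample skewness.

    Resamples of size n with replacement; resamples with zero variance
    (possible for tiny or heavily tied samples) are skipped and counted,
    and more than 10% degenerate resamples is an error.
    """
    x = _check(x)
    if n_boot < 100:
        raise DataError(f"n_boot must be >= 100, got {n_boot}")
    if not (0 < level < 1):
        raise DataError(f"level must be in (0, 1), got {level!r}")
    rng = np.random.default_rng(seed)
    n = x.size
    if estimator_type == 1:
        factor = 1.0
    elif estimator_type == 2:
        if n < 4:
            raise DataError("type-2 skewness requires n >= 4")
        factor = math.sqrt(n * (n - 1)) / (n - 2)
    elif estimator_type == 3:
        factor = ((n - 1) / n) ** 1.5
    else:
        raise DataError(f"estimator_type must be 1, 2 or 3, got {estimator_type!r}")
    chunks = []
    # chunked, vectorized resampling keeps memory bounded at large n
    chunk = max(1, min(n_boot, 2_000_000 // max(n, 1)))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        xb = x[rng.integers(0, n, size=(m, n))]
        xb -= xb.mean(axis=1, keepdims=True)
        d2 = xb * xb
        m2 = d2.mean(axis=1)
        m3 = (d2 * xb).mean(axis=1)
        ok = m2 > 0
        chunks.append(m3[ok] / m2[ok] ** 1.5 * factor)
        done += m
    stats = np.concatenate(chunks)
    kept = stats.size
    dropped = n_boot - kept
    if dropped:
        logger.warning("%d of %d bootstrap resamples were degenerate", dropped, n_boot)
        if dropped > 0.1 * n_boot:
            raise DataError(
                f"{dropped}/{n_boot} bootstrap resamples had zero variance"
            )
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [tail, 1.0 - tail])
    return SkewnessEstimate(
        value=fisher_skewness(x, estimator_type),
        ci_low=float(lo),
        ci_high=float(hi),
        n=n,
        n_boot=kept,
        level=level,
        estimator_type=estimator_type,
    )
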