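"""Synthetic-data generators.

The central generator reproduces the constrained-performance model used to
validate the skew-based approach: raw performance is drawn from a normal
"target" distribution and a one-sided ramp penalty compresses draws above
the target mean,

    b                      if b <= mean
    b / (1 + k*(b - mean)) if b >  mean,

so the upper tail is squashed toward an asymptote at ``mean + 1/k`` and the
resulting distribution skews *away* from the constraint (negative skew for
a constraint on high performance). Two resource conditions provide a
confound: the low-resource condition has target mean 0 and a strong penalty
(k = 0.5); the high-resource condition has target mean 1 and a weak penalty
(k = 0.1). Pooling the conditions masks the per-condition skew, which is
exactly the situation the covariate-dependent skew model is built to
untangle.

Also provided: pure skew-normal samples with group-varying shape (fixtures
for random-intercept models) and two-trait trade-off data with a known
performance-limit line (fixtures for the quantile-regression preprocessor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import DataError
from .distribution import MAX_SKEWNESS, SkewNormalParams, sample, skewness_from_alpha

__all__ = [
    "PenaltyConfig",
    "LOW_RESOURCE",
    "HIGH_RESOURCE",
    "apply_penalty",
    "generate_condition",
    "generate_two_condition_dataset",
    "generate_skewnormal_dataset",
    "generate_hierarchical",
    "generate_tradeoff",
]


@dataclass(frozen=True)
class PenaltyConfig:
    """Target distribution plus ramp-penalty strength for one condition.

    ``penalty_strength`` (k) is the per-unit growth rate of the penalty
    above the target mean; k = 0 disables the constraint entirely.
    """

    target_mean: float
    target_sd: float = 1.0
    penalty_strength: float = 0.5
    label: str = ""

    def __post_init__(self) -> None:
        if self.target_sd <= 0:
            raise DataError(f"target_sd must be positive, got {self.target_sd!r}")
        if self.penalty_strength < 0:
            raise DataError(
                f"penalty_strength must be >= 0, got {self.penalty_strength!r}"
            )


#: The two study conditions: strong constraint / low target vs weak / high.
LOW_RESOURCE = PenaltyConfig(target_mean=0.0, target_sd=1.0, penalty_strength=0.5, label="low")
HIGH_RESOURCE = PenaltyConfig(target_mean=1.0, target_sd=1.0, penalty_strength=0.1, label="high")


def apply_penalty(b, config: PenaltyConfig):
    """One-sided ramp penalty on raw performance ``b``.

    Values at or below the target mean pass through unchanged; values above
    are divided by ``1 + k*(b - mean)``. Continuous at the mean, monotone
    increasing, and bounded above by ``mean + 1/k`` when the mean is
    non-negative and k > 0.
    """
    b = np.asarray(b, dtype=float)
    if not np.all(np.isfinite(b)):
        raise DataError("performance values must be finite")
    k, m = config.penalty_strength, config.target_mean
    out = np.where(b > m, b / (1.0 + k * np.clip(b - m, 0.0, None)), b)
    return out if out.ndim else float(out)


def generate_condition(n: int, config: PenaltyConfig, seed: int | np.random.Generator) -> np.ndarray:
    """``n`` penalized performance draws from one condition."""
    if n < 1:
        raise DataError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = rng.normal(config.target_mean, config.target_sd, size=n)
    return np.asarray(apply_penalty(b, config))


def generate_two_condition_dataset(
    n_per_condition: int = 5000, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """The two-condition constrained-performance dataset.

    Returns a frame with columns ``performance`` (float) and ``resource``
    (ordered categorical, levels ``low`` then ``high`` so that treatment
    coding makes "low" the reference and the fitted contrast is the
    high-vs-low shift).
    """
    if n_per_condition < 10:
        raise DataError(f"n_per_condition must be >= 10, got {n_per_condition}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    low = generate_condition(n_per_condition, LOW_RESOURCE, rng)
    high = generate_condition(n_per_condition, HIGH_RESOURCE, rng)
    return pd.DataFrame(
        {
            "performance": np.concatenate([low, high]),
            "resource": pd.Categorical(
                ["low"] * n_per_condition + ["high"] * n_per_condition,
                categories=["low", "high"],
            ),
        }
    )


def generate_skewnormal_dataset(
    n: int,
    params: SkewNormalParams,
    seed: int | np.random.Generator = 0,
    column: str = "y",
) -> pd.DataFrame:
    """Plain i.i.d. skew-normal draws as a one-column frame."""
    return pd.DataFrame({column: sample(params, n, seed)})


def generate_hierarchical(
    n_groups: int,
    n_per_group: int,
    alpha_mean: float,
    alpha_sd: float,
    mu: float = 0.0,
    sigma: float = 1.0,
    seed: int | np.random.Generator = 0,
    n_subgroups: int = 0,
) -> pd.DataFrame:
    """Grouped skew-normal data with group-varying shape.

    Each group g gets its own shape ``alpha_g ~ N(alpha_mean, alpha_sd^2)``
    and contributes ``n_per_group`` draws from the centered skew normal
    (mu, sigma, alpha_g). With ``n_subgroups > 0`` each group's draws are
    split evenly across nested subgroups (labels only; no extra variance),
    giving a fixture for nested ``(1|g1/g2)`` model terms.

    Columns: ``y``, ``ID`` and, when nested, ``songID``.
    """
    if n_groups < 1 or n_per_group < 1:
        raise DataError("n_groups and n_per_group must be >= 1")
    if alpha_sd < 0:
        raise DataError(f"alpha_sd must be >= 0, got {alpha_sd!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alphas = rng.normal(alpha_mean, alpha_sd, size=n_groups)
    frames = []
    for g, a in enumerate(alphas):
        if abs(skewness_from_alpha(a)) >= MAX_SKEWNESS:
            raise DataError("implied group skewness reaches the skew-normal bound")
        y = sample(SkewNormalParams(mu, sigma, a, "centered"), n_per_group, rng)
        frame = pd.DataFrame({"y": y, "ID": f"g{g + 1:02d}"})
        if n_subgroups > 0:
            frame["songID"] = [
                f"s{(i % n_subgroups) + 1:02d}" for i in range(n_per_group)
            ]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def generate_tradeoff(
    n: int,
    limit_slope: float = -1.0,
    limit_intercept: float = 5.0,
    noise_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Two-trait data bounded below by a known performance-limit line.

    Points sit at ``y = intercept + slope*x + e`` with one-sided
    exponential noise ``e >= 0`` (rate ``1/noise_scale``), emulating a
    trait pair (e.g. note duration vs gap duration) whose joint range is
    forbidden beyond the limit. A low-tau quantile line fitted to the
    output recovers (slope, intercept) approximately.
    """
    if n < 20:
        raise DataError(f"n must be >= 20, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.uniform(0.0, 10.0, size=n)
    e = rng.exponential(noise_scale, size=n)
    y = limit_intercept + limit_slope * x + e
    return pd.DataFrame({"x": x, "y": y})
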