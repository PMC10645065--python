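"""Minimal plotting helpers (histogram with skewness, constraint curves)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .constraint import ConstraintCurve
from .skewness import SkewnessEstimate

__all__ = ["plot_histogram", "plot_constraint_curves"]


def plot_histogram(x, estimate: SkewnessEstimate | None, path) -> None:
    """Histogram of a performance distribution, annotated with skewness."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(np.asarray(x, dtype=float), bins=40, color="0.6", edgecolor="white")
    if estimate is not None:
        ax.set_title(
            f"skewness = {estimate.value:.2f} "
            f"({estimate.level:.0%} CI {estimate.ci_low:.2f}, {estimate.ci_high:.2f})"
        )
    ax.set_xlabel("performance")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_constraint_curves(curves: list[ConstraintCurve], path) -> None:
    """Overlay constraint curves; steeper curves mean stronger constraint."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for c in curves:
        label = ", ".join(f"{k}={v}" for k, v in c.label.items()) or None
        ax.plot(c.grid, c.constraint, label=label)
    ax.set_xlabel("performance")
    ax.set_ylabel("constraint (challenge)")
    ax.set_ylim(-0.02, 1.02)
    if any(c.label for c in curves):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
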