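"""Tabular and JSON I/O for the command-line workflow.

CSV (comma separated, header row, '.' decimal) is the only tabular
dialect. Fit and comparison results are serialized to JSON with enough
metadata (spec, seed, package version) to re-load and re-use them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from ._exceptions import DataError
from .constraint import ConstraintCurve
from .regression import ComparisonResult, FitResult, ModelSpec
from .skewness import SkewnessEstimate
from .tradeoff import QuantileLine

logger = logging.getLogger(__name__)

__all__ = ["read_table", "write_result", "load_fit_result"]


def read_table(
    path,
    response: str | None = None,
    required_columns: tuple[str, ...] = (),
    level_order: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Read a CSV observation table.

    Numeric columns are parsed as floats, everything else as categorical
    text. Rows with a missing response are dropped (with a logged count);
    a declared ``level_order`` turns a text column into an ordered
    categorical, fixing the reference level for treatment coding.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    df = pd.read_csv(path)
    for col in (response, *required_columns):
        if col is not None and col not in df.columns:
            raise DataError(f"column {col!r} not found in {path}")
    if response is not None:
        if not pd.api.types.is_numeric_dtype(df[response]):
            raise DataError(f"response column {response!r} is not numeric")
        n0 = len(df)
        df = df.dropna(subset=[response]).reset_index(drop=True)
        if len(df) < n0:
            logger.warning(
                "dropped %d row(s) with missing response %r", n0 - len(df), response
            )
    for col, order in (level_order or {}).items():
        if col not in df.columns:
            raise DataError(f"level_order references unknown column {col!r}")
        observed = set(df[col].astype(str))
        missing = observed - set(order)
        if missing:
            raise DataError(
                f"level_order for {col!r} is missing observed level(s) "
                f"{sorted(missing)}"
            )
        df[col] = pd.Categorical(df[col].astype(str), categories=order)
    return df


def _package_version() -> str:
    from . import __version__

    return __version__


def _fit_to_dict(result: FitResult, seed: int | None) -> dict[str, Any]:
    return {
        "kind": "fit_result",
        "version": _package_version(),
        "seed": result.seed if seed is None else seed,
        "spec": {
            "response": result.spec.response,
            "mu_formula": result.spec.mu_formula,
            "sigma_formula": result.spec.sigma_formula,
            "alpha_formula": result.spec.alpha_formula,
        },
        "estimates": result.estimates,
        "intervals": {k: list(v) for k, v in result.intervals.items()},
        "loglik": result.loglik,
        "n_obs": result.n_obs,
        "converged": result.converged,
        "level": result.level,
        "param_names": result.param_names,
        "theta": result.theta.tolist(),
        "levels": result.levels,
        "group_level_index": result.group_level_index,
        "n_fixed": result.n_fixed,
    }


def load_fit_result(path) -> FitResult:
    """Re-load a fit result written by :func:`write_result`."""
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    if d.get("kind") != "fit_result":
        raise DataError(f"{path} does not contain a fit result")
    return FitResult(
        spec=ModelSpec(**d["spec"]),
        estimates=d["estimates"],
        intervals={k: (v[0], v[1]) for k, v in d["intervals"].items()},
        loglik=d["loglik"],
        n_obs=d["n_obs"],
        converged=d["converged"],
        level=d["level"],
        seed=d["seed"],
        param_names=d["param_names"],
        theta=np.asarray(d["theta"], dtype=float),
        levels=d["levels"],
        group_level_index=d["group_level_index"],
        n_fixed=d["n_fixed"],
    )


def write_result(result, path, seed: int | None = None) -> None:
    """Serialize a result object.

    Fit, comparison, skewness and quantile-line results go to JSON; data
    frames and constraint curves go to CSV (curves additionally get a JSON
    sidecar with their parameters). The seed is recorded in every output.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, FitResult):
        _dump_json(_fit_to_dict(result, seed), path)
    elif isinstance(result, ComparisonResult):
        _dump_json(
            {
                "kind": "comparison_result",
                "version": _package_version(),
                "seed": seed,
                "elpd_diff": result.elpd_diff,
                "se_diff": result.se_diff,
                "method": result.method,
            },
            path,
        )
    elif isinstance(result, SkewnessEstimate):
        _dump_json(
            {
                "kind": "skewness_estimate",
                "version": _package_version(),
                "seed": seed,
                "value": result.value,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
                "n": result.n,
                "n_boot": result.n_boot,
                "level": result.level,
                "estimator_type": result.estimator_type,
            },
            path,
        )
    elif isinstance(result, QuantileLine):
        _dump_json(
            {
                "kind": "quantile_line",
                "version": _package_version(),
                "seed": seed,
                "slope": result.slope,
                "intercept": result.intercept,
                "tau": result.tau,
                "n": result.n,
                "group_offsets": result.group_offsets,
            },
            path,
        )
    elif isinstance(result, ConstraintCurve):
        pd.DataFrame({"grid": result.grid, "constraint": result.constraint}).to_csv(
            path, index=False
        )
        c = result.params
        _dump_json(
            {
                "kind": "constraint_curve_params",
                "version": _package_version(),
                "seed": seed,
                "location": c.location,
                "scale": c.scale,
                "shape": c.shape,
                "parameterization": c.parameterization,
                "grid_halfwidth_sds": result.grid_halfwidth_sds,
                "label": {k: str(v) for k, v in result.label.items()},
            },
            path.with_suffix(".params.json"),
        )
    elif isinstance(result, pd.DataFrame):
        df = result.copy()
        df.attrs["seed"] = seed
        df.to_csv(path, index=False)
    else:
        raise DataError(f"do not know how to serialize {type(result).__name__}")


def _dump_json(obj: dict[str, Any], path: Path) -> None:
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise DataError(f"cannot write {path}: {exc}") from exc
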