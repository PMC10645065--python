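"""A small model-formula language for the distributional regression.

Grammar (right-hand side of "~" only; the response is named separately):

    rhs      := term ("+" term)*
    term     := "1" | column | "(1|" group ")" | "(1|" group "/" group ")"

* ``1`` is the intercept (always included; listing it is allowed).
* A numeric column enters as-is; a categorical column expands to
  treatment-coded indicators against its declared first level (declared
  category order if the column is a pandas Categorical, otherwise order of
  first appearance).
* ``(1|g)`` is a random intercept on grouping factor g; the nested form
  ``(1|g1/g2)`` expands to grouping factors g1 and g1:g2.

Interactions, random slopes, and transformations are deliberately out of
scope: every model in the target workflow is additive in a handful of
covariates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import DataError, FormulaError

__all__ = ["ParsedFormula", "parse_formula", "DesignInfo", "build_design"]

_RANDOM_RE = re.compile(r"^\(\s*1\s*\|\s*([A-Za-z_]\w*)\s*(?:/\s*([A-Za-z_]\w*)\s*)?\)$")
_NAME_RE = re.compile(r"^[A-Za-z_]\w*$")


@dataclass(frozen=True)
class ParsedFormula:
    """Fixed terms (column names, in order) and grouping factors.

    A grouping factor is a tuple of column names: ``("g",)`` for a plain
    random intercept, ``("g1", "g2")`` for the nested level g1:g2.
    """

    fixed: tuple[str, ...]
    groups: tuple[tuple[str, ...], ...]
    text: str


def parse_formula(text: str) -> ParsedFormula:
    """Parse a formula string such as ``"~ time + (1|birdID/songID)"``."""
    if not isinstance(text, str):
        raise FormulaError(f"formula must be a string, got {type(text).__name__}")
    body = text.strip()
    if body.startswith("~"):
        body = body[1:]
    if "~" in body:
        raise FormulaError(f"unexpected '~' in formula {text!r}")
    fixed: list[str] = []
    groups: list[tuple[str, ...]] = []
    terms = [t.strip() for t in _split_terms(body)]
    for term in terms:
        if not term:
            raise FormulaError(f"empty term in formula {text!r}")
        if term == "1":
            continue
        m = _RANDOM_RE.match(term)
        if m:
            g1, g2 = m.group(1), m.group(2)
            if g2 is None:
                groups.append((g1,))
            else:
                groups.append((g1,))
                groups.append((g1, g2))
            continue
        if term.startswith("("):
            raise FormulaError(
                f"unsupported random term {term!r}: only '(1|g)' and "
                f"'(1|g1/g2)' intercepts are allowed"
            )
        if not _NAME_RE.match(term):
            raise FormulaError(f"cannot parse term {term!r} in formula {text!r}")
        fixed.append(term)
    # drop duplicate grouping factors while keeping order
    seen: set[tuple[str, ...]] = set()
    uniq = [g for g in groups if not (g in seen or seen.add(g))]
    return ParsedFormula(tuple(fixed), tuple(uniq), text)


def _split_terms(body: str) -> list[str]:
    """Split on '+' at depth zero so '(1|a/b)' survives intact."""
    out, depth, cur = [], 0, []
    for ch in body:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormulaError(f"unbalanced parentheses in {body!r}")
        if ch == "+" and depth == 0:
            out.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise FormulaError(f"unbalanced parentheses in {body!r}")
    out.append("".join(cur))
    return out if body.strip() else []


@dataclass
class DesignInfo:
    """A realized design: fixed-effect matrix plus random-intercept codes.

    ``levels`` records the treatment-coding contract per categorical column
    (first level = reference) so that prediction frames are coded
    identically; ``group_levels`` does the same for grouping factors.
    """

    formula: ParsedFormula
    columns: list[str]
    X: np.ndarray
    levels: dict[str, list[str]] = field(default_factory=dict)
    group_names: list[str] = field(default_factory=list)
    group_codes: list[np.ndarray] = field(default_factory=list)
    group_levels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]


def _category_order(s: pd.Series) -> list[str]:
    if isinstance(s.dtype, pd.CategoricalDtype):
        return [str(c) for c in s.cat.categories]
    return [str(v) for v in pd.unique(s.astype(str))]


def build_design(
    data: pd.DataFrame,
    formula: ParsedFormula,
    *,
    levels: dict[str, list[str]] | None = None,
    group_levels: dict[str, list[str]] | None = None,
    allow_new_group_levels: bool = False,
) -> DesignInfo:
    """Build the fixed design matrix and grouping codes for ``formula``.

    When ``levels``/``group_levels`` are given (prediction on new data),
    the stored coding is enforced: an unseen fixed-covariate level is an
    error; an unseen group level is an error unless
    ``allow_new_group_levels`` (code -1, meaning "population level").
    """
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    out_levels: dict[str, list[str]] = {}
    for term in formula.fixed:
        if term not in data.columns:
            raise FormulaError(f"formula references unknown column {term!r}")
        s = data[term]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            vals = s.to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise DataError(f"non-finite values in covariate {term!r}")
            cols.append(vals)
            names.append(term)
        else:
            order = (levels or {}).get(term) or _category_order(s)
            sval = s.astype(str)
            unknown = set(sval.unique()) - set(order)
            if unknown:
                raise DataError(
                    f"unknown level(s) {sorted(unknown)} for covariate {term!r}"
                )
            out_levels[term] = list(order)
            for lev in order[1:]:
                cols.append((sval == lev).to_numpy(dtype=float))
                names.append(f"{term}_{lev}")
    X = np.column_stack(cols) if cols else np.empty((n, 0))

    g_names: list[str] = []
    g_codes: list[np.ndarray] = []
    out_glevels: dict[str, list[str]] = {}
    for gspec in formula.groups:
        for col in gspec:
            if col not in data.columns:
                raise FormulaError(f"formula references unknown grouping column {col!r}")
        name = ":".join(gspec)
        lab = data[gspec[0]].astype(str)
        for col in gspec[1:]:
            lab = lab + ":" + data[col].astype(str)
        order = (group_levels or {}).get(name)
        if order is None:
            order = [str(v) for v in pd.unique(lab)]
        index = {lev: i for i, lev in enumerate(order)}
        codes = np.empty(n, dtype=int)
        for i, v in enumerate(lab):
            if v in index:
                codes[i] = index[v]
            elif allow_new_group_levels:
                codes[i] = -1
            else:
                raise DataError(f"unknown level {v!r} for grouping factor {name!r}")
        g_names.append(name)
        g_codes.append(codes)
        out_glevels[name] = list(order)
    return DesignInfo(
        formula=formula,
        columns=names,
        X=X,
        levels=out_levels,
        group_names=g_names,
        group_codes=g_codes,
        group_levels=out_glevels,
    )
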