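"""Exception hierarchy used across the package.

The CLI maps these onto distinct exit codes, so library code should raise
the most specific class that applies.
"""


class SkewConstraintError(Exception):
    """Base class for all package errors."""


class DataError(SkewConstraintError):
    """Invalid, missing, or degenerate input data."""


class FormulaError(SkewConstraintError):
    """Malformed model formula."""


class ConvergenceError(SkewConstraintError):
    """An optimizer failed to converge."""


class DegenerateConstraintError(SkewConstraintError):
    """Constraint curve requested for a symmetric (alpha = 0) distribution,
    where the inverted-CDF normalization divides by zero."""
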