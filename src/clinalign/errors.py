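"""Exception types raised across the package.

Every error deliberately raised by clinalign derives from
:class:`ClinalignError`, so callers can catch package failures without
swallowing programming errors.
"""


class ClinalignError(Exception):
    """Base class for all clinalign errors."""


class ConfigError(ClinalignError, ValueError):
    """An invalid configuration value or infeasible parameter combination."""


class FormatError(ClinalignError, ValueError):
    """A malformed input file (bad header, wrong column arity, ...).

    Attributes
    ----------
    line : int or None
        1-based line number of the offending line, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UnknownCodeError(ClinalignError, KeyError):
    """A code was looked up that is not in the vocabulary."""


class AlignmentError(ClinalignError, ValueError):
    """Procrustes fitting or transform application failed (shape mismatch,
    degenerate anchors, empty candidate pool, ...)."""


class EvaluationError(ClinalignError, ValueError):
    """An evaluation is undefined (e.g. AUC with no positives or negatives,
    similarity over an empty group set, zero-norm query vector)."""
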