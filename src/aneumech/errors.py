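"""Exception hierarchy shared across the package."""

from __future__ import annotations


class AneumechError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AneumechError):
    """Input file does not have the expected structure (e.g. missing column)."""


class ParseError(AneumechError):
    """A cell could not be parsed; carries the offending file line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class EmptyCurveError(AneumechError):
    """All rows of a record were dropped during preprocessing."""


class DomainError(AneumechError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class ValidationError(AneumechError, ValueError):
    """One or more fields of a configuration/record are invalid."""

    def __init__(self, message: str, fields: list[str] | None = None):
        self.fields = list(fields or [])
        if self.fields:
            message = f"{message}: {', '.join(self.fields)}"
        super().__init__(message)


class InfeasibleError(AneumechError):
    """The constraint set of a fit admits no solution."""


class UndefinedNormalizationError(AneumechError, ZeroDivisionError):
    """NRMSE normalization is undefined (mean of observations is zero)."""
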