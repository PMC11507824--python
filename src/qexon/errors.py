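"""Exception hierarchy shared across the package."""


class QexonError(Exception):
    """Base class for all package errors."""


class ParseError(QexonError):
    """Malformed annotation input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyInputError(QexonError):
    """No usable records after parsing/filtering."""


class ValidationError(QexonError):
    """A value or parameter set violates a documented invariant."""


class ValidityError(ValidationError):
    """Distribution parameters violate normalizability/support constraints."""


class DegenerateSeriesError(QexonError):
    """Series has zero variance or is otherwise unusable for the operation."""


class WindowError(QexonError):
    """Window size incompatible with the series length."""


class SkipWindow(QexonError):
    """Signal: this window is degenerate and must be excluded (not fatal)."""


class InsufficientDataError(QexonError):
    """Too few observations for a stable fit."""


class FitFailureError(QexonError):
    """No optimization start converged; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class EvidenceError(QexonError):
    """Nested-sampling run failed to produce a usable evidence estimate."""
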