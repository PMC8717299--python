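"""Exception hierarchy for the ugof package."""


class UgofError(Exception):
    """Base class for all package-specific errors."""


class ParseError(UgofError):
    """A text input could not be parsed; carries the offending location."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(UgofError):
    """An onset sequence violates its invariants (e.g. duplicate times)."""


class InsufficientDataError(UgofError):
    """Too few onsets/intervals for the requested operation."""


class BinCollisionError(UgofError):
    """Two onsets mapped to the same sample during binarization."""


class DegenerateDistributionError(UgofError):
    """A ugof distribution with zero spread cannot yield z-scores."""
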