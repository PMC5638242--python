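"""Exception hierarchy for polyflow."""


class PolyflowError(Exception):
    """Base class for all polyflow errors."""


class ConfigurationError(PolyflowError):
    """Invalid scenario or pipeline configuration."""


class SizingError(PolyflowError):
    """A graph or universe is too small to host the requested structure."""


class InsufficientDataError(PolyflowError):
    """Too few data points for a model fit."""


class InputError(PolyflowError):
    """Malformed numeric input (e.g. non-positive edge confidence)."""


class ParseError(PolyflowError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SolverError(PolyflowError):
    """The linear program could not be solved."""


class ValidationError(PolyflowError):
    """Pipeline input validation failed."""
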