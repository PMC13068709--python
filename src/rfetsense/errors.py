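"""Exception hierarchy for rfetsense."""


class RfetSenseError(Exception):
    """Base class for all package errors."""


class DomainError(RfetSenseError, ValueError):
    """An argument lies outside the physical domain of an operation."""


class ValidationError(RfetSenseError, ValueError):
    """A structured input violates its invariants."""


class BracketError(RfetSenseError, ValueError):
    """A curve does not bracket the level requested for read-off."""


class ParseError(RfetSenseError, ValueError):
    """A text input could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyInputError(RfetSenseError, ValueError):
    """An input that must be non-empty was empty."""


class ConvergenceError(RfetSenseError, RuntimeError):
    """The nonlinear device solve failed to converge."""

    def __init__(self, message: str, residual: float | None = None,
                 trace: list | None = None):
        self.residual = residual
        self.trace = trace or []
        super().__init__(message)


class ConfigurationError(RfetSenseError, ValueError):
    """A device or run configuration is inconsistent."""


class NotApplicableError(RfetSenseError, ValueError):
    """The requested quantity is undefined in the current mode."""


class ExtrapolationError(RfetSenseError, ValueError):
    """A requested point lies outside the tabulated range."""


class InversionError(RfetSenseError, ValueError):
    """A curve is not monotone and cannot be inverted."""
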