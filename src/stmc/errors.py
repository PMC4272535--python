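"""Exception hierarchy shared across the package."""


class StmcError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(StmcError, ValueError):
    """A configuration or function parameter is outside its admissible range."""


class StmlParseError(StmcError):
    """The STML file is not well-formed XML or misses required structure."""


class StmlValidationError(StmcError):
    """An STML document violates a structural or range constraint.

    The message names the offending element and the constraint.
    """


class PblstlSyntaxError(StmcError):
    """Syntax error while parsing a PBLSTL specification (carries position)."""

    def __init__(self, message, line=None, column=None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"line {line}, column {column}: {message}"
        super().__init__(message)


class PblstlSemanticError(StmcError):
    """Well-formed but semantically invalid specification (e.g. theta not in (0,1))."""


class TraceTooShortError(StmcError):
    """A temporal window or next-state reference extends beyond the trace end."""


class ProviderExhaustedError(StmcError):
    """The trace provider has no further traces to offer."""


class ProviderError(StmcError):
    """The external trace-generator script failed."""


class UndecidableError(StmcError):
    """No observations are available, so no verdict can be produced."""
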