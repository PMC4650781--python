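"""Exception hierarchy shared across the package."""


class BraggmapError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BraggmapError, ValueError):
    """An argument violates a documented precondition."""


class UnreachableTargetError(BraggmapError, ValueError):
    """A requested depth or LET lies beyond the beam's range."""


class NoSignalError(BraggmapError, ValueError):
    """An event stream carries no energy deposition to score."""


class InsufficientDataError(BraggmapError, ValueError):
    """Too few observations for the requested estimate."""


class FitFailureError(BraggmapError, RuntimeError):
    """Nonlinear regression failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(BraggmapError, ValueError):
    """A CSV or config file does not conform to the documented dialect."""
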