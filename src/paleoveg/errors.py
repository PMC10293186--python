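"""Exception hierarchy shared across the package."""


class PaleovegError(Exception):
    """Base class for package-specific errors."""


class InvalidSpecError(PaleovegError, ValueError):
    """A landscape or model specification violates its invariants."""


class EmptyExtentError(PaleovegError, ValueError):
    """A vegetation-unit extent overlaps zero grid cells."""


class OffGridError(PaleovegError, ValueError):
    """A coordinate falls outside the grid."""


class GeometryMismatchError(PaleovegError, ValueError):
    """Two gridded objects do not share the same geometry."""


class ConvergenceError(PaleovegError, RuntimeError):
    """The model solver stopped before reaching its tolerance.

    Carries solver diagnostics in ``details``.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class AlreadyCorrectedError(PaleovegError, ValueError):
    """A CO2 correction was applied twice to the same surface."""
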