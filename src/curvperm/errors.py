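"""Exception hierarchy.

All package errors derive from :class:`CurvpermError` so callers (and the
command-line layer, which maps them to exit status 2) can distinguish
validation problems from genuine bugs.
"""


class CurvpermError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CurvpermError, ValueError):
    """Invalid argument or inconsistent input data."""


class DomainError(ValidationError):
    """A coordinate or grid lies outside the model's spatial domain."""


class ConvergenceError(CurvpermError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class GapError(CurvpermError, ValueError):
    """An operation ran into undefined (unsampled) bins it cannot cross."""


class PipelineError(CurvpermError, RuntimeError):
    """A multi-stage computation failed (e.g. too many bootstrap failures)."""
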