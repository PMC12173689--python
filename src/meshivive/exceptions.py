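"""Exception hierarchy for meshivive.

All library errors derive from :class:`MeshIviveError` so callers can catch
one base class; domain/validation errors also derive from ``ValueError`` so
they behave sensibly in generic code.
"""


class MeshIviveError(Exception):
    """Base class for all meshivive errors."""


class DomainError(MeshIviveError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InsufficientDataError(DomainError):
    """Too few observations to perform a fit."""


class ValidationError(MeshIviveError, ValueError):
    """A file, table or configuration failed schema validation."""


class FitConvergenceError(MeshIviveError, RuntimeError):
    """An optimiser failed to converge; carries the last iterate when known."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class IntegrationError(MeshIviveError, RuntimeError):
    """The ODE solver failed; message carries solver diagnostics."""


class IdentifiabilityError(MeshIviveError, ValueError):
    """The requested free parameters cannot be identified from the data."""
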