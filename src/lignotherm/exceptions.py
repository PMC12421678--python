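"""Exception hierarchy for lignotherm.

All package-specific failures derive from :class:`LignothermError` so callers
can catch broadly; subclasses distinguish data problems from fit failures.
"""


class LignothermError(Exception):
    """Base class for all lignotherm errors."""


class DomainError(LignothermError, ValueError):
    """An input value lies outside the mathematically admissible domain."""


class StructuralIntegrityError(LignothermError):
    """A chain graph violates a structural invariant (e.g. disconnected)."""


class ConfigurationError(LignothermError):
    """A required configuration entry (e.g. a monomer mass) is missing."""


class FitFailureError(LignothermError):
    """A nonlinear fit failed to converge after all restarts."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateFitError(LignothermError):
    """A fit is too degenerate to support the requested derived quantity."""


class NoCrossoverError(LignothermError):
    """Two fitted lines are (near-)parallel: no crossover temperature."""


class NoOnsetError(LignothermError):
    """Deviation never exceeds the onset threshold within the scanned span."""


class DataError(LignothermError):
    """Input data violate a physical precondition (e.g. wrapped coordinates)."""
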