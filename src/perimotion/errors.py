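"""Exception hierarchy shared across the package."""


class PerimotionError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PerimotionError, ValueError):
    """A physical parameter is outside its admissible range."""


class InvalidGeometryError(InvalidParameterError):
    """A geometric quantity (gap, diameter, channel dimension) is inadmissible."""


class ContactSingularityError(InvalidParameterError):
    """Normal-motion amplitude reaches or exceeds the mean film thickness."""


class SolverFailureError(PerimotionError, RuntimeError):
    """The time-stepping solver produced a non-finite field."""

    def __init__(self, message: str, step: int | None = None,
                 diagnostic: float | None = None) -> None:
        super().__init__(message)
        self.step = step
        self.diagnostic = diagnostic


class EstimationFailureError(PerimotionError, RuntimeError):
    """Parameter recovery cannot proceed (degenerate or non-finite data)."""


class NonIdentifiableError(PerimotionError, ValueError):
    """Requested joint fit is structurally non-identifiable."""


class ConfigError(PerimotionError, ValueError):
    """Configuration file failed validation."""
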