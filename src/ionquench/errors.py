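"""Exception hierarchy."""


class IonquenchError(Exception):
    """Base class for all package errors."""


class DomainError(IonquenchError, ValueError):
    """Input outside the validity domain of a formula."""


class ConfigurationError(IonquenchError, ValueError):
    """Inconsistent or incomplete configuration."""


class CalibrationError(IonquenchError, ValueError):
    """Missing or unusable calibration point."""


class AlignmentError(IonquenchError, ValueError):
    """Depth axes of two inputs cannot be aligned."""


class FittingError(IonquenchError, RuntimeError):
    """Nonlinear fit failed to converge."""
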