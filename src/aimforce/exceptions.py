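"""Exception hierarchy shared across the package."""


class AimforceError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AimforceError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(AimforceError, ValueError):
    """Inputs are structurally invalid (wrong shape, too few points, bad metadata)."""


class FitError(AimforceError, RuntimeError):
    """A nonlinear or linear fit failed; carries diagnostics in ``args``."""


class MeasurementError(AimforceError, RuntimeError):
    """A trace-derived quantity could not be measured (e.g. force never re-established)."""
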