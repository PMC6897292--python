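"""Exception hierarchy used across the package."""


class DinchPbpkError(Exception):
    """Base class for package errors."""


class InputError(DinchPbpkError, ValueError):
    """Invalid user-supplied value (negative concentration, bad bounds, ...)."""


class FitError(DinchPbpkError, RuntimeError):
    """A curve fit failed or the data do not support the assumed model."""


class DegenerateCorrectionError(FitError):
    """The non-specific-binding line crosses zero inside the observed time range."""


class InfeasibleParameterError(DinchPbpkError, ValueError):
    """Mass-balance closure left a non-positive residual volume or blood flow."""


class IntegrationError(DinchPbpkError, RuntimeError):
    """The kinetic simulation failed (solver breakdown, negative state)."""


class ConfigError(DinchPbpkError, ValueError):
    """A configuration file failed validation."""
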