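"""Exception hierarchy shared across the package."""


class NotetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NotetError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive half-life)."""


class IntegrationError(NotetError, RuntimeError):
    """The ODE solver failed to converge or produced a non-physical state."""


class FitError(NotetError, RuntimeError):
    """Non-linear least squares failed or the model is unidentifiable."""


class SchemaError(NotetError, ValueError):
    """An input table is missing required columns or is empty."""


class InsufficientDataError(NotetError, ValueError):
    """Too few observations to run the requested statistic."""
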