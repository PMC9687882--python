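"""Exception hierarchy for the panfat pipeline."""


class PanfatError(Exception):
    """Base class for all panfat-specific errors."""


class InvalidInputError(PanfatError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedMetricError(PanfatError, ValueError):
    """A quality metric is undefined for the given inputs (e.g. empty mask)."""


class InvalidConfigError(PanfatError, ValueError):
    """A configuration object is internally inconsistent."""


class ConfigurationError(PanfatError):
    """A pipeline stage is missing required configuration (e.g. calibration)."""


class DependencyError(PanfatError):
    """A pipeline stage was requested before its upstream artifacts exist."""


class FormatError(PanfatError, IOError):
    """A file could not be read in the expected image format."""


class FitError(PanfatError, ValueError):
    """A model fit failed on degenerate data."""
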