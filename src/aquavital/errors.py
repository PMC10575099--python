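"""Exception hierarchy shared across the package."""


class AquavitalError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AquavitalError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(AquavitalError):
    """A malformed input file; the message carries the line number when known."""


class CalibrationError(AquavitalError):
    """Nonpositive reference magnitude or resistance."""


class DegenerateSweepError(AquavitalError):
    """Both the real and imaginary sweep components are zero."""


class InsufficientDataError(AquavitalError):
    """A series is too short for the requested operation."""


class ExtrapolationError(AquavitalError):
    """A query time falls outside the checkpoint range."""


class UndefinedStatisticError(AquavitalError):
    """A statistic (MIC, MAPE, ...) is undefined for the given input."""


class FitError(AquavitalError):
    """An envelope or model fit could not be completed."""


class TrainingError(AquavitalError):
    """Model training diverged (NaN loss); the message echoes the config."""


class PipelineError(AquavitalError):
    """A pipeline stage failed; the message names the stage."""
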