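"""Exception hierarchy shared across the pipeline stages."""


class NucleomorphError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NucleomorphError):
    """Unknown preset / invalid configuration value."""


class PlacementError(NucleomorphError):
    """Chromocenter placement failed after bounded retries."""


class FormatError(NucleomorphError):
    """Unreadable or unsupported image file / channel."""


class EmptySegmentationError(NucleomorphError):
    """No foreground object found above threshold."""


class MeasurementError(NucleomorphError):
    """Morphometric measurement on a degenerate input (e.g. empty mask)."""


class CalibrationError(NucleomorphError):
    """Ploidy calibration without anchor records."""


class InsufficientDataError(NucleomorphError):
    """Group comparison with degenerate group sizes."""


class MissingArtifactError(NucleomorphError):
    """A pipeline stage's required upstream artifact does not exist."""
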