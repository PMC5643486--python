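"""Exception hierarchy shared across the package."""


class FadynError(Exception):
    """Base class for all package errors."""


class FormatError(FadynError):
    """A file or in-memory object violates the expected format."""


class ParameterError(FadynError, ValueError):
    """A model or configuration parameter is out of its valid range."""


class ConfigError(FadynError):
    """An analysis or scene configuration is internally inconsistent."""


class WindowError(FadynError):
    """A time window (baseline, plateau) is invalid for the given recording."""


class NoPeakError(FadynError):
    """A pixel time course has no detectable transit peak above baseline noise."""


class InsufficientDataError(FadynError):
    """Too few samples (animals, pixels) for the requested statistic."""


class EmptyInputError(FadynError, ValueError):
    """An operation received an empty value sequence."""


class SegmentationError(FadynError):
    """Vessel segmentation produced no usable foreground."""


class ClassificationError(FadynError):
    """Fill-timing classification is degenerate (no separable clusters)."""


class RegistrationError(FadynError):
    """Frame alignment failed in a way that cannot be flagged per frame."""
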