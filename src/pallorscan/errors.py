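"""Exception hierarchy.

Every stage raises a subclass of :class:`PallorscanError` so that pipeline
drivers can tag failures with the stage that produced them.
"""


class PallorscanError(Exception):
    """Base class for all pallorscan errors."""


class ImageFormatError(PallorscanError):
    """File exists but is not a decodable image, or has the wrong layout."""


class ConfigError(PallorscanError):
    """Invalid configuration value (unknown preset, empty preset list, ...)."""


class DetectionError(PallorscanError):
    """ROI detection found no candidate conjunctiva pixels."""


class BoundsError(PallorscanError):
    """A bounding box does not lie within its image."""


class MaskAlignmentError(PallorscanError):
    """A mask's dimensions do not match its image."""


class EmptyRegionError(PallorscanError):
    """A feature was requested on a region with zero pixels."""


class RegionTooSmallError(PallorscanError):
    """Segmented region is below the configured minimum pixel count."""


class DegenerateChannelError(PallorscanError):
    """A channel mean is (near) zero where a ratio requires it positive."""


class ValidationError(PallorscanError):
    """Invalid domain value (implausible Hb, mismatched label sequences...)."""


class TrainingError(PallorscanError):
    """Classifier training preconditions violated (e.g. a class is absent)."""


class ModelStateError(PallorscanError):
    """Prediction requested from an untrained or corrupt model."""
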