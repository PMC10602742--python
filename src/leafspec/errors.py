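"""Exception hierarchy shared across the pipeline."""


class LeafspecError(Exception):
    """Base class for all package errors."""


class StructuralError(LeafspecError):
    """Shape / wavelength-axis / metadata mismatch between objects."""


class CalibrationError(LeafspecError):
    """Reflectance calibration cannot proceed (e.g. degenerate references)."""


class RangeError(LeafspecError):
    """A wavelength range selects no bands."""


class FormatError(LeafspecError):
    """A file does not conform to its declared on-disk format."""


class SegmentationError(LeafspecError):
    """Leaf/background segmentation failed (constant image, empty mask)."""


class PreprocessError(LeafspecError):
    """A spectral pretreatment failed for one or more samples."""


class ConfigError(LeafspecError):
    """Invalid parameter combination."""


class ModelError(LeafspecError):
    """Model fitting failed (zero-variance target, singular system)."""
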