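"""Exception hierarchy shared across the pipeline stages."""


class HsimeatError(Exception):
    """Base class for all package errors."""


class InvalidGridError(HsimeatError, ValueError):
    """Wavelength vector is not strictly increasing or lies outside the sensor range."""


class GeometryError(HsimeatError, ValueError):
    """Synthetic scene geometry does not fit the image frame."""


class ConfigError(HsimeatError, ValueError):
    """Inconsistent or out-of-vocabulary configuration."""


class FormatError(HsimeatError, ValueError):
    """Malformed ENVI header or data file."""


class DimensionError(HsimeatError, ValueError):
    """Array shapes or band counts do not match."""


class EmptySelectionError(HsimeatError, ValueError):
    """A spectral trim retained no bands."""


class EmptyROIError(HsimeatError, ValueError):
    """Segmentation produced an empty foreground; signals a failed mask, never a silent zero."""


class DegenerateSpectrumError(HsimeatError, ValueError):
    """A per-spectrum transform is undefined (constant spectrum)."""


class RankError(HsimeatError, ValueError):
    """Requested more components than the data rank supports."""


class DegenerateClassesError(HsimeatError, ValueError):
    """Classifier fit requires at least two classes."""


class CompatibilityError(HsimeatError, ValueError):
    """Model and wavelength subset disagree on the bands they cover."""


class LegendError(HsimeatError, KeyError):
    """A class map contains a label missing from the legend."""


class UndefinedMetricWarning(UserWarning):
    """A metric is undefined for the given confusion matrix stratum; NaN is returned."""
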