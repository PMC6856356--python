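"""Exception hierarchy."""


class WoundtrackError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(WoundtrackError, ValueError):
    """Invalid parameter value (geometry does not fit, negative rate, ...)."""


class SegmentationFailure(WoundtrackError):
    """Active-contour evolution produced no usable cell region."""


class DegenerateContourError(WoundtrackError):
    """Contour thickness meets or exceeds the mask inradius."""


class PlacementError(WoundtrackError):
    """Could not place the requested number of non-overlapping cells."""


class NormalizationError(WoundtrackError, ZeroDivisionError):
    """Normalization divisor is zero or no reference cells were given."""


class DataError(WoundtrackError, ValueError):
    """Malformed input data (non-monotone time, bad CSV rows, ...)."""


class ConfigError(WoundtrackError, ValueError):
    """Invalid run configuration (unknown keys, missing seed, bad paths)."""
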