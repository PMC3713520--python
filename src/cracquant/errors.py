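"""Exception hierarchy for cracquant."""


class CracQuantError(Exception):
    """Base class for all package errors."""


class UnsupportedImageError(CracQuantError):
    """Raised for images that are not single-plane grayscale TIFF."""


class ChannelAlignmentError(CracQuantError):
    """Raised when channel images of one field of view disagree in shape."""


class MissingChannelError(CracQuantError):
    """Raised when a manifest entry lacks a required channel."""


class TraceParseError(CracQuantError):
    """Raised for malformed trace tables (e.g. non-monotone time)."""


class SpotPlacementError(CracQuantError):
    """Raised when spots cannot be placed under the separation constraint."""


class RatioComputationError(CracQuantError):
    """Raised when too many timepoints have a non-positive F380 denominator."""


class TooFewSamplesError(CracQuantError):
    """Raised when a sliding-window fit has fewer samples than the window."""


class IncompatibleTablesError(CracQuantError):
    """Raised when pooling cluster tables produced with different parameters."""


class GroupCountError(CracQuantError):
    """Raised when a two-group comparison receives != 2 groups."""


class EventOrderError(CracQuantError):
    """Raised when protocol event times are invalid or outside the trace span."""


class ConfigError(CracQuantError):
    """Raised for invalid or incomplete run configurations."""
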