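"""Exception hierarchy shared across the package."""


class WoundTrackError(Exception):
    """Base class for all package errors."""


class InputError(WoundTrackError):
    """Unreadable, empty, or malformed external input."""


class ValidationError(WoundTrackError):
    """A precondition on arguments or data shapes is violated."""


class FitError(WoundTrackError):
    """A model fit is degenerate or cannot be computed."""


class SegmentationError(WoundTrackError):
    """Segmentation produced no usable wound geometry."""
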