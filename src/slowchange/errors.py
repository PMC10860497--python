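"""Exception hierarchy shared across the toolkit."""


class SlowChangeError(Exception):
    """Base class for all errors raised by this package."""


class GeometryError(SlowChangeError):
    """A shape or bounding box does not fit the canvas, or dimensions disagree."""


class StateError(SlowChangeError):
    """A quick-change state label is unknown for its feature."""


class NameParseError(SlowChangeError):
    """A composite filename does not follow the Img#_Color_state... pattern."""


class CompletenessError(SlowChangeError):
    """A composite set is missing one or more (color, state-vector) combinations."""


class AmbiguityError(SlowChangeError):
    """A composite folder holds more than the two color labels a run needs."""


class SchedulingError(SlowChangeError):
    """Quick-change windows cannot be packed into the morph segment."""


class ConsistencyError(SlowChangeError):
    """A schedule, series map and feature list disagree with each other."""


class EncoderError(SlowChangeError):
    """The requested video codec backend is not available."""


class DecodeError(SlowChangeError):
    """A video file is truncated, variable-frame-rate, or otherwise unreadable."""


class NoChangeError(SlowChangeError):
    """Start and end images are identical: no slow-change region can be derived."""


class DegenerateError(SlowChangeError):
    """A statistic is undefined for the given input (zero variance, empty cell...)."""
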