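"""Exception hierarchy for the toolkit.

All domain errors derive from :class:`MicroCtQcError` so callers can catch
one base class; ``ValueError``/``OSError`` semantics are preserved where a
generic handler is more natural.
"""


class MicroCtQcError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(MicroCtQcError, ValueError):
    """An input violates a documented precondition or invariant."""


class ConfigurationError(MicroCtQcError, ValueError):
    """A file format, sidecar, or option is missing or unsupported."""


class GeometryError(MicroCtQcError, ValueError):
    """A requested geometry does not fit inside the phantom or grid."""


class SegmentationError(MicroCtQcError, RuntimeError):
    """Threshold segmentation produced no usable lung mask."""


class ChartOrderError(ValidationError):
    """A control-chart update is out of time order or duplicates a date."""
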