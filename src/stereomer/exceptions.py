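"""Exception hierarchy.

All package errors derive from :class:`StereomerError` so callers can catch
one base class at pipeline boundaries.
"""


class StereomerError(Exception):
    """Base class for all package errors."""


class SchemaError(StereomerError):
    """A structured input file violates the documented schema."""


class RangeError(StereomerError, ValueError):
    """A numeric field is outside its documented range."""


class DegenerateGeometryError(StereomerError):
    """Geometric input is degenerate (collinear fiducials, parallel axes, ...)."""


class SegmentRejected(StereomerError):
    """A recording segment fails a quality precondition (e.g. too short).

    Carries a machine-readable ``reason`` token.
    """

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)


class InsufficientOverlapError(StereomerError):
    """Two depth profiles do not overlap enough to be cross-correlated."""
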