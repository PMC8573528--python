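"""Exception hierarchy for sparsecap.

Every error raised by the library derives from :class:`SparseCapError`, so callers
(and the CLI) can catch one base class.
"""


class SparseCapError(Exception):
    """Base class for all sparsecap errors."""


class MissingMarkerError(SparseCapError):
    """A required marker/electrode label is absent from the input."""


class DegenerateGeometryError(SparseCapError):
    """Marker geometry does not admit the requested construction
    (coincident fiducials, collinear fiducials, coplanar electrode cloud, ...)."""


class OffsetExceedsRadiusError(SparseCapError):
    """A radial stem-offset correction would move a marker past the frame origin."""


class EmptyComparisonError(SparseCapError):
    """Two labelled point sets share too few labels to compare."""


class ConfigError(SparseCapError):
    """Inconsistent or unsupported configuration value."""


class FormatError(SparseCapError):
    """A file could not be parsed; message carries the offending line number."""


class ShortEpochError(SparseCapError):
    """The recorded epoch does not cover the requested analysis window."""


class AllRejectedError(SparseCapError):
    """Artifact rejection removed every epoch (or none were supplied)."""


class ShapeError(SparseCapError):
    """Array arguments have incompatible shapes or channel sets."""
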