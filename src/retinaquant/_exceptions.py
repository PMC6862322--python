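"""Exception hierarchy shared across the pipeline stages."""


class RetinaQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(RetinaQuantError, ValueError):
    """An input value violates a documented precondition or invariant."""


class FormatError(RetinaQuantError, ValueError):
    """An input array/file does not have the expected layout."""


class ExtractionError(RetinaQuantError):
    """Retina extraction produced an empty or unusable mask."""


class GeometryError(RetinaQuantError):
    """A mask or curve does not have the geometry an operation requires."""


class SegmentationError(RetinaQuantError):
    """Layer segmentation could not locate the expected bands."""


class MeasurementError(RetinaQuantError):
    """All measurement sites were rejected; nothing to report."""


class InsufficientDataError(RetinaQuantError, ValueError):
    """Too few observations for the requested statistical procedure."""
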