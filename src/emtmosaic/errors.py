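"""Exception hierarchy shared across the package."""


class EmtMosaicError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(EmtMosaicError):
    """A homography became singular, e.g. the camera center lies on the scene plane."""


class InfinitePointError(EmtMosaicError):
    """A point maps to the line at infinity under a homography."""


class InsufficientDataError(EmtMosaicError):
    """Too few (or degenerate, e.g. collinear) correspondences for an estimate."""


class BrokenChainError(EmtMosaicError):
    """A pairwise link needed to compose a chained mosaic is missing."""

    def __init__(self, gap, message=None):
        self.gap = gap
        super().__init__(message or f"missing pairwise registration for pair {gap}")


class CanvasOverflowError(EmtMosaicError):
    """The mosaic canvas exceeds the configured area cap (a drift diagnostic)."""


class OutOfBoundsError(EmtMosaicError):
    """A rendered frame footprint leaves the source texture."""


class AlignmentError(EmtMosaicError):
    """Frame images and pose measurements cannot be aligned by frame index."""


class SchemaError(EmtMosaicError):
    """A configuration or data file violates its documented schema."""
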