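"""Exception hierarchy.

Every error raised by nodtex derives from :class:`NodtexError` so callers
(and the CLI, which maps them to exit code 2) can catch one type.
"""


class NodtexError(Exception):
    """Base class for all nodtex errors."""


class FormatError(NodtexError):
    """Unsupported or malformed on-disk format."""


class MetadataError(NodtexError):
    """Required volume metadata (e.g. spacing) missing or invalid."""


class ValidationError(NodtexError):
    """Input table or specification fails a structural invariant."""


class CongruenceError(NodtexError):
    """Mask and volume grids do not share a shape."""


class EmptySegmentError(NodtexError):
    """Segmentation refinement discarded every voxel."""

    def __init__(self, message: str, nodule_id: str | None = None):
        super().__init__(message)
        self.nodule_id = nodule_id


class DegenerateMaskError(NodtexError):
    """A mask perturbation produced an empty mask."""


class InsufficientSampleError(NodtexError):
    """Too few observations for the requested statistic."""


class UndefinedMomentError(NodtexError):
    """A standardized moment is undefined (zero variance)."""


class NoPairsError(NodtexError):
    """No valid voxel pair exists for co-occurrence counting."""


class DegenerateModelError(NodtexError):
    """A statistical model cannot be formed (e.g. nothing retained)."""


class DegenerateROCError(NodtexError):
    """ROC analysis on constant marker values."""


class UndefinedICCError(NodtexError):
    """ICC undefined because total variance is zero."""
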