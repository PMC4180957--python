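"""Exception hierarchy shared across the package.

Every error a pipeline stage can raise derives from :class:`ScarflowError`
so the command-line layer can catch one type and report the failing stage.
"""


class ScarflowError(Exception):
    """Base class for all scarflow errors."""


class FormatError(ScarflowError):
    """An on-disk artifact is missing, malformed or not 3D."""


class GridMismatchError(ScarflowError):
    """Two arrays that must share one voxel grid do not."""


class CoRegistrationError(GridMismatchError):
    """Fusion inputs are not on the same grid; this tool never resamples."""


class SizingError(ScarflowError):
    """Requested phantom geometry does not fit the voxel grid."""


class MissingClassError(ScarflowError):
    """A tissue class required for seeding is absent from the label map."""


class SeedingError(ScarflowError):
    """A seed class is absent or has too few voxels to build a histogram."""


class DegenerateInputError(ScarflowError):
    """Input volume carries no usable intensity contrast."""


class SizeError(ScarflowError):
    """Problem too large for an exhaustive computation."""


class EmptySurfaceError(ScarflowError):
    """A surface/mesh operation was asked for an empty mask."""
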