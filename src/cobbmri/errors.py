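"""Exception hierarchy.

Every failure mode that callers are expected to branch on gets its own
class; anything else surfaces as the nearest built-in.
"""


class CobbMriError(Exception):
    """Base class for all package-specific errors."""


class VolumeReadError(CobbMriError):
    """The file could not be read as a labeled volume."""


class OrientationError(CobbMriError):
    """Orientation metadata is missing or too oblique to canonicalize."""


class FormatError(CobbMriError):
    """Voxel data is not integer-labeled."""


class EmptyStructureError(CobbMriError):
    """A requested label has no voxels in the volume."""


class DegenerateStructureError(CobbMriError):
    """Structure too small/thin to mesh."""


class DegenerateFitError(CobbMriError):
    """Point set is too small or collinear for a plane fit."""


class DegenerateDiscError(CobbMriError):
    """One half of a split disc has too few vertices."""

    def __init__(self, message: str, level: str | None = None):
        super().__init__(message)
        self.level = level


class UndefinedAngleError(CobbMriError):
    """Plane normal has no usable projection in the requested view."""


class OrderingError(CobbMriError):
    """Discs cannot be ordered cranio-caudally without ambiguity."""


class NoMeasurementError(CobbMriError):
    """No Cobb candidates available."""


class UnavailableLevelError(CobbMriError):
    """A requested vertebral endplate is not covered by any disc."""

    def __init__(self, message: str, levels: list[str] | None = None):
        super().__init__(message)
        self.levels = levels or []


class SchemeError(CobbMriError):
    """Label scheme violates its invariants."""


class InfeasibleConfigError(CobbMriError):
    """Phantom geometry is self-intersecting for the requested tilts."""


class UnsupportedConfigurationError(CobbMriError):
    """Statistical operation called with an unsupported layout (e.g. even reader count)."""


class ClippedContentWarning(UserWarning):
    """A resampling operation pushed structure voxels outside the field of view."""
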