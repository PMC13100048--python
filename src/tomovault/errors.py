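"""Exception hierarchy for tomovault."""


class TomovaultError(Exception):
    """Base class for all tomovault errors."""


class VolumeIOError(TomovaultError):
    """Malformed, truncated or otherwise unreadable volume file."""


class AnisotropicVoxelError(VolumeIOError):
    """Voxel size differs between axes; only isotropic grids are supported."""


class PoseTableError(TomovaultError):
    """Pose table is missing columns or uses an unknown angle convention."""


class FilterParameterError(TomovaultError):
    """Invalid parameter for a volume filter (cutoff below Nyquist, etc.)."""


class SizingError(TomovaultError):
    """Requested synthetic geometry does not fit the requested grid."""


class PackingError(TomovaultError):
    """Could not place particles with the requested minimum separation."""


class ProfileExtentError(TomovaultError):
    """An intensity profile segment leaves the volume."""


class NoBilayerError(TomovaultError):
    """Fewer than two leaflet minima were found on a profile."""


class DegenerateProfileError(TomovaultError):
    """The two leaflet minima are not separated by a maximum."""


class MeasurementError(TomovaultError):
    """A measurement group produced no valid readouts."""


class EmptySurfaceError(TomovaultError):
    """Marching cubes produced no surface at the requested iso level."""


class LeafletSeparationError(TomovaultError):
    """The segmentation surface could not be split into two leaflets."""


class EmptyThicknessMapError(TomovaultError):
    """No leaflet point pair lies within the pairing distance."""


class DegenerateStatisticsError(TomovaultError):
    """Statistical input is degenerate (empty sample, zero spread, ...)."""
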