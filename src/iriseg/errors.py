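"""Exception hierarchy shared across the package.

Every failure mode a caller is expected to handle gets its own class so
that CLI exit codes and library callers can distinguish usage errors,
I/O problems and numerical/geometric failures.
"""


class IrisegError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(IrisegError):
    """A file exists but is not a readable NIfTI-1 image."""


class NotThreeDimensionalError(VolumeFormatError):
    """The image on disk does not hold a 3D scalar volume."""


class ShapeMismatchError(IrisegError, ValueError):
    """Two grids that must be congruent (shape + spacing) are not."""


class ParameterError(IrisegError, ValueError):
    """A numeric parameter is outside its admissible range."""


class OutOfBoundsError(IrisegError, IndexError):
    """A voxel coordinate falls outside the volume."""


class EmptyInputError(IrisegError, ValueError):
    """An operation received an empty list/mask where data is required."""


class PackingError(IrisegError):
    """Phantom geometry could not be realised within the retry budget."""


class SessionError(IrisegError):
    """An edit-session script is malformed or contains an invalid event."""
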