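"""Exception hierarchy shared across the package."""


class DensedockError(Exception):
    """Base class for all package errors."""


class MapFormatError(DensedockError):
    """A density file is malformed, truncated, or uses an unsupported layout."""


class EmptyModelError(DensedockError):
    """A coordinate file yielded no atoms."""


class PoseInconsistencyError(DensedockError):
    """Poses in one set disagree in atom count or element composition."""

    def __init__(self, message: str, pose_ids=()):
        super().__init__(message)
        self.pose_ids = list(pose_ids)


class CongruenceError(DensedockError):
    """Two voxel grids do not share shape, voxel size and origin."""


class OutOfBoundsError(DensedockError):
    """Atoms fall outside a supplied grid."""

    def __init__(self, message: str, atoms=()):
        super().__init__(message)
        self.atoms = list(atoms)


class CorrespondenceError(DensedockError):
    """Two poses cannot be matched atom-for-atom."""


class ScoreOrientationError(DensedockError):
    """Poses of one engine mix lower-is-better and higher-is-better scores."""


class FitFailureError(DensedockError):
    """A nonlinear fit failed to converge or the data are degenerate."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigurationError(DensedockError):
    """Invalid or incomplete pipeline configuration / inputs."""
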