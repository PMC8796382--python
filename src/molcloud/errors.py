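"""Exception hierarchy.

All library-specific failures derive from :class:`MolCloudError` so callers
can catch a single base class at API boundaries (the CLI does exactly that).
"""


class MolCloudError(Exception):
    """Base class for all molcloud errors."""


class SelectionError(MolCloudError):
    """A selection predicate references unknown metadata columns or is malformed."""


class TransformError(MolCloudError):
    """A rigid transform is invalid (e.g. rotation not proper-orthonormal)."""


class SizeMismatchError(MolCloudError):
    """Two structures/selections that must have equal point counts do not."""


class MassError(MolCloudError):
    """An operation requiring positive total mass got zero/negative mass."""


class PDBError(MolCloudError):
    """Malformed or unusable PDB input/output."""


class ModelMismatchError(PDBError):
    """MODEL blocks of a multi-model PDB disagree in atom count."""


class FieldOverflowError(PDBError):
    """A value does not fit in its fixed-width PDB column."""


class DXError(MolCloudError):
    """Malformed or unsupported OpenDX scalar field."""


class KernelError(MolCloudError):
    """Invalid density-kernel parameters (e.g. voxel size exceeding resolution)."""


class InfeasibleVolumeError(MolCloudError):
    """A mass-implied volume cannot be enclosed by any isovalue of the map."""


class RasterError(MolCloudError):
    """Rasterization step too coarse for the smallest atom radius."""


class EmptyStructureError(MolCloudError):
    """An operation requiring at least one point received an empty structure."""


class BuriedEndpointError(MolCloudError):
    """No accessible lattice node within the snap cutoff of a path endpoint."""


class NoPathError(MolCloudError):
    """Path endpoints lie in disconnected accessible components."""
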