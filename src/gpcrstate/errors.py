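"""Exception hierarchy shared across the package."""


class GPCRStateError(Exception):
    """Base class for all package-specific errors."""


class LabelParseError(GPCRStateError, ValueError):
    """A generic residue label string could not be parsed."""


class MappingError(GPCRStateError, ValueError):
    """A residue-mapping file or table is invalid (e.g. duplicate labels)."""


class UnmappedLabelError(GPCRStateError, KeyError):
    """A generic label is not present in the mapping."""


class MissingResidueError(GPCRStateError, LookupError):
    """A mapped residue does not exist in the structure."""


class DegenerateResidueError(GPCRStateError, ValueError):
    """A residue has no usable atoms for the side-chain center."""


class FeaturizationError(GPCRStateError, ValueError):
    """One or more residue pairs could not be turned into distances."""


class TrajectoryError(GPCRStateError, ValueError):
    """A trajectory cannot satisfy the requested sampling plan."""


class DatasetError(GPCRStateError, ValueError):
    """A labeled frame dataset violates its construction contract."""


class SplitError(GPCRStateError, ValueError):
    """A train/test fold assignment is infeasible or inconsistent."""


class ModelError(GPCRStateError, ValueError):
    """A state model was used inconsistently with how it was trained."""


class BindingSiteError(GPCRStateError, ValueError):
    """A binding-site definition or RMSD computation failed."""
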