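"""Exception hierarchy for the scanbody congruence pipeline."""


class ScanbodyError(Exception):
    """Base class for all package errors."""


class MeshInputError(ScanbodyError):
    """A mesh file could not be read or is not a supported format."""


class EmptyMeshError(ScanbodyError):
    """An operation produced or received a mesh with no valid faces."""


class ParameterError(ScanbodyError, ValueError):
    """A geometric or simulation parameter is infeasible."""


class DegenerateGeometryError(ScanbodyError):
    """A triangle or landmark set is degenerate (zero area / collinear)."""


class IllConditionedRegistrationError(ScanbodyError):
    """The ICP normal equations are rank deficient (e.g. planar source)."""


class InsufficientDataError(ScanbodyError):
    """Too few samples or replicates for the requested statistic."""


class LabelingError(ScanbodyError):
    """The reference mesh does not match the scanbody spec topology."""


class IncompleteBlocksError(ScanbodyError):
    """A blocked design (model x scanbody) has missing cells."""
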