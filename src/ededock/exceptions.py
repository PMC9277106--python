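"""Named error types raised by the pipeline stages."""


class EdedError(Exception):
    """Base class for all ededock errors."""


class StructureParseError(EdedError):
    """The structure or trajectory file could not be parsed."""


class LigandNotFoundError(EdedError):
    """No atom matched the requested ligand residue name."""


class AtomCountMismatchError(EdedError):
    """Topology and trajectory frames disagree on atom count."""


class EmptyTrajectoryError(EdedError):
    """A trajectory with zero frames was supplied."""


class FrameIndexError(EdedError):
    """A requested frame index is outside the trajectory."""


class EmptyPocketError(EdedError):
    """No residue satisfied the pocket contact rule."""


class AlignmentAtomsError(EdedError):
    """Fewer than three usable alignment atoms were found."""


class MissingPocketResidueError(EdedError):
    """A pocket residue is absent from the trajectory topology."""


class ZeroVarianceError(EdedError):
    """All frames are identical; the covariance has no variance to analyse."""


class DimensionMismatchError(EdedError):
    """Feature/score dimensionality does not match the fitted model."""


class ClusterCountError(EdedError):
    """Requested cluster count is invalid for the data."""


class EmptyClusterError(EdedError):
    """K-means produced an empty cluster even after all restarts."""


class ZeroPopulationError(EdedError):
    """A cluster population of zero has no defined free energy."""


class AllScoresMissingError(EdedError):
    """A compound has no docking score against any conformation."""


class ReferenceEnergyError(EdedError):
    """The reference conformation's relative free energy must be zero."""


class UnlabeledCompoundError(EdedError):
    """A scored compound has no activity label."""


class EmptyResultsError(EdedError):
    """An empty result list cannot be summarised."""


class InfeasibleGeometryError(EdedError):
    """The requested synthetic geometry cannot be constructed."""


class ConfigError(EdedError):
    """A pipeline configuration value violates a stage precondition."""
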