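"""Exception hierarchy.

Every error raised by the package derives from :class:`LayerCascadeError`,
so callers can catch the whole family with one clause.
"""


class LayerCascadeError(Exception):
    """Base class for all package errors."""


class UnknownReactionError(LayerCascadeError):
    """A reaction identifier does not exist in the network."""


class UnknownSpeciesError(LayerCascadeError):
    """A species identifier does not exist in the network."""


class RateEvaluationError(LayerCascadeError):
    """A rate law evaluated to a non-finite value or could not be evaluated."""


class ScheduleError(LayerCascadeError):
    """A time point falls outside every segment of a piecewise input schedule."""


class GridMismatchError(LayerCascadeError):
    """Two trajectories do not share the same time grid."""


class PartitionError(LayerCascadeError):
    """A reaction grouping violates the strict-partition requirement."""


class CoverError(LayerCascadeError):
    """Functionality reaction sets do not cover the full reaction set."""


class StructureError(LayerCascadeError):
    """A mixed (control-layer) structure violates its disjointness contract."""


class SolverError(LayerCascadeError):
    """Numerical integration failed for a reason other than divergence."""


class GraphPopulationError(LayerCascadeError):
    """A layering-graph node required for a derivation is missing."""


class WeightError(LayerCascadeError):
    """A per-species weight vector contains negative entries."""


class UndefinedAverageError(LayerCascadeError):
    """A time average was requested over a fully masked series."""


class UnsupportedSBMLError(LayerCascadeError):
    """The SBML document uses a construct outside the supported core subset."""


class SBMLValidationError(LayerCascadeError):
    """The SBML document is malformed or missing required elements."""


class ConfigError(LayerCascadeError):
    """A configuration file is malformed or inconsistent with the model."""


class SyntheticSpecError(LayerCascadeError):
    """A synthetic-network specification is infeasible."""


class EquilibrationError(LayerCascadeError):
    """Steady-state equilibration of a fixture model failed."""


class ProbingError(LayerCascadeError):
    """Numerical dependency probing hit non-finite rates."""
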