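"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`RestgraphError` so callers can
distinguish pipeline contract violations from programming errors.
"""


class RestgraphError(Exception):
    """Base class for all pipeline errors."""


class InvalidSpecError(RestgraphError):
    """A cohort/group specification violates its invariants."""


class GenerationFailureError(RestgraphError):
    """A random-graph generator failed to produce a connected graph."""


class DegenerateDesignError(RestgraphError):
    """Nuisance-regression design matrix is rank deficient."""


class InvalidBandError(RestgraphError):
    """Band-pass corner frequencies outside (0, Nyquist)."""


class InsufficientVolumesError(RestgraphError):
    """Motion trace has fewer than two volumes."""


class DegenerateRegionError(RestgraphError):
    """A region's time series has zero variance."""


class CohortInconsistencyError(RestgraphError):
    """Region labels differ between subjects of one cohort."""


class TrivialGraphError(RestgraphError):
    """Graph operations need at least two nodes."""


class InfeasibleCostError(RestgraphError):
    """Requested density cannot hold a spanning tree."""


class DisconnectedGraphError(RestgraphError):
    """Path-length metrics require a connected graph."""


class UndefinedGammaError(RestgraphError):
    """Null ensemble has zero mean clustering; gamma undefined."""


class DegenerateVarianceError(RestgraphError):
    """Two-sample test with zero pooled variance."""


class IncompleteCohortError(RestgraphError):
    """Metric tables are missing subject/cost combinations."""


class UnderpoweredSubgroupError(RestgraphError):
    """A subgroup has fewer than two subjects."""
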