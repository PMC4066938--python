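"""Exception hierarchy for niblpa.

All niblpa-specific failures derive from :class:`NiblpaError` so callers can
catch the whole family with one clause; each subclass marks a distinct
failure mode of the input contracts.
"""


class NiblpaError(Exception):
    """Base class for all niblpa errors."""


class EdgeListError(NiblpaError, ValueError):
    """Malformed edge-list input (bad field count, unparseable weight, ...)."""


class WeightConflictError(EdgeListError):
    """The same undirected edge appeared twice with different weights."""


class EmptyGraphError(NiblpaError, ValueError):
    """An edge-list file contained no usable edges."""


class CoverageError(NiblpaError, ValueError):
    """A labeling or partition does not cover the graph's node set."""


class ConsistencyError(NiblpaError, ValueError):
    """Two inputs that must share a node set do not (graph vs shells,
    partition vs partition, ...)."""


class UndefinedMetricError(NiblpaError, ValueError):
    """The requested metric is undefined for this input (e.g. modularity of
    an edgeless graph)."""


class ValidationError(NiblpaError, ValueError):
    """Generator or benchmark parameters outside their valid range."""
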