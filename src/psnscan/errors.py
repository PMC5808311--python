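"""Exception hierarchy for psnscan.

All validation failures raise a subclass of :class:`PsnscanError`, so callers
(and the CLI) can distinguish bad input from I/O problems with one except
clause.
"""


class PsnscanError(ValueError):
    """Base class for all psnscan validation errors."""


class DimensionError(PsnscanError):
    """A table that should be square is not (row/column counts differ)."""


class RangeError(PsnscanError):
    """A similarity score lies outside the percent-identity range [0, 100]."""


class DuplicateLabelError(PsnscanError):
    """The same sequence identifier appears more than once."""


class EmptyInputError(PsnscanError):
    """An input that must contain at least one record is empty."""


class StateError(PsnscanError):
    """An operation was called on an object in the wrong state
    (e.g. building a threshold network from an unsymmetrized matrix)."""


class AlignmentError(PsnscanError):
    """Two objects that must share a labeled node set do not."""


class SizeError(PsnscanError):
    """The problem is too small for the requested operation."""


class UndefinedPathError(PsnscanError):
    """Path statistics requested for a graph with no finite paths."""


class UndefinedDimensionError(PsnscanError):
    """Fractal dimension requested for a graph with diameter < 2
    or a disconnected graph."""


class PartitionError(PsnscanError):
    """A community partition does not cover the node set exactly once."""


class NotABranchError(PsnscanError):
    """A node set was required to be a dendrogram branch but never occurs
    as a connected component during edge removal."""


class NoOverlapError(PsnscanError):
    """Two classifications share no organisms, so congruence is undefined."""
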