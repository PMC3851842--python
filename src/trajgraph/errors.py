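"""Exception hierarchy shared across the package."""


class TrajGraphError(Exception):
    """Base class for all trajgraph errors."""


class ParseError(TrajGraphError):
    """Malformed genome or trajectory text."""

    def __init__(self, message, line=None, column=None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", col {column})" if column is not None else ")")
        super().__init__(message + loc)
        self.line = line
        self.column = column


class DuplicateGeneError(ParseError):
    """The same (family, copy) pair occurs twice in one genome."""


class InvalidAdjacencySetError(TrajGraphError):
    """An adjacency multiset does not encode a valid genome."""


class MissingAdjacencyError(TrajGraphError):
    """An operation references an adjacency absent from the current state."""


class InvalidOperationError(TrajGraphError):
    """An operation is structurally ill-formed."""


class OverlapError(InvalidOperationError):
    """A duplication target lies inside (or touches the interior of) its segment."""


class SegmentError(InvalidOperationError):
    """A duplication segment is not contiguous in the current state."""


class TrajectoryConsistencyError(TrajGraphError):
    """An operation in a trajectory cannot be applied at its position."""

    def __init__(self, message, op_index=None):
        if op_index is not None:
            message = f"operation {op_index}: {message}"
        super().__init__(message)
        self.op_index = op_index


class CorruptGraphError(TrajGraphError):
    """A trajectory graph violates a structural invariant (bug surface)."""


class ExchangeError(TrajGraphError):
    """A cycle exchange or resolution could not be carried out (bug surface)."""


class IncomparableGenomesError(TrajGraphError):
    """Two genomes do not share the extremity set required by the adjacency graph."""


class ConfigError(TrajGraphError):
    """Invalid simulator configuration."""


class SimulationError(TrajGraphError):
    """The simulator could not produce a valid operation."""
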