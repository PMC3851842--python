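"""DCJ and segmental-duplication operations as functions of adjacencies.

A DCJ cuts two adjacencies (a, b) and (c, d) and rejoins the four ends as
(a, d), (c, b) or as (a, -c), (-b, d); the third rejoining repairs the cuts
and is not modelled.  A type-1 duplication copies a contiguous segment
(g_1..g_n) and inserts the copy (forward or inverted) at a target adjacency
(a, b); a type-2 duplication closes the copy into a new circular chromosome.

Each operation exposes two views of its inputs/outputs:

* the *state* view (:func:`apply_op`): the adjacencies removed from and added
  to the running adjacency set; duplications leave the original segment
  adjacencies untouched;
* the *graph* view (:meth:`graph_inputs` / :meth:`graph_outputs`): duplications
  additionally consume the original segment adjacencies and re-emit them, so
  that the trajectory graph records the dependency (inactive edges).

The active-edge pattern follows the change rule: an edge is active iff the
adjacency at its far end was actually changed by the operation.  All four DCJ
edges are active; a type-1 duplication has one active in-edge (the target)
and two active out-edges (the junction adjacencies); a type-2 duplication has
a single active out-edge, to the adjacency closing the copied circle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Union

from .errors import (
    InvalidOperationError,
    MissingAdjacencyError,
    OverlapError,
    ParseError,
    SegmentError,
)
from .genome_model import (
    Adjacency,
    Extremity,
    GeneId,
    SignedGene,
    adjacency,
    adjacency_token,
    _parse_gene_token,
    null_extremity,
)


def _extremity_multiset(adjs: Iterable[Adjacency]) -> list:
    out = []
    for a in adjs:
        out.extend(a)
    return sorted(out, key=Extremity.sort_key)


@dataclass(frozen=True)
class Dcj:
    """A double-cut-and-join: two input adjacencies, two output adjacencies."""

    inputs: tuple
    outputs: tuple

    def __post_init__(self):
        if len(self.inputs) != 2 or len(self.outputs) != 2:
            raise InvalidOperationError("DCJ takes two adjacencies to two")
        if self.inputs[0] == self.inputs[1]:
            raise InvalidOperationError("DCJ inputs must be distinct adjacencies")
        if _extremity_multiset(self.inputs) != _extremity_multiset(self.outputs):
            raise InvalidOperationError("DCJ must conserve extremities")
        if frozenset(self.outputs) == frozenset(self.inputs):
            raise InvalidOperationError("DCJ must change both adjacencies")

    @staticmethod
    def outcomes(a: Adjacency, b: Adjacency) -> list:
        """The (at most two) nontrivial rejoinings of adjacencies a and b."""
        e = sorted(a, key=Extremity.sort_key) + sorted(b, key=Extremity.sort_key)
        if len(e) != 4 or len(set(e)) != 4:
            raise InvalidOperationError("DCJ requires four distinct cut ends")
        a1, a2, b1, b2 = e
        cands = [
            (adjacency(a1, b1), adjacency(a2, b2)),
            (adjacency(a1, b2), adjacency(a2, b1)),
        ]
        return [c for c in cands if frozenset(c) != frozenset((a, b))]

    def inverse(self) -> "Dcj":
        return Dcj(self.outputs, self.inputs)

    def token(self) -> str:
        return "DCJ {} {} -> {} {}".format(
            *(adjacency_token(x) for x in (*self.inputs, *self.outputs))
        )


def _copies_for(segment: tuple, copies: Optional[tuple]) -> tuple:
    if copies is None:
        return None
    if len(copies) != len(segment):
        raise InvalidOperationError("one copy gene per segment gene required")
    for sg, cp in zip(segment, copies):
        if cp.family != sg.gene.family:
            raise InvalidOperationError(
                f"copy {cp} is not a copy of segment gene {sg.gene}"
            )
    return tuple(copies)


@dataclass(frozen=True)
class _DupBase:
    #: the duplicated segment, as it reads in the current genome
    segment: tuple
    #: GeneIds assigned to the copies (same families, fresh copy indices);
    #: None until the trajectory is concretised
    copies: Optional[tuple] = None

    def __post_init__(self):
        if not self.segment:
            raise InvalidOperationError("empty segment")
        object.__setattr__(self, "copies", _copies_for(self.segment, self.copies))

    def _need_copies(self):
        if self.copies is None:
            raise InvalidOperationError(
                "duplication has unassigned copies; concretise the trajectory first"
            )

    def segment_adjacencies(self) -> list:
        """The n - 1 adjacencies identifying the original segment."""
        s = self.segment
        return [adjacency(s[i].right, s[i + 1].left) for i in range(len(s) - 1)]

    def copy_segment(self) -> tuple:
        self._need_copies()
        return tuple(
            SignedGene(cp, sg.sign) for sg, cp in zip(self.segment, self.copies)
        )

    def copy_internal_adjacencies(self) -> list:
        """Internal adjacencies of the copied segment (same set either strand)."""
        c = self.copy_segment()
        return [adjacency(c[i].right, c[i + 1].left) for i in range(len(c) - 1)]

    def _seg_token(self) -> str:
        return "(" + ",".join(g.token() for g in self.segment) + ")"

    def _copies_token(self) -> str:
        if self.copies is None:
            return ""
        return " copies=(" + ",".join(c.label for c in self.copies) + ")"


@dataclass(frozen=True)
class DupInsert(_DupBase):
    """Type-1 duplication: insert a copy of the segment at a target adjacency.

    The target ``{e_a, e_b}`` is an unordered pair; the two possible readings
    of an ordered insert position (a, b) are canonicalised by sorting the
    extremities, and the remaining degree of freedom is exactly the
    ``inverted`` flag.
    """

    target: Adjacency = None
    inverted: bool = False

    def __post_init__(self):
        super().__post_init__()
        if self.target is None:
            raise InvalidOperationError("insert duplication needs a target")
        internal = set().union(*self.segment_adjacencies()) if len(self.segment) > 1 else set()
        if self.target in self.segment_adjacencies():
            raise OverlapError("target lies inside the duplicated segment")
        if internal & set(self.target):
            raise OverlapError("target touches segment-internal extremities")

    def _target_pair(self):
        ea, eb = sorted(self.target, key=Extremity.sort_key)
        return ea, eb

    def junction_adjacencies(self) -> list:
        """The two adjacencies stitching the copy into the target position."""
        self._need_copies()
        ea, eb = self._target_pair()
        c = self.copy_segment()
        if self.inverted:
            return [adjacency(ea, c[-1].right), adjacency(c[0].left, eb)]
        return [adjacency(ea, c[0].left), adjacency(c[-1].right, eb)]

    def flipped(self) -> "DupInsert":
        return replace(self, inverted=not self.inverted)

    def graph_inputs(self) -> list:
        return self.segment_adjacencies() + [self.target]

    def graph_outputs(self) -> list:
        return (
            self.segment_adjacencies()
            + self.junction_adjacencies()
            + self.copy_internal_adjacencies()
        )

    def token(self) -> str:
        return (
            f"DUPI segment={self._seg_token()} "
            f"target={adjacency_token(self.target)} "
            f"inverted={int(self.inverted)}{self._copies_token()}"
        )


@dataclass(frozen=True)
class DupCircular(_DupBase):
    """Type-2 duplication: close a copy of the segment into a circular chromosome."""

    def closing_adjacency(self) -> Adjacency:
        self._need_copies()
        c = self.copy_segment()
        return adjacency(c[-1].right, c[0].left)

    def graph_inputs(self) -> list:
        return self.segment_adjacencies()

    def graph_outputs(self) -> list:
        return (
            self.segment_adjacencies()
            + self.copy_internal_adjacencies()
            + [self.closing_adjacency()]
        )

    def token(self) -> str:
        return f"DUPC segment={self._seg_token()}{self._copies_token()}"


Operation = Union[Dcj, DupInsert, DupCircular]
Duplication = (DupInsert, DupCircular)


def graph_inputs(op: Operation) -> list:
    return list(op.inputs) if isinstance(op, Dcj) else op.graph_inputs()


def graph_outputs(op: Operation) -> list:
    return list(op.outputs) if isinstance(op, Dcj) else op.graph_outputs()


@dataclass(frozen=True)
class ActiveEdgePattern:
    """Which input/output adjacency slots of an operation are active."""

    active_in: frozenset
    active_out: frozenset


def active_pattern(op: Operation) -> ActiveEdgePattern:
    if isinstance(op, Dcj):
        return ActiveEdgePattern(frozenset(op.inputs), frozenset(op.outputs))
    if isinstance(op, DupInsert):
        return ActiveEdgePattern(
            frozenset([op.target]), frozenset(op.junction_adjacencies())
        )
    if isinstance(op, DupCircular):
        return ActiveEdgePattern(frozenset(), frozenset([op.closing_adjacency()]))
    raise InvalidOperationError(f"unknown operation {op!r}")


# ---------------------------------------------------------------------------
# Applying operations to adjacency states
# ---------------------------------------------------------------------------


def _check_segment_in_state(op: _DupBase, state: set):
    for a in op.segment_adjacencies():
        if a not in state:
            raise SegmentError(
                f"segment {op._seg_token()} not contiguous: missing {adjacency_token(a)}"
            )
    if len(op.segment) == 1:
        # no internal adjacency anchors a single-gene segment; check the gene
        # is present in the state at all
        ext = op.segment[0].left
        if not any(ext in a for a in state):
            raise SegmentError(f"segment gene {op.segment[0].gene} absent from state")


def apply_dcj(state: set, op: Dcj) -> set:
    for a in op.inputs:
        if a not in state:
            raise MissingAdjacencyError(adjacency_token(a))
    new = set(state)
    new.difference_update(op.inputs)
    new.update(op.outputs)
    return new


def apply_dup_insert(state: set, op: DupInsert) -> set:
    op._need_copies()
    _check_segment_in_state(op, state)
    if op.target not in state:
        raise MissingAdjacencyError(adjacency_token(op.target))
    new = set(state)
    new.remove(op.target)
    new.update(op.junction_adjacencies())
    new.update(op.copy_internal_adjacencies())
    return new


def apply_dup_circular(state: set, op: DupCircular) -> set:
    op._need_copies()
    _check_segment_in_state(op, state)
    new = set(state)
    new.update(op.copy_internal_adjacencies())
    new.add(op.closing_adjacency())
    return new


def apply_op(state: set, op: Operation) -> set:
    if isinstance(op, Dcj):
        return apply_dcj(state, op)
    if isinstance(op, DupInsert):
        return apply_dup_insert(state, op)
    if isinstance(op, DupCircular):
        return apply_dup_circular(state, op)
    raise InvalidOperationError(f"unknown operation {op!r}")


def concretize_trajectory(initial_adjacencies: Iterable[Adjacency], ops: list) -> list:
    """Assign copy GeneIds to duplications lacking them, in trajectory order.

    Copy indices continue from the highest index already present per family,
    so the assignment is deterministic given the trajectory.  The ops are
    not replayed here: validity is checked where they are applied.
    """
    next_copy: dict = {}
    for a in initial_adjacencies:
        for e in a:
            if not e.is_null:
                fam, cp = e.gene.family, e.gene.copy
                next_copy[fam] = max(next_copy.get(fam, 0), cp)
    out = []
    for op in ops:
        if isinstance(op, Duplication) and op.copies is None:
            copies = []
            for sg in op.segment:
                fam = sg.gene.family
                next_copy[fam] = next_copy.get(fam, 0) + 1
                copies.append(GeneId(fam, next_copy[fam]))
            op = replace(op, copies=tuple(copies))
        elif isinstance(op, Duplication):
            for cp in op.copies:
                next_copy[cp.family] = max(next_copy.get(cp.family, 0), cp.copy)
        out.append(op)
    return out


# ---------------------------------------------------------------------------
# Trajectory text format (one operation per line)
#
#   DCJ {1_h,2_t} {3_h,0#1} -> {1_h,0#1} {3_h,2_t}
#   DUPI segment=(2,3,-4) target={5_h,0#2} inverted=0 copies=(2',3',4')
#   DUPC segment=(2,3) copies=(2'',3'')
#
# 'copies=' is optional on input (indices are then assigned on replay) and
# always written on output; '#' starts a comment.
# ---------------------------------------------------------------------------

_EXT_RE = re.compile(r"^(?:0#(\d+)|0|(-?\d+'*)_(h|t))$")


def parse_extremity(tok: str, lineno: int = None) -> Extremity:
    m = _EXT_RE.match(tok)
    if not m:
        raise ParseError(f"bad extremity token {tok!r}", line=lineno)
    if m.group(1) is not None:
        return null_extremity(int(m.group(1)))
    if tok == "0":
        return null_extremity()
    sg = _parse_gene_token(m.group(2), lineno, 0)
    if sg.sign == -1:
        raise ParseError(f"extremity gene must be unsigned: {tok!r}", line=lineno)
    return Extremity(m.group(3), sg.gene)


def parse_adjacency(tok: str, lineno: int = None) -> Adjacency:
    if not (tok.startswith("{") and tok.endswith("}")):
        raise ParseError(f"bad adjacency token {tok!r}", line=lineno)
    parts = [p for p in tok[1:-1].split(",") if p]
    if not 1 <= len(parts) <= 2:
        raise ParseError(f"adjacency needs 1-2 extremities: {tok!r}", line=lineno)
    return adjacency(*(parse_extremity(p, lineno) for p in parts))


def _parse_gene_list(tok: str, lineno: int) -> tuple:
    if not (tok.startswith("(") and tok.endswith(")")):
        raise ParseError(f"bad gene list {tok!r}", line=lineno)
    return tuple(
        _parse_gene_token(p, lineno, 0) for p in tok[1:-1].split(",") if p
    )


def _parse_kv(parts: list, lineno: int) -> dict:
    kv = {}
    for p in parts:
        if "=" not in p:
            raise ParseError(f"expected key=value, got {p!r}", line=lineno)
        k, v = p.split("=", 1)
        kv[k] = v
    return kv


def parse_trajectory(text: str) -> list:
    """Parse an operation-list file into a list of operations."""
    ops = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        # '#' also appears inside cap tokens (0#3), so only whole-line comments
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        kind = parts[0]
        if kind == "DCJ":
            if len(parts) != 6 or parts[3] != "->":
                raise ParseError("DCJ line must be 'DCJ A B -> C D'", line=lineno)
            ins = tuple(parse_adjacency(p, lineno) for p in parts[1:3])
            outs = tuple(parse_adjacency(p, lineno) for p in parts[4:6])
            ops.append(Dcj(ins, outs))
        elif kind == "DUPI":
            kv = _parse_kv(parts[1:], lineno)
            if not {"segment", "target"} <= set(kv):
                raise ParseError("DUPI needs segment= and target=", line=lineno)
            copies = None
            if "copies" in kv:
                copies = tuple(
                    sg.gene for sg in _parse_gene_list(kv["copies"], lineno)
                )
            ops.append(
                DupInsert(
                    segment=_parse_gene_list(kv["segment"], lineno),
                    copies=copies,
                    target=parse_adjacency(kv["target"], lineno),
                    inverted=bool(int(kv.get("inverted", "0"))),
                )
            )
        elif kind == "DUPC":
            kv = _parse_kv(parts[1:], lineno)
            if "segment" not in kv:
                raise ParseError("DUPC needs segment=", line=lineno)
            copies = None
            if "copies" in kv:
                copies = tuple(
                    sg.gene for sg in _parse_gene_list(kv["copies"], lineno)
                )
            ops.append(
                DupCircular(segment=_parse_gene_list(kv["segment"], lineno), copies=copies)
            )
        else:
            raise ParseError(f"unknown operation {kind!r}", line=lineno)
    return ops


def format_trajectory(ops: Iterable[Operation]) -> str:
    return "\n".join(op.token() for op in ops) + "\n"
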