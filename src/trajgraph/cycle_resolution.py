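"""Iterative shortening of a trajectory by resolving active cycles.

An active cycle in the trajectory graph witnesses a redundancy among the
rearrangements of the trajectory.  The improvement procedure repeatedly
picks an active cycle and shrinks it by *exchanging* the bottom DCJ node
with one of its two parent operation nodes (moving one operation off the
cycle while keeping the total operation count, the endpoint genomes and
acyclicity unchanged), until the cycle has exactly two operation nodes;
a size-2 cycle is then *resolved* by replacing its two operations with at
most one:

* two DCJs whose supernode input and output differ collapse to a single
  DCJ; if input equals output both are deleted;
* an insert-duplication whose two junction adjacencies are immediately
  consumed by a DCJ collapses to a single duplication: the inverted
  insertion at the same target if the DCJ does not restore the target
  adjacency, and a circular duplication of the same segment if it does.

Every resolved cycle removes at least one DCJ node and never changes the
number of duplications, so the driver terminates; with DCJ-only input the
final trajectory is optimal (its graph is a forest and its length equals the
adjacency-graph distance |X| - c).  With duplications the procedure is an
improvement heuristic: no active cycle remains, but global optimality is not
guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import networkx as nx

from .errors import CorruptGraphError, ExchangeError
from .errors import InvalidOperationError as tj_invalid
from .genome_model import Genome, adjacency_token
from .operations import Dcj, DupCircular, DupInsert, Operation
from .trajectory_graph import (
    ActiveCycle,
    AdjNode,
    OpNode,
    TrajectoryGraph,
    find_active_cycle,
)


@dataclass
class ExchangeRecord:
    """One mutation of the trajectory graph."""

    kind: str  # 'dcj_dcj' | 'dcj_dup' | 'base_dcj_dcj' | 'base_dup_dcj'
    removed_nodes: list
    added_nodes: list
    cycle_size_before: int
    cycle_size_after: int
    dcj_count_after: int
    dup_count_after: int

    @property
    def is_base(self) -> bool:
        return self.kind.startswith("base_")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "removed": [repr(n) for n in self.removed_nodes],
            "added": [repr(n) for n in self.added_nodes],
            "cycle_size_before": self.cycle_size_before,
            "cycle_size_after": self.cycle_size_after,
            "dcj_count_after": self.dcj_count_after,
            "dup_count_after": self.dup_count_after,
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _parents_of_bottom(cycle: ActiveCycle) -> Tuple[OpNode, OpNode]:
    """The two operation nodes adjacent to the bottom along the cycle."""
    seq = cycle.seq
    k = len(seq)
    i = seq.index(cycle.bottom)
    p1, p2 = seq[(i - 2) % k], seq[(i + 2) % k]
    if not (isinstance(p1, OpNode) and isinstance(p2, OpNode)):
        raise ExchangeError("bottom parents must be operation nodes")
    return p1, p2


def choose_parent(cycle: ActiveCycle, tg: TrajectoryGraph) -> OpNode:
    """Pick the bottom's parent to exchange so no directed cycle can arise.

    If one parent lies on a directed path to the other, the descendant is
    chosen; independent parents break the tie by smallest uid.  The rule
    also guarantees the new dependency created by the exchange (the chosen
    parent's surviving outputs come to depend on the bottom's other input)
    cannot close a directed cycle.
    """
    p1, p2 = _parents_of_bottom(cycle)
    if p1 is p2:
        raise ExchangeError("shared parent implies an undetected size-2 cycle")
    if nx.has_path(tg.g, p1, p2):
        return p2
    if nx.has_path(tg.g, p2, p1):
        return p1
    return min(p1, p2, key=lambda n: n.uid)


def _bottom_context(tg: TrajectoryGraph, cycle: ActiveCycle, parent: OpNode):
    """Locate the cycle nodes around bottom and ``parent``.

    Returns ``(b, u_par, u_other, cycle_in)`` where ``u_par`` is the bottom
    input produced by ``parent``, ``u_other`` the bottom's other input, and
    ``cycle_in`` the parent's on-cycle input adjacency node when the cycle
    enters the parent from above (``None`` when the parent is itself a local
    maximum of the cycle, i.e. both its cycle edges point away from it).
    """
    b = cycle.bottom
    seq = cycle.seq
    k = len(seq)
    i = seq.index(b)
    if seq[(i - 2) % k] is parent:
        u_par, u_other = seq[(i - 1) % k], seq[(i + 1) % k]
        w3 = seq[(i - 3) % k]
    elif seq[(i + 2) % k] is parent:
        u_par, u_other = seq[(i + 1) % k], seq[(i - 1) % k]
        w3 = seq[(i + 3) % k]
    else:
        raise ExchangeError("parent not adjacent to bottom on the cycle")
    if not (isinstance(u_par, AdjNode) and isinstance(u_other, AdjNode)):
        raise ExchangeError("malformed cycle sequence")
    if tg.producer(u_other) is parent:
        raise ExchangeError(
            "bottom consumes two outputs of the parent: size-2 cycle missed"
        )
    cycle_in = w3 if tg.g.has_edge(w3, parent) else None
    return b, u_par, u_other, cycle_in


def _adj_sort_key(content):
    return adjacency_token(content)


def _remove_nodes(tg: TrajectoryGraph, nodes):
    for n in nodes:
        tg.g.remove_node(n)


def _redirect_consumer(tg: TrajectoryGraph, old: AdjNode, new: AdjNode):
    """Move ``old``'s consumer edge (if any) onto ``new`` and drop ``old``."""
    cons = tg.consumer(old)
    if cons is not None:
        active = tg.g.edges[old, cons]["active"]
        tg.g.add_edge(new, cons, active=active)
    tg.g.remove_node(old)


def _check_dag(tg: TrajectoryGraph):
    if not tg.is_dag():
        raise ExchangeError("exchange created a directed cycle")


# ---------------------------------------------------------------------------
# exchanges (cycle size > 2)
# ---------------------------------------------------------------------------


def exchange_dcj_dcj(
    tg: TrajectoryGraph, cycle: ActiveCycle, parent: OpNode
) -> ExchangeRecord:
    """Exchange the bottom DCJ with a parent DCJ (supernode rewrite).

    The two nodes are viewed as one supernode with three input and three
    output adjacencies, and replaced by two new DCJs with the same supernode
    boundary.  When the cycle enters the parent from above, the new first
    DCJ takes the parent's on-cycle input together with the bottom's other
    input, and the new second DCJ leaves the cycle, which shrinks by one
    operation.  When the parent is itself a local maximum of the cycle
    (both its cycle edges point downward — possible only on crumpled,
    non-theta cycles), the first input is chosen by feasibility instead;
    the cycle keeps its size but loses one maximum/minimum pair, so it
    straightens towards the theta shape.
    """
    b, u_par, u_other, cycle_in = _bottom_context(tg, cycle, parent)
    if not (parent.is_dcj and b.is_dcj):
        raise ExchangeError("exchange_dcj_dcj needs two DCJ nodes")

    p_ins = sorted(tg.g.predecessors(parent), key=lambda n: n.uid)
    if cycle_in is not None:
        if cycle_in not in p_ins:
            raise ExchangeError("cycle path does not enter the parent")
        orderings = [(cycle_in, next(n for n in p_ins if n is not cycle_in))]
    else:
        orderings = [(p_ins[0], p_ins[1]), (p_ins[1], p_ins[0])]
    p_outs = sorted(tg.g.successors(parent), key=lambda n: n.uid)
    if u_par not in p_outs:
        raise ExchangeError("parent does not feed the bottom on the cycle")
    y_other = next(n for n in p_outs if n is not u_par)
    b_outs = sorted(tg.g.successors(b), key=lambda n: n.uid)

    supernode_outs = [y_other] + b_outs  # three adjacency nodes, kept in place

    candidates = []
    for xa, xb in orderings:
        try:
            outcomes = Dcj.outcomes(xa.content, u_other.content)
        except tj_invalid:
            continue
        for o1, o2 in outcomes:
            for matched_c, z_c in ((o1, o2), (o2, o1)):
                matched_nodes = [
                    n for n in supernode_outs if n.content == matched_c
                ]
                if not matched_nodes:
                    continue
                matched = matched_nodes[0]
                rest = [n for n in supernode_outs if n is not matched]
                try:
                    rest_outcomes = Dcj.outcomes(z_c, xb.content)
                except tj_invalid:
                    continue
                for r1, r2 in rest_outcomes:
                    if {r1, r2} == {rest[0].content, rest[1].content}:
                        candidates.append((matched, z_c, xa, xb))
    if not candidates:
        raise ExchangeError("supernode reconstruction infeasible")
    # deterministic pick: prefer reproducing one of the original bottom's
    # outputs, then canonical adjacency order of the matched node
    orig_out_contents = {n.content for n in b_outs}
    candidates.sort(
        key=lambda c: (
            c[0].content not in orig_out_contents,
            _adj_sort_key(c[0].content),
            _adj_sort_key(c[1]),
        )
    )
    matched, z_c, xa, xb = candidates[0]
    rest = [n for n in supernode_outs if n is not matched]

    new_top = tg.new_op_node(
        Dcj((xa.content, u_other.content), (matched.content, z_c))
    )
    z_node = tg.new_adj_node(z_c)
    new_bot = tg.new_op_node(
        Dcj((z_c, xb.content), (rest[0].content, rest[1].content))
    )

    _remove_nodes(tg, [parent, b, u_par])
    tg.g.add_edge(xa, new_top, active=True)
    tg.g.add_edge(u_other, new_top, active=True)
    tg.g.add_edge(new_top, matched, active=True)
    tg.g.add_edge(new_top, z_node, active=True)
    tg.g.add_edge(z_node, new_bot, active=True)
    tg.g.add_edge(xb, new_bot, active=True)
    tg.g.add_edge(new_bot, rest[0], active=True)
    tg.g.add_edge(new_bot, rest[1], active=True)
    _check_dag(tg)

    return ExchangeRecord(
        kind="dcj_dcj",
        removed_nodes=[parent, b],
        added_nodes=[new_top, new_bot],
        cycle_size_before=cycle.size,
        cycle_size_after=cycle.size - 1 if cycle_in is not None else cycle.size,
        dcj_count_after=tg.dcj_count(),
        dup_count_after=tg.dup_count(),
    )


def exchange_dcj_dup(
    tg: TrajectoryGraph, cycle: ActiveCycle, parent: OpNode
) -> ExchangeRecord:
    """Exchange the bottom DCJ with its parent insert-duplication.

    The new DCJ takes the target adjacency and the bottom's other input; one
    output is a supernode output, the other becomes the insert position of
    the new bottom duplication node.  When the cycle enters the duplication
    via its target the new duplication leaves the cycle (size shrinks by
    one); when the duplication is a local maximum — the cycle descends via
    both junctions — the pair is rewritten in place, removing one
    maximum/minimum pair of the cycle.
    """
    b, u_par, u_other, cycle_in = _bottom_context(tg, cycle, parent)
    dup = parent.op
    if not isinstance(dup, DupInsert) or not b.is_dcj:
        raise ExchangeError("exchange_dcj_dup needs DupInsert parent, DCJ bottom")

    t_node = next(
        (n for n in tg.g.predecessors(parent) if n.content == dup.target), None
    )
    if t_node is None:
        raise ExchangeError("duplication node lacks its target input")
    if cycle_in is not None and cycle_in is not t_node:
        raise ExchangeError("cycle must enter the duplication via its target")

    junctions = dup.junction_adjacencies()
    if u_par.content not in junctions:
        raise ExchangeError("bottom must consume a junction adjacency")
    seg_nodes = [
        n for n in tg.g.predecessors(parent) if n is not t_node
    ]
    out_by_content = {}
    for n in tg.g.successors(parent):
        out_by_content.setdefault(n.content, []).append(n)
    j_other_c = next(c for c in junctions if c != u_par.content)
    j_other = out_by_content[j_other_c][0]
    reemit = [
        n
        for n in tg.g.successors(parent)
        if n is not u_par and n is not j_other
    ]  # re-emitted originals + copy-internal nodes, kept in place
    b_outs = sorted(tg.g.successors(b), key=lambda n: n.uid)

    supernode_outs = [j_other] + b_outs
    candidates = []
    for o1, o2 in Dcj.outcomes(t_node.content, u_other.content):
        for matched_c, z_c in ((o1, o2), (o2, o1)):
            matched_nodes = [n for n in supernode_outs if n.content == matched_c]
            if not matched_nodes:
                continue
            matched = matched_nodes[0]
            rest = [n for n in supernode_outs if n is not matched]
            for inv in (not dup.inverted, dup.inverted):
                try:
                    nd = replace(dup, target=z_c, inverted=inv)
                except Exception:
                    continue
                if set(nd.junction_adjacencies()) == {n.content for n in rest}:
                    candidates.append((matched, z_c, nd))
    if not candidates:
        raise ExchangeError("supernode reconstruction infeasible")
    candidates.sort(key=lambda c: (_adj_sort_key(c[0].content), _adj_sort_key(c[1])))
    matched, z_c, new_dup = candidates[0]
    rest = [n for n in supernode_outs if n is not matched]

    new_dcj = tg.new_op_node(
        Dcj((t_node.content, u_other.content), (matched.content, z_c))
    )
    z_node = tg.new_adj_node(z_c)
    new_dup_node = tg.new_op_node(new_dup)

    _remove_nodes(tg, [parent, b, u_par])
    tg.g.add_edge(t_node, new_dcj, active=True)
    tg.g.add_edge(u_other, new_dcj, active=True)
    tg.g.add_edge(new_dcj, matched, active=True)
    tg.g.add_edge(new_dcj, z_node, active=True)
    # the new duplication consumes the segment adjacencies and the new target
    for n in seg_nodes:
        tg.g.add_edge(n, new_dup_node, active=False)
    tg.g.add_edge(z_node, new_dup_node, active=True)
    junction_contents = set(new_dup.junction_adjacencies())
    for n in rest:
        tg.g.add_edge(new_dup_node, n, active=n.content in junction_contents)
    for n in reemit:
        tg.g.add_edge(new_dup_node, n, active=False)
    _check_dag(tg)

    return ExchangeRecord(
        kind="dcj_dup",
        removed_nodes=[parent, b],
        added_nodes=[new_dcj, new_dup_node],
        cycle_size_before=cycle.size,
        cycle_size_after=cycle.size - 1 if cycle_in is not None else cycle.size,
        dcj_count_after=tg.dcj_count(),
        dup_count_after=tg.dup_count(),
    )


# ---------------------------------------------------------------------------
# base cases (cycle size == 2)
# ---------------------------------------------------------------------------


def resolve_base_dcj_dcj(tg: TrajectoryGraph, cycle: ActiveCycle) -> ExchangeRecord:
    """Replace a size-2 DCJ/DCJ cycle with one DCJ, or with nothing."""
    t, b = cycle.top, cycle.bottom
    if not (t.is_dcj and b.is_dcj):
        raise ExchangeError("base case needs two DCJ nodes")
    x_nodes = sorted(tg.g.predecessors(t), key=lambda n: n.uid)
    u_nodes = sorted(tg.g.successors(t), key=lambda n: n.uid)
    w_nodes = sorted(tg.g.successors(b), key=lambda n: n.uid)
    if sorted(tg.g.predecessors(b), key=lambda n: n.uid) != u_nodes:
        raise ExchangeError("bottom must consume both outputs of the top")

    x_contents = sorted((n.content for n in x_nodes), key=_adj_sort_key)
    w_contents = sorted((n.content for n in w_nodes), key=_adj_sort_key)

    if x_contents == w_contents:
        # inverse pair: drop both operations, splice sources to sinks
        _remove_nodes(tg, [t, b] + u_nodes)
        unmatched = list(w_nodes)
        for x in x_nodes:
            w = next(n for n in unmatched if n.content == x.content)
            unmatched.remove(w)
            _redirect_consumer(tg, w, x)
        added = []
        kind_removed = [t, b]
    else:
        new_op = tg.new_op_node(
            Dcj(
                (x_nodes[0].content, x_nodes[1].content),
                (w_nodes[0].content, w_nodes[1].content),
            )
        )
        _remove_nodes(tg, [t, b] + u_nodes)
        tg.g.add_edge(x_nodes[0], new_op, active=True)
        tg.g.add_edge(x_nodes[1], new_op, active=True)
        tg.g.add_edge(new_op, w_nodes[0], active=True)
        tg.g.add_edge(new_op, w_nodes[1], active=True)
        added = [new_op]
        kind_removed = [t, b]
    _check_dag(tg)

    return ExchangeRecord(
        kind="base_dcj_dcj",
        removed_nodes=kind_removed,
        added_nodes=added,
        cycle_size_before=2,
        cycle_size_after=0,
        dcj_count_after=tg.dcj_count(),
        dup_count_after=tg.dup_count(),
    )


def resolve_base_dup_dcj(tg: TrajectoryGraph, cycle: ActiveCycle) -> ExchangeRecord:
    """Replace a size-2 duplication/DCJ cycle with a single duplication.

    If the bottom DCJ recreates the insertion target (a, b), the pair
    becomes a circular duplication of the segment; otherwise it becomes an
    insertion of the oppositely-oriented copy at the same target.
    """
    t, b = cycle.top, cycle.bottom
    dup = t.op
    if not isinstance(dup, DupInsert) or not b.is_dcj:
        raise ExchangeError("base case needs DupInsert top and DCJ bottom")

    junctions = dup.junction_adjacencies()
    j_nodes = sorted(tg.g.successors(t), key=lambda n: n.uid)
    j_nodes = [n for n in j_nodes if n.content in junctions]
    if sorted(tg.g.predecessors(b), key=lambda n: n.uid) != sorted(
        j_nodes, key=lambda n: n.uid
    ) or len(j_nodes) != 2:
        raise ExchangeError("bottom must consume exactly the two junctions")

    t_in = {n.content: n for n in tg.g.predecessors(t)}
    t_node = t_in[dup.target]
    seg_nodes = [n for n in tg.g.predecessors(t) if n is not t_node]
    reemit = [n for n in tg.g.successors(t) if n not in j_nodes]
    w_nodes = sorted(tg.g.successors(b), key=lambda n: n.uid)

    w_contents = {n.content for n in w_nodes}
    removed = [t, b]
    if dup.target in w_contents:
        # target restored: the copy is excised as a circle
        new_dup = DupCircular(segment=dup.segment, copies=dup.copies)
        closing = new_dup.closing_adjacency()
        w_target = next(n for n in w_nodes if n.content == dup.target)
        w_circle = next(n for n in w_nodes if n is not w_target)
        if w_circle.content != closing:
            raise ExchangeError("excised copy does not close into a circle")
        new_node = tg.new_op_node(new_dup)
        _remove_nodes(tg, [t, b] + j_nodes)
        for n in seg_nodes:
            tg.g.add_edge(n, new_node, active=False)
        tg.g.add_edge(new_node, w_circle, active=True)
        for n in reemit:
            tg.g.add_edge(new_node, n, active=False)
        # the untouched target now flows straight to the old DCJ output's
        # consumer
        _redirect_consumer(tg, w_target, t_node)
        kind = "base_dup_dcj"
    else:
        new_dup = dup.flipped()
        if set(new_dup.junction_adjacencies()) != w_contents:
            raise ExchangeError("inverted insertion does not reproduce the outputs")
        new_node = tg.new_op_node(new_dup)
        _remove_nodes(tg, [t, b] + j_nodes)
        for n in seg_nodes:
            tg.g.add_edge(n, new_node, active=False)
        tg.g.add_edge(t_node, new_node, active=True)
        for n in w_nodes:
            tg.g.add_edge(new_node, n, active=True)
        for n in reemit:
            tg.g.add_edge(new_node, n, active=False)
        kind = "base_dup_dcj"
    _check_dag(tg)

    return ExchangeRecord(
        kind=kind,
        removed_nodes=removed,
        added_nodes=[new_node],
        cycle_size_before=2,
        cycle_size_after=0,
        dcj_count_after=tg.dcj_count(),
        dup_count_after=tg.dup_count(),
    )


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def resolve_step(tg: TrajectoryGraph) -> Optional[ExchangeRecord]:
    """Perform one exchange or base-case resolution; None if no active cycle."""
    cycle = find_active_cycle(tg)
    if cycle is None:
        return None
    if cycle.size == 2:
        if cycle.top.is_dcj:
            return resolve_base_dcj_dcj(tg, cycle)
        return resolve_base_dup_dcj(tg, cycle)
    parent = choose_parent(cycle, tg)
    if parent.is_dcj:
        return exchange_dcj_dcj(tg, cycle, parent)
    return exchange_dcj_dup(tg, cycle, parent)


def optimize_graph(tg: TrajectoryGraph) -> List[ExchangeRecord]:
    """Resolve active cycles until none remain; returns the mutation log."""
    n_ops = len(tg.op_nodes())
    budget = 10 * (n_ops + 1) * (n_ops + 1) + 100
    log = []
    while True:
        rec = resolve_step(tg)
        if rec is None:
            return log
        log.append(rec)
        if len(log) > budget:
            raise ExchangeError("cycle resolution did not terminate")


def optimize_trajectory(
    initial: Genome, ops: List[Operation]
) -> Tuple[List[Operation], List[ExchangeRecord]]:
    """Shorten ``ops`` by iterated active-cycle resolution.

    Returns a trajectory with the same endpoints, at most as many DCJs and
    exactly as many duplications, together with the log of exchanges.  For a
    DCJ-only input the result is an optimal (minimum-length) trajectory.
    """
    tg = TrajectoryGraph.build(initial, ops)
    target = tg.sink_contents()
    log = optimize_graph(tg)
    new_ops = tg.extract_sorting_path()
    final = tg.replay(new_ops)
    counts: dict = {}
    from .genome_model import content_key

    for a in final:
        k = content_key(a)
        counts[k] = counts.get(k, 0) + 1
    if counts != target:
        raise CorruptGraphError("optimized trajectory changed the final genome")
    return new_ops, log
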