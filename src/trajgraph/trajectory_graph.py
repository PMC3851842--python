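"""The trajectory graph: a DAG encoding an evolutionary trajectory.

Given an initial genome X and a trajectory P = (p_1 .. p_n) of DCJ and
duplication operations, the trajectory graph G(P) contains one *adjacency
node* per adjacency instance ever present along the trace and one *operation
node* per operation, with a directed edge from each input adjacency node to
the operation node and from the operation node to each output adjacency node.
Adjacency nodes of indegree 0 form the adjacency set of X, those of outdegree
0 form the adjacency set of the final genome Y, and every other adjacency
node has indegree 1 and outdegree 1.  The graph is acyclic, and any
topological order of its operation nodes is a valid trajectory from X to Y.

Duplication nodes consume the original segment adjacencies and re-emit fresh
nodes with identical content via *inactive* edges (an edge is active iff its
far-end adjacency was actually changed by the operation).  This keeps the
dependency structure explicit, which both the active-cycle search and the
tree/cycle accounting rely on.

An *active cycle* is a pair of node-disjoint all-active directed paths from a
common top operation node to a common bottom operation node; the bottom node
is necessarily a DCJ (a duplication node has at most one active in-edge).
Active cycles are exactly the structures that the iterative improvement
algorithm in :mod:`trajgraph.cycle_resolution` removes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, List, Optional

import networkx as nx

from .errors import CorruptGraphError, TrajectoryConsistencyError
from .genome_model import (
    Adjacency,
    Genome,
    adjacency_token,
    content_key,
)
from .operations import (
    Dcj,
    Operation,
    active_pattern,
    apply_op,
    concretize_trajectory,
    graph_inputs,
    graph_outputs,
    parse_adjacency,
    parse_trajectory,
)


class AdjNode:
    """An adjacency *instance*; distinct nodes may share the same content."""

    __slots__ = ("uid", "content")

    def __init__(self, uid: int, content: Adjacency):
        self.uid = uid
        self.content = content

    def __repr__(self):
        return f"A{self.uid}:{adjacency_token(self.content)}"


class OpNode:
    """An operation instance at a position in (some retrieval of) the trajectory."""

    __slots__ = ("uid", "op")

    def __init__(self, uid: int, op: Operation):
        self.uid = uid
        self.op = op

    @property
    def is_dcj(self) -> bool:
        return isinstance(self.op, Dcj)

    def __repr__(self):
        return f"P{self.uid}:{self.op.token()}"


@dataclass
class Component:
    """A weakly connected component with its source/sink/interior partition."""

    nodes: list
    I: list  # indegree-0 adjacency nodes
    O: list  # outdegree-0 adjacency nodes
    A: list  # indegree-1/outdegree-1 adjacency nodes
    D: list  # DCJ operation nodes
    dups: list  # duplication operation nodes

    @property
    def trivial(self) -> bool:
        return len(self.nodes) == 1

    @property
    def op_nodes(self) -> list:
        return self.D + self.dups


@dataclass
class ActiveCycle:
    """An all-active cycle, stored as a cyclic alternating node sequence.

    ``bottom`` is the chosen local minimum (an operation node whose two
    incident cycle edges both point into it; necessarily a DCJ).  When the
    cycle is theta-shaped — exactly one local minimum, hence exactly one
    local maximum ``top`` with two node-disjoint directed all-active paths
    down to ``bottom`` — ``top``, ``left_path`` and ``right_path`` are set;
    for more crumpled cycles (several minima) they are ``None`` and the
    exchange machinery first straightens the cycle by reducing its number
    of minima.
    """

    seq: list  # cyclic sequence, ops and adjacency nodes alternating
    bottom: OpNode
    n_minima: int
    top: Optional[OpNode] = None
    left_path: Optional[list] = None  # theta only: top .. bottom inclusive
    right_path: Optional[list] = None

    @property
    def size(self) -> int:
        """Number of operation nodes on the cycle."""
        return sum(1 for n in self.seq if isinstance(n, OpNode))

    @property
    def is_theta(self) -> bool:
        return self.n_minima == 1


class TrajectoryGraph:
    """Mutable trajectory graph over a networkx DiGraph.

    Edges carry a boolean ``active`` attribute.  Node identity is by object
    (instances), never by adjacency content.
    """

    def __init__(self, initial: Genome):
        self.g = nx.DiGraph()
        self.initial = initial
        self._uid = 0
        # frontier: content -> sink AdjNode, i.e. the current state S_k
        self._frontier: dict = {}
        for content in initial.adjacencies():
            node = self.new_adj_node(content)
            self.g.add_node(node)
            self._frontier[content] = node

    # -- construction -------------------------------------------------------

    def new_uid(self) -> int:
        self._uid += 1
        return self._uid

    def new_adj_node(self, content: Adjacency) -> AdjNode:
        return AdjNode(self.new_uid(), content)

    def new_op_node(self, op: Operation) -> OpNode:
        return OpNode(self.new_uid(), op)

    def add_operation(self, op: Operation, index: Optional[int] = None) -> OpNode:
        """Append one operation, consuming its inputs from the sink frontier."""
        pat = active_pattern(op)
        in_nodes = []
        for content in graph_inputs(op):
            node = self._frontier.pop(content, None)
            if node is None:
                raise TrajectoryConsistencyError(
                    f"input {adjacency_token(content)} not in current genome state",
                    op_index=index,
                )
            in_nodes.append(node)
        opn = self.new_op_node(op)
        self.g.add_node(opn)
        for node in in_nodes:
            self.g.add_edge(node, opn, active=node.content in pat.active_in)
        for content in graph_outputs(op):
            out = self.new_adj_node(content)
            self.g.add_edge(opn, out, active=content in pat.active_out)
            self._frontier[content] = out
        return opn

    @classmethod
    def build(cls, initial: Genome, ops: Iterable[Operation]) -> "TrajectoryGraph":
        ops = concretize_trajectory(initial.adjacencies(), list(ops))
        tg = cls(initial)
        for k, op in enumerate(ops):
            tg.add_operation(op, index=k)
        return tg

    # -- queries ------------------------------------------------------------

    def adjacency_nodes(self) -> list:
        return [n for n in self.g.nodes if isinstance(n, AdjNode)]

    def op_nodes(self) -> list:
        return sorted(
            (n for n in self.g.nodes if isinstance(n, OpNode)), key=lambda n: n.uid
        )

    def dcj_count(self) -> int:
        return sum(1 for n in self.op_nodes() if n.is_dcj)

    def dup_count(self) -> int:
        return sum(1 for n in self.op_nodes() if not n.is_dcj)

    def sources(self) -> list:
        """Adjacency nodes of indegree 0 (the adjacency set of X)."""
        return [
            n for n in self.g.nodes
            if isinstance(n, AdjNode) and self.g.in_degree(n) == 0
        ]

    def sinks(self) -> list:
        """Adjacency nodes of outdegree 0 (the adjacency set of Y)."""
        return [
            n for n in self.g.nodes
            if isinstance(n, AdjNode) and self.g.out_degree(n) == 0
        ]

    def sink_contents(self) -> dict:
        """Cap-insensitive content multiset of the sinks."""
        counts: dict = {}
        for n in self.sinks():
            k = content_key(n.content)
            counts[k] = counts.get(k, 0) + 1
        return counts

    def is_dag(self) -> bool:
        return nx.is_directed_acyclic_graph(self.g)

    def producer(self, node: AdjNode) -> Optional[OpNode]:
        preds = list(self.g.predecessors(node))
        return preds[0] if preds else None

    def consumer(self, node: AdjNode) -> Optional[OpNode]:
        succs = list(self.g.successors(node))
        return succs[0] if succs else None

    def connected_components(self) -> List[Component]:
        comps = []
        for nodes in nx.weakly_connected_components(self.g):
            nodes = sorted(nodes, key=lambda n: n.uid)
            I, O, A, D, dups = [], [], [], [], []
            for n in nodes:
                if isinstance(n, OpNode):
                    (D if n.is_dcj else dups).append(n)
                else:
                    indeg, outdeg = self.g.in_degree(n), self.g.out_degree(n)
                    if indeg == 0:
                        I.append(n)
                    if outdeg == 0:
                        O.append(n)
                    if indeg == 1 and outdeg == 1:
                        A.append(n)
            comps.append(Component(nodes, I, O, A, D, dups))
        comps.sort(key=lambda c: c.nodes[0].uid)
        return comps

    # -- sorting-path retrieval ---------------------------------------------

    def extract_sorting_path(self) -> list:
        """A trajectory from any topological order of the operation nodes.

        Deterministic: among ready nodes the smallest uid goes first.
        """
        indeg = {n: self.g.in_degree(n) for n in self.g.nodes}
        ready = [(n.uid, n) for n in self.g.nodes if indeg[n] == 0]
        import heapq

        heapq.heapify(ready)
        ops, seen = [], 0
        while ready:
            _, n = heapq.heappop(ready)
            seen += 1
            if isinstance(n, OpNode):
                ops.append(n.op)
            for m in self.g.successors(n):
                indeg[m] -= 1
                if indeg[m] == 0:
                    heapq.heappush(ready, (m.uid, m))
        if seen != self.g.number_of_nodes():
            raise CorruptGraphError("directed cycle in trajectory graph")
        return ops

    def replay(self, ops: Optional[list] = None) -> set:
        """Replay a trajectory from X; returns the final adjacency state."""
        if ops is None:
            ops = self.extract_sorting_path()
        state = set(self.initial.adjacencies())
        for op in ops:
            state = apply_op(state, op)
        return state

    # -- invariants ----------------------------------------------------------

    def validate(self):
        """Full structural check; raises :class:`CorruptGraphError` on failure."""
        if not self.is_dag():
            raise CorruptGraphError("not a DAG")
        for n in self.g.nodes:
            if isinstance(n, AdjNode):
                if self.g.in_degree(n) > 1 or self.g.out_degree(n) > 1:
                    raise CorruptGraphError(f"adjacency node {n} has bad degree")
            else:
                gin = {}
                for content in graph_inputs(n.op):
                    gin[content] = gin.get(content, 0) + 1
                have = {}
                for m in self.g.predecessors(n):
                    have[m.content] = have.get(m.content, 0) + 1
                if gin != have:
                    raise CorruptGraphError(f"inputs of {n} disagree with its edges")
                gout = {}
                for content in graph_outputs(n.op):
                    gout[content] = gout.get(content, 0) + 1
                haveo = {}
                for m in self.g.successors(n):
                    haveo[m.content] = haveo.get(m.content, 0) + 1
                if gout != haveo:
                    raise CorruptGraphError(f"outputs of {n} disagree with its edges")

    # -- export ---------------------------------------------------------------

    def to_dot(self) -> str:
        """Graphviz DOT export: adjacency nodes as ellipses, operations as
        boxes, active edges solid, inactive dotted."""
        lines = ["digraph trajectory {"]
        for n in sorted(self.g.nodes, key=lambda n: n.uid):
            if isinstance(n, AdjNode):
                lines.append(
                    f'  n{n.uid} [shape=ellipse label="{adjacency_token(n.content)}"];'
                )
            else:
                kind = type(n.op).__name__
                lines.append(f'  n{n.uid} [shape=box label="{kind}#{n.uid}"];')
        for u, v, data in sorted(
            self.g.edges(data=True), key=lambda e: (e[0].uid, e[1].uid)
        ):
            style = "solid" if data["active"] else "dotted"
            lines.append(f"  n{u.uid} -> n{v.uid} [style={style}];")
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        nodes = []
        for n in sorted(self.g.nodes, key=lambda n: n.uid):
            if isinstance(n, AdjNode):
                nodes.append(
                    {"uid": n.uid, "type": "adjacency",
                     "content": adjacency_token(n.content)}
                )
            else:
                nodes.append({"uid": n.uid, "type": "operation", "op": n.op.token()})
        edges = [
            {"from": u.uid, "to": v.uid, "active": bool(d["active"])}
            for u, v, d in sorted(
                self.g.edges(data=True), key=lambda e: (e[0].uid, e[1].uid)
            )
        ]
        return json.dumps(
            {"initial": [adjacency_token(a) for a in self.initial.adjacencies()],
             "nodes": nodes, "edges": edges},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str, initial: Genome) -> "TrajectoryGraph":
        """Rebuild a graph dumped by :meth:`to_json` (round-trip check)."""
        data = json.loads(text)
        tg = cls.__new__(cls)
        tg.g = nx.DiGraph()
        tg.initial = initial
        tg._frontier = {}
        by_uid = {}
        maxuid = 0
        for nd in data["nodes"]:
            if nd["type"] == "adjacency":
                node = AdjNode(nd["uid"], parse_adjacency(nd["content"]))
            else:
                node = OpNode(nd["uid"], parse_trajectory(nd["op"])[0])
            by_uid[nd["uid"]] = node
            tg.g.add_node(node)
            maxuid = max(maxuid, nd["uid"])
        for ed in data["edges"]:
            tg.g.add_edge(by_uid[ed["from"]], by_uid[ed["to"]], active=ed["active"])
        tg._uid = maxuid
        for n in tg.sinks():
            tg._frontier[n.content] = n
        return tg


# ---------------------------------------------------------------------------
# Active-cycle search
# ---------------------------------------------------------------------------


def _active_preds(tg: TrajectoryGraph, node) -> list:
    return sorted(
        (u for u, _, d in tg.g.in_edges(node, data=True) if d["active"]),
        key=lambda n: n.uid,
    )


def _active_ancestor_paths(tg: TrajectoryGraph, start: AdjNode) -> dict:
    """Backward BFS over active edges from ``start``.

    Returns ``{node: next_node_towards_start}`` so that following ``next``
    pointers from any visited node yields an all-active directed path down to
    ``start``.
    """
    nxt = {start: None}
    queue = [start]
    while queue:
        node = queue.pop(0)
        for u in _active_preds(tg, node):
            if u not in nxt:
                nxt[u] = node
                queue.append(u)
    return nxt


def _path_from(nxt: dict, top) -> list:
    path = []
    n = top
    while n is not None:
        path.append(n)
        n = nxt[n]
    return path


def _find_theta_cycle(tg: TrajectoryGraph) -> Optional[ActiveCycle]:
    """Smallest theta-shaped active cycle (deterministically), or None.

    For each DCJ node ``b``, a theta cycle with bottom ``b`` exists iff the
    active-ancestor sets of its two input adjacency nodes share an operation
    node: taking any shared ancestor and walking the two paths down to ``b``,
    the topologically-latest node shared by both paths is a divergence point
    whose two path suffixes are node-disjoint.  Candidates are ranked by
    (cycle size, bottom uid, top uid).
    """
    best = None
    best_key = None
    for b in tg.op_nodes():
        if not b.is_dcj:
            continue
        preds = sorted(tg.g.predecessors(b), key=lambda n: n.uid)
        if len(preds) != 2:
            raise CorruptGraphError(f"DCJ node {b} must have two inputs")
        u1, u2 = preds
        nxt1 = _active_ancestor_paths(tg, u1)
        nxt2 = _active_ancestor_paths(tg, u2)
        common = [
            n for n in nxt1 if n in nxt2 and isinstance(n, OpNode)
        ]
        if not common:
            continue
        t0 = min(common, key=lambda n: n.uid)
        p1 = _path_from(nxt1, t0) + [b]
        p2 = _path_from(nxt2, t0) + [b]
        # reduce to the last divergence point: suffixes are then disjoint
        shared = (set(p1) & set(p2)) - {b}
        pos1 = {n: i for i, n in enumerate(p1)}
        v = max(shared, key=lambda n: pos1[n])
        left = p1[pos1[v]:]
        pos2 = {n: i for i, n in enumerate(p2)}
        right = p2[pos2[v]:]
        seq = left + right[-2:0:-1]
        cyc = ActiveCycle(
            seq=seq, bottom=b, n_minima=1, top=v,
            left_path=left, right_path=right,
        )
        key = (cyc.size, b.uid, v.uid)
        if best_key is None or key < best_key:
            best, best_key = cyc, key
    return best


def _find_crumpled_cycle(tg: TrajectoryGraph) -> Optional[ActiveCycle]:
    """Any all-active undirected cycle, oriented and annotated with minima.

    Used when no theta cycle exists: a cycle may still wind up and down
    through several local maxima and minima.  Candidates come from a cycle
    basis of the active subgraph and are ranked by (number of minima, size,
    op uids) for determinism.
    """
    h = nx.Graph()
    h.add_nodes_from(tg.g.nodes)
    for u, v, d in tg.g.edges(data=True):
        if d["active"]:
            h.add_edge(u, v)
    best = None
    best_key = None
    for nodes in nx.cycle_basis(h):
        k = len(nodes)
        minima = []
        for i, n in enumerate(nodes):
            if not isinstance(n, OpNode):
                continue
            prev_in = tg.g.has_edge(nodes[i - 1], n)
            next_in = tg.g.has_edge(nodes[(i + 1) % k], n)
            if prev_in and next_in:
                if not n.is_dcj:
                    raise CorruptGraphError(
                        "cycle minimum is not a DCJ node"
                    )
                minima.append(n)
        if not minima:
            raise CorruptGraphError("directed cycle in active subgraph")
        bottom = min(minima, key=lambda n: n.uid)
        op_uids = tuple(sorted(n.uid for n in nodes if isinstance(n, OpNode)))
        key = (len(minima), len(op_uids), op_uids)
        if best_key is None or key < best_key:
            best_key = key
            best = ActiveCycle(seq=list(nodes), bottom=bottom,
                               n_minima=len(minima))
    return best


def find_active_cycle(tg: TrajectoryGraph) -> Optional[ActiveCycle]:
    """Find an active cycle to resolve, preferring theta-shaped ones."""
    cyc = _find_theta_cycle(tg)
    if cyc is not None:
        return cyc
    return _find_crumpled_cycle(tg)
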