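"""Adjacency graph between two genomes and the DCJ distance |X| - c.

For adjacency sets X and Y over the same extremity set (each extremity
appearing exactly once per genome), the adjacency graph is the bipartite
multigraph linking u in X and v in Y by one edge per shared extremity.
Every node then has degree 2, the graph decomposes into node-disjoint
cycles, and the minimum number of DCJs transforming X into Y is |X| - c
with c the number of cycles.

The |X| - c formula requires unique extremities, which null extremities of
linear chromosomes violate; the default here is to reject genomes with
telomeres.  ``match_telomeres=True`` enables an approximate regime that
pairs the k-th cap of X with the k-th cap of Y in serialisation order.

Also provided: a (bidirectional) breadth-first search over the DCJ
neighbourhood as an exhaustive small-instance distance oracle, and the
tree/cycle correspondence checks used to certify optimality of DCJ-only
trajectories (a component C of a DCJ-only trajectory graph is a tree iff
|D(C)| = |I(C)| - 1, and a tree iff the adjacency graph on I(C), O(C) has
exactly one cycle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

import networkx as nx

from .errors import IncomparableGenomesError
from .genome_model import (
    Adjacency,
    Extremity,
    Genome,
    null_extremity,
    sorted_adjacencies,
)
from .operations import Dcj
from .trajectory_graph import Component, TrajectoryGraph


@dataclass
class AdjacencyGraph:
    """Bipartite multigraph between two adjacency sets."""

    left: list
    right: list
    graph: nx.MultiGraph

    @property
    def cycles(self) -> List[list]:
        """Connected components; with unique extremities each is a cycle."""
        return sorted(
            (sorted(c, key=str) for c in nx.connected_components(self.graph)),
            key=str,
        )

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def cycle_lengths(self) -> List[int]:
        """Edge count of every cycle, in a deterministic order."""
        out = []
        for comp in self.cycles:
            sub = self.graph.subgraph(comp)
            out.append(sub.number_of_edges())
        return sorted(out)


def _renumber_caps(adjs: list) -> list:
    """Give the caps of one genome serial identities 1..k in canonical order."""
    adjs = sorted_adjacencies(adjs)
    cap = 0
    out = []
    for a in adjs:
        new = set()
        for e in sorted(a, key=Extremity.sort_key):
            if e.is_null:
                cap += 1
                new.add(null_extremity(cap))
            else:
                new.add(e)
        out.append(frozenset(new))
    return out


def build_adjacency_graph(
    X: Iterable[Adjacency], Y: Iterable[Adjacency], match_telomeres: bool = False
) -> AdjacencyGraph:
    """The bipartite multigraph A = {X, Y, E}, one edge per shared extremity."""
    X, Y = list(X), list(Y)
    has_null = any(e.is_null for a in X + Y for e in a)
    if has_null:
        if not match_telomeres:
            raise IncomparableGenomesError(
                "genomes with telomeres need match_telomeres=True (approximate)"
            )
        X, Y = _renumber_caps(X), _renumber_caps(Y)
    else:
        X, Y = sorted_adjacencies(X), sorted_adjacencies(Y)

    def ext_index(adjs, side):
        idx = {}
        for i, a in enumerate(adjs):
            for e in a:
                if e in idx:
                    raise IncomparableGenomesError(
                        f"extremity {e} not unique on side {side}"
                    )
                idx[e] = i
        return idx

    xi, yi = ext_index(X, "X"), ext_index(Y, "Y")
    if set(xi) != set(yi):
        raise IncomparableGenomesError("extremity sets differ")

    g = nx.MultiGraph()
    left = [("X", i) for i in range(len(X))]
    right = [("Y", i) for i in range(len(Y))]
    g.add_nodes_from(left)
    g.add_nodes_from(right)
    for e in sorted(xi, key=Extremity.sort_key):
        g.add_edge(("X", xi[e]), ("Y", yi[e]), extremity=e)
    return AdjacencyGraph(left=X, right=Y, graph=g)


def dcj_distance(
    X: Iterable[Adjacency], Y: Iterable[Adjacency], match_telomeres: bool = False
) -> int:
    """The DCJ distance |X| - c between two adjacency sets."""
    X = list(X)
    ag = build_adjacency_graph(X, Y, match_telomeres=match_telomeres)
    return len(X) - ag.n_cycles


def dcj_distance_genomes(a: Genome, b: Genome, match_telomeres: bool = False) -> int:
    return dcj_distance(a.adjacencies(), b.adjacencies(), match_telomeres=match_telomeres)


# ---------------------------------------------------------------------------
# Exhaustive search oracle (tiny instances)
# ---------------------------------------------------------------------------


def _neighbours(state: frozenset) -> list:
    adjs = sorted_adjacencies(state)
    out = []
    for i in range(len(adjs)):
        for j in range(i + 1, len(adjs)):
            for o1, o2 in Dcj.outcomes(adjs[i], adjs[j]):
                new = set(state)
                new.discard(adjs[i])
                new.discard(adjs[j])
                new.add(o1)
                new.add(o2)
                out.append(frozenset(new))
    return out


def bfs_dcj_distance(
    X: Iterable[Adjacency], Y: Iterable[Adjacency], limit: int = 8
) -> Optional[int]:
    """Exact DCJ distance by bidirectional BFS; None if beyond ``limit``.

    Intended for genomes of at most ~6 genes without telomeres; the state
    space grows far too quickly beyond that.
    """
    start, goal = frozenset(X), frozenset(Y)
    if start == goal:
        return 0
    front_a, front_b = {start: 0}, {goal: 0}
    layer_a, layer_b = [start], [goal]
    dist = 0
    while dist < limit:
        # expand the smaller frontier
        if len(layer_a) <= len(layer_b):
            layer, front, other = layer_a, front_a, front_b
        else:
            layer, front, other = layer_b, front_b, front_a
        dist += 1
        new_layer = []
        for state in layer:
            d = front[state]
            for nb in _neighbours(state):
                if nb in other:
                    return d + 1 + other[nb]
                if nb not in front:
                    front[nb] = d + 1
                    new_layer.append(nb)
        if layer is layer_a:
            layer_a = new_layer
        else:
            layer_b = new_layer
        if not new_layer:
            return None
    return None


# ---------------------------------------------------------------------------
# Structure checks on DCJ-only trajectory graphs
# ---------------------------------------------------------------------------


def component_is_tree(tg: TrajectoryGraph, comp: Component) -> bool:
    sub = tg.g.subgraph(comp.nodes)
    return sub.number_of_edges() == sub.number_of_nodes() - 1


def check_tree_count_criterion(tg: TrajectoryGraph, comp: Component) -> bool:
    """Tree <=> |D(C)| = |I(C)| - 1, for components of DCJ-only graphs."""
    return component_is_tree(tg, comp) == (len(comp.D) == len(comp.I) - 1)


def component_adjacency_graph(tg: TrajectoryGraph, comp: Component) -> AdjacencyGraph:
    """The adjacency graph A = {I(C), O(C), E} of one component.

    For a trivial component the single node is both a source and a sink, so
    A is two copies of one adjacency joined by two parallel edges: a cycle
    of length 2.  Cap identities are consistent within one trajectory graph,
    so telomeres need no re-matching here.
    """
    I = [n.content for n in comp.I]
    O = [n.content for n in comp.O]
    g = nx.MultiGraph()
    xi, yi = {}, {}
    for i, a in enumerate(I):
        g.add_node(("X", i))
        for e in a:
            xi[e] = i
    for i, a in enumerate(O):
        g.add_node(("Y", i))
        for e in a:
            yi[e] = i
    if set(xi) != set(yi):
        raise IncomparableGenomesError("component sources/sinks mismatch")
    for e in sorted(xi, key=Extremity.sort_key):
        g.add_edge(("X", xi[e]), ("Y", yi[e]), extremity=e)
    return AdjacencyGraph(left=I, right=O, graph=g)


def check_tree_cycle_correspondence(tg: TrajectoryGraph, comp: Component) -> bool:
    """Tree component <=> its adjacency graph consists of exactly one cycle."""
    ag = component_adjacency_graph(tg, comp)
    return component_is_tree(tg, comp) == (ag.n_cycles == 1)
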