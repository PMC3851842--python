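# Methods

## Model

A genome is a set of linear and circular chromosomes over signed genes.
Gene `g` has a tail `g_t` and a head `g_h`; `+g` reads tail→head.  Two
consecutive gene ends form an **adjacency**, an unordered pair of
extremities, so `(a, b)` and `(-b, -a)` are the same value while `(a, b)`
and `(b, a)` are not.  Linear chromosome ends are completed with **null
extremities** ("caps"), making a linear chromosome of n genes contribute
n + 1 adjacencies and a circular one n.  A genome with all-distinct genes is
uniquely encoded by its adjacency multiset.

Two operation classes are modelled as functions of adjacencies:

* **DCJ** — cut adjacencies `(a, b)`, `(c, d)` and rejoin as `(a, d), (c, b)`
  or `(a, -c), (-b, d)`; the third rejoining repairs the cuts and is not
  modelled.  DCJ subsumes inversions, translocations, fusions, fissions and
  (de)circularisations.
* **Segmental duplication** — copy a contiguous segment `(g_1..g_n)`
  (identified by its n − 1 internal adjacencies) and either insert the copy,
  forward or inverted, at a target adjacency `(a, b)` (type 1), or close the
  copy into a new circular chromosome (type 2).  Originals are untouched;
  copies receive fresh copy indices, serialised `g'`, `g''`, …

## Trajectory graph

For a trajectory P from X to Y the trajectory graph G(P) contains one
adjacency node per adjacency *instance* along the trace and one operation
node per operation, with edges input-node → op → output-node.  Indegree-0
adjacency nodes are exactly X, outdegree-0 nodes exactly Y, every other
adjacency node has indegree 1 and outdegree 1, the graph is acyclic, and any
topological order of the operation nodes is an equivalent trajectory.

Duplication nodes consume the original segment adjacencies and re-emit
equal-content instances, so the dependency is an explicit (inactive) edge.
An edge is **active** iff the adjacency at its far end was changed by the
operation: all four DCJ edges; the target in-edge and the two junction
out-edges of an insert-duplication; only the circle-closing out-edge of a
circular duplication.

## Cycle resolution

An all-active cycle witnesses redundant rearrangements.  Oriented inside
the DAG, a cycle alternates between local maxima (operation nodes with both
cycle edges leaving) and local minima (both entering).  A minimum has two
active in-edges and is therefore always a DCJ node.

The engine repeatedly finds a cycle and applies one of:

* **Theta exchange** (one minimum, cycle size > 2): view the bottom DCJ and
  its on-cycle parent as a supernode with three inputs and three outputs and
  rewrite it as two new operations with the same boundary; the first takes
  the two supernode inputs linked in the cycle, the second leaves the cycle.
  With a DCJ parent both replacements are DCJs; with an insert-duplication
  parent (entered through its target) the replacement is a DCJ followed by a
  re-targeted duplication.  Cycle size shrinks by one.
* **Straightening exchange** (several minima): the same supernode rewrite
  applies when the chosen parent is a local *maximum*; the first input of
  the new leading DCJ is then chosen by feasibility rather than by cycle
  position.  The pair of old nodes (one maximum, one minimum) becomes two
  intermediate nodes, so the cycle keeps its size but loses one
  maximum/minimum pair, monotonically straightening towards the theta shape.
  This case is this package's extension: crumpled cycles do occur (random
  DCJ-only trajectories produce them) and theta-only resolution can
  otherwise terminate prematurely on a non-optimal trajectory.
* **Base cases** (theta of size 2): two DCJs whose supernode input and
  output differ collapse to one DCJ, an inverse pair to nothing; an
  insert-duplication whose junctions feed a DCJ collapses to the inverted
  insertion at the same target, or, when the DCJ restores the target
  adjacency, to a circular duplication of the segment.

Parent choice: if one of the bottom's two cycle-parents lies on a directed
path to the other, the descendant is taken (ties by node id).  This both
prevents the rewrite from closing a directed cycle and guarantees the four
cut ends handled by each new DCJ are distinct.  Every mutation is followed
by an acyclicity check and, in the tests, by degree/content validation and a
replay of the whole graph.

Each base resolution removes one or two DCJ nodes and never changes the
number of duplications; exchanges keep the operation count and strictly
decrease the (minima, size) pair of the worked cycle, so the driver
terminates.  For DCJ-only input the final graph is a forest and the final
length equals the adjacency-graph distance |X| − c (verified against an
exhaustive bidirectional BFS on small instances).  With duplications the
procedure is an improvement heuristic: no active cycle remains, but a
cycle-free graph is not a certificate of global optimality.

## Adjacency-graph oracle

The classical adjacency graph links u ∈ X and v ∈ Y by one edge per shared
extremity; with unique extremities it decomposes into cycles and the DCJ
distance is |X| − c.  The formula assumes unique extremities, which null
extremities violate, so the oracle rejects genomes with telomeres by
default; `match_telomeres=True` pairs the k-th caps of the two genomes in
serialisation order and is flagged approximate.  Distance tests therefore
use circular genomes.  Inside one trajectory graph cap identities are
consistent, so per-component adjacency graphs (the tree ⇔ one-cycle
correspondence, and |D(C)| = |I(C)| − 1 for trees) need no re-matching.

## Numerical / representational choices

* Adjacency contents are frozensets of extremities, which makes the
  `(a, b) ≡ (-b, -a)` identification automatic; graph nodes are instances
  with serial ids and are never merged by content (duplicated genes and
  repeated states make equal contents common).
* Null caps carry per-instance ids so telomeres stay distinct node
  instances; genome-level comparison strips them.
* The unordered target pair of an insert-duplication leaves a binary
  ambiguity (which end receives the segment's first copy); it is resolved by
  sorting the two extremities, and the remaining degree of freedom is
  exactly the `inverted` flag.
* Both-null adjacencies are rejected at the genome level (no empty linear
  chromosomes) but allowed inside adjacency states: an exchange may create
  one as a transient intermediate, and the algebra treats caps as ordinary
  extremities.  The simulator never proposes DCJs with a both-null output,
  so simulated endpoint genomes are always realisable.
* All candidate enumerations (cycle search, supernode reconstruction,
  topological retrieval) sort by serial id or serialised adjacency before
  choosing, so results are reproducible across platforms and hash seeds.

## Simulator

`SimConfig` fixes the study conditions: `n_genes` gene families (default
10) over `n_chromosomes` chromosomes with a configurable circular fraction;
`n_dcj` uniform random DCJs (rejecting both-null outputs); `n_dup`
duplications of contiguous segments of length 1..`dup_segment_max`
(default 3), type 2 with probability `dup_circular_fraction` (default 0.3);
and `redundancy_pairs` planted DCJ/inverse-DCJ pairs inserted at random
positions, which leave the final genome unchanged and create exactly the
active cycles the resolution engine removes.  One `random.Random(seed)`
instance drives all draws.

The generator emulates gene-order evolution at desk scale, not real data:
gene families are equal-sized and pre-matched, there are no losses, novel
insertions or whole-genome duplications, and rates are uniform.  Passing
tests therefore certify the combinatorial machinery (construction,
invariants, convergence), not biological realism of inferred scenarios.

One modelling gap is inherited from the adjacency-only encoding: a
single-gene segment has no internal adjacency, so duplicating a single
*copied* gene would give the new operation no graph dependency on the
operation that created the copy, and reordering could then break replay.
The simulator never emits such segments; single-gene duplications of
original genes are safe and supported (a single-gene type-2 duplication
produces the one-gene circle `{g'_h, g'_t}`).

## Test problem sizes

The suites run genomes of 4–30 genes with trajectories up to ~20
operations: 200 mixed fixtures for the resolution invariants, 500 circular
DCJ-only fixtures for convergence (those with ≤ 6 genes also checked
against exhaustive BFS), and 60 fixtures for the forest/optimality
correspondence.  These sizes exercise every exchange and base-case kind
while keeping the default test run around a few seconds.

## Known limitations

* Optimality is guaranteed only for DCJ-only trajectories; with
  duplications the result is locally irreducible (no active cycle), but a
  cycle-free graph does not certify global optimality — duplications can be
  exploited to build shorter scenarios the exchanges cannot reach.
* The telomere-matching distance mode is approximate by construction.
* Finding good *initial* trajectories is out of scope; the package improves
  a given one.
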