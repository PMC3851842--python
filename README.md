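# trajgraph

Trajectory graphs for sorting genomes under DCJ rearrangements and
segmental duplications.

Comparative genomics usually summarises the difference between two gene
orders as a single *distance*; reconstructing the actual **evolutionary
trajectory** — which inversions, translocations and duplications happened,
and in what order — is harder, and any proposed trajectory may contain
redundant rearrangements.  `trajgraph` is for researchers in genome
rearrangement who have candidate trajectories (from simulation, sampling or
heuristics) and want to shorten and analyse them.

The core data structure is the **trajectory graph** G(P): a DAG with one
node per adjacency instance and one per operation, edges from each
operation's input adjacencies to it and from it to its outputs.  Sources
are the adjacency set of the start genome X, sinks that of the final genome
Y, and any topological order of the operation nodes is an equivalent
trajectory.  Edges are *active* when the far-end adjacency was actually
changed by the operation.  Redundant rearrangements show up as **active
cycles**, which the package removes by iterated local exchanges of the
cycle's bottom DCJ with a parent operation, finishing each cycle with a
two-operation base case that deletes at least one DCJ while preserving both
endpoint genomes and the number of duplications.

For DCJ-only trajectories the procedure converges to an optimal trajectory
of length exactly

    d_DCJ(X, Y) = |X| − c,

where c is the number of cycles of the bipartite adjacency graph between
the two adjacency sets (one edge per shared extremity); equivalently, a
DCJ-only trajectory is optimal iff its trajectory graph is a forest.  With
duplications the result is an improvement heuristic: no active cycle
remains, but global optimality is not guaranteed.  See `docs/methods.md`
for the model, the exchange rules (including the handling of crumpled,
non-theta cycles) and the limitations.

## Worked example

Start from the linear genome `(1, 2, 3, 4, 5)`.  A duplication inserts a
copy of `(2, 3, 4)` at the right end, then two DCJs invert `(4, 5, 2')` and
`(1, 2)`:

```sh
$ cat A.grimm
>A
1 2 3 4 5 $

$ cat P.ops
DUPI segment=(2,3,4) target={5_h,0#2} inverted=0
DCJ {3_h,4_t} {2'_h,3'_t} -> {3_h,2'_h} {4_t,3'_t}
DCJ {0#1,1_t} {2_h,3_t} -> {0#1,2_h} {1_t,3_t}

$ trajgraph build-graph A.grimm P.ops
{"n_operations": 3, "n_dcj": 2, "n_dup": 1, "n_components": 3, "n_trivial": 2}
```

The final genome, reconstructed from the graph's sinks, is
`-2 -1 3 -2' -5 -4 3' 4' $`.  The two trivial components are the
adjacencies `{1_h,2_t}` and `{4_h,5_t}` — the only two the whole trajectory
never touched.  This trajectory is already cycle-free, so optimisation
leaves it alone:

```sh
$ trajgraph optimize --genome A.grimm --trajectory P.ops --out P_opt.ops
{"input_length": 3, "output_length": 3, "dcj_before": 2, "dcj_after": 2,
 "dup_before": 1, "dup_after": 1, "cycles_resolved": 0, "exchanges": 0,
 "log_path": null}
```

(`output_length == input_length` and `cycles_resolved == 0`: nothing was
redundant.  On a trajectory with planted redundancy, `dcj_after` drops to
the DCJ distance and the JSON-lines log lists every exchange.)

DCJ distance between two circular genomes — one inversion apart, so the
adjacency graph has a single cycle and the distance is 2 − 1 = 1:

```sh
$ trajgraph distance B1.grimm B2.grimm   # (1 2) vs (1 -2)
1
```

`trajgraph simulate` generates seeded random genomes and trajectories
(optionally inflated with DCJ/inverse-DCJ pairs) for experimentation, and
`build-graph --dot` exports the graph with the standard legend: ellipses
for adjacencies, boxes for operations, solid edges active, dotted inactive.

The same functionality is available as a library:

```python
import trajgraph as tj

genome = tj.parse_genome(">A\n1 2 3 4 5 $")
ops = tj.parse_trajectory(open("P.ops").read())
shorter, log = tj.optimize_trajectory(genome, ops)
```

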