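"""Seeded generators for genomes, trajectories and redundancy-inflated
trajectories.

All randomness flows through one explicit :class:`random.Random` instance
derived from ``SimConfig.seed``; candidate sets are always sorted before
sampling so runs are reproducible across platforms and hash seeds.

The generator emulates the study conditions the trajectory-graph machinery
is meant for: moderate genomes (tens of gene families, one or a few
chromosomes, both topologies), trajectories mixing DCJs with type-1 and
type-2 segmental duplications of short segments, and "inflated" trajectories
carrying planted DCJ/inverse-DCJ pairs, which are exactly the redundancies
that active-cycle resolution removes.
"""

from __future__ import annotations

from dataclasses import dataclass
from random import Random
from typing import Optional, Tuple

from .errors import ConfigError, SimulationError
from .genome_model import (
    Chromosome,
    GeneId,
    Genome,
    SignedGene,
    adjacencies_to_genome,
    is_null_null,
    sorted_adjacencies,
)
from .operations import (
    Dcj,
    DupCircular,
    DupInsert,
    Operation,
    apply_op,
    concretize_trajectory,
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated instance."""

    n_genes: int = 10
    n_chromosomes: int = 1
    circular_fraction: float = 0.0  # probability that a chromosome is circular
    n_dcj: int = 5
    n_dup: int = 0
    dup_segment_max: int = 3
    dup_circular_fraction: float = 0.3
    redundancy_pairs: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_chromosomes <= 0:
            raise ConfigError("need positive gene and chromosome counts")
        if self.n_genes < self.n_chromosomes:
            raise ConfigError("fewer genes than chromosomes")
        if min(self.n_dcj, self.n_dup, self.redundancy_pairs) < 0:
            raise ConfigError("operation counts must be non-negative")
        if self.dup_segment_max < 1:
            raise ConfigError("dup_segment_max must be >= 1")


def random_genome(cfg: SimConfig, rng: Optional[Random] = None) -> Genome:
    """A genome with families 1..n_genes split over the requested chromosomes."""
    rng = rng or Random(cfg.seed)
    genes = [
        SignedGene(GeneId(str(i + 1)), rng.choice((1, -1)))
        for i in range(cfg.n_genes)
    ]
    # split into n_chromosomes non-empty runs
    cuts = sorted(rng.sample(range(1, cfg.n_genes), cfg.n_chromosomes - 1))
    chroms = []
    prev = 0
    for cut in cuts + [cfg.n_genes]:
        circular = rng.random() < cfg.circular_fraction
        chroms.append(Chromosome(tuple(genes[prev:cut]), circular=circular))
        prev = cut
    return Genome(chroms)


def _random_dcj(state: set, rng: Random) -> Dcj:
    adjs = sorted_adjacencies(state)
    if len(adjs) < 2:
        raise SimulationError("too few adjacencies for a DCJ")
    for _ in range(200):
        a, b = rng.sample(adjs, 2)
        outcomes = Dcj.outcomes(a, b)
        rng.shuffle(outcomes)
        for out in outcomes:
            if not any(is_null_null(x) for x in out):
                return Dcj((a, b), tuple(out))
    raise SimulationError("no valid DCJ found")


def _segment_candidates(genome: Genome, max_len: int) -> list:
    """All contiguous runs of length 1..max_len, wrapping on circular chromosomes."""
    cands = []
    for ci, chrom in enumerate(genome.chromosomes):
        n = len(chrom.genes)
        for start in range(n):
            top = min(max_len, n if chrom.circular else n - start)
            for length in range(1, top + 1):
                if chrom.circular:
                    run = tuple(
                        chrom.genes[(start + k) % n] for k in range(length)
                    )
                    if length == n:
                        continue  # whole-chromosome copies excluded
                else:
                    run = chrom.genes[start : start + length]
                # a single duplicated gene gives the copy no graph anchor to
                # the operation that created it; skip those segments
                if length == 1 and run[0].gene.copy > 0:
                    continue
                cands.append(run)
    return cands


def _random_dup(genome: Genome, state: set, cfg: SimConfig, rng: Random) -> Operation:
    cands = _segment_candidates(genome, cfg.dup_segment_max)
    if not cands:
        raise SimulationError("no duplicable segment")
    rng.shuffle(cands)
    for segment in cands:
        if rng.random() < cfg.dup_circular_fraction:
            return DupCircular(segment=segment)
        internal = set()
        seg_adjs = DupCircular(segment=segment).segment_adjacencies()
        for a in seg_adjs:
            internal |= set(a)
        targets = [
            a
            for a in sorted_adjacencies(state)
            if a not in seg_adjs and not (internal & set(a))
        ]
        if not targets:
            continue
        return DupInsert(
            segment=segment,
            target=rng.choice(targets),
            inverted=rng.random() < 0.5,
        )
    raise SimulationError("no valid duplication found")


def random_trajectory(genome: Genome, cfg: SimConfig, rng: Optional[Random] = None) -> list:
    """A valid trajectory with cfg.n_dcj DCJs and cfg.n_dup duplications."""
    rng = rng or Random(cfg.seed + 1)
    schedule = ["dcj"] * cfg.n_dcj + ["dup"] * cfg.n_dup
    rng.shuffle(schedule)
    state = set(genome.adjacencies())
    current = genome
    ops: list = []
    for what in schedule:
        if what == "dcj":
            op = _random_dcj(state, rng)
        else:
            op = _random_dup(current, state, cfg, rng)
        ops, state = _append(genome, ops, op)
        current = adjacencies_to_genome(state)
    return ops


def _append(genome: Genome, ops: list, op: Operation) -> Tuple[list, set]:
    ops = concretize_trajectory(genome.adjacencies(), ops + [op])
    state = set(genome.adjacencies())
    for o in ops:
        state = apply_op(state, o)
    return ops, state


def inflate_with_redundancy(
    genome: Genome, ops: list, cfg: SimConfig, rng: Optional[Random] = None
) -> list:
    """Insert ``cfg.redundancy_pairs`` DCJ/inverse-DCJ pairs at random points.

    The final genome is unchanged: each planted pair cancels locally, and
    the suffix of the trajectory sees the state it saw before.
    """
    rng = rng or Random(cfg.seed + 2)
    ops = concretize_trajectory(genome.adjacencies(), list(ops))
    for _ in range(cfg.redundancy_pairs):
        k = rng.randint(0, len(ops))
        state = set(genome.adjacencies())
        for o in ops[:k]:
            state = apply_op(state, o)
        d = _random_dcj(state, rng)
        ops = ops[:k] + [d, d.inverse()] + ops[k:]
    return ops
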