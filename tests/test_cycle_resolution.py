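"""Exchanges, base-case resolutions, and the iterative improvement driver."""

import pytest

import trajgraph as tj
from trajgraph.adjacency_oracle import dcj_distance
from trajgraph.cycle_resolution import choose_parent, optimize_trajectory, resolve_step
from trajgraph.genome_model import content_key
from trajgraph.operations import Dcj, DupCircular, DupInsert, parse_adjacency
from trajgraph.simulator import (
    SimConfig,
    inflate_with_redundancy,
    random_genome,
    random_trajectory,
)
from trajgraph.trajectory_graph import TrajectoryGraph, find_active_cycle


def adj(tok):
    return parse_adjacency(tok)


def counts(contents):
    out = {}
    for c in contents:
        k = content_key(c)
        out[k] = out.get(k, 0) + 1
    return out


def mixed_instance(seed, redundancy=2):
    cfg = SimConfig(n_genes=8, n_chromosomes=1 + seed % 2,
                    circular_fraction=0.4, n_dcj=4, n_dup=2,
                    dup_segment_max=3, redundancy_pairs=redundancy, seed=seed)
    g = random_genome(cfg)
    ops = inflate_with_redundancy(g, random_trajectory(g, cfg), cfg)
    return g, ops


class TestChooseParent:
    def test_descendant_parent_preferred(self):
        # chain of three DCJs forming a size-3 cycle: the parent on the
        # directed path from the other parent must be chosen
        g = tj.parse_genome(">A\n1 2 3 4 @")
        p1 = Dcj((adj("{1_h,2_t}"), adj("{2_h,3_t}")),
                 (adj("{1_h,3_t}"), adj("{2_h,2_t}")))
        p2 = Dcj((adj("{2_h,2_t}"), adj("{3_h,4_t}")),
                 (adj("{2_h,4_t}"), adj("{3_h,2_t}")))
        p3 = Dcj((adj("{1_h,3_t}"), adj("{3_h,2_t}")),
                 (adj("{1_h,2_t}"), adj("{3_h,3_t}")))
        tg = TrajectoryGraph.build(g, [p1, p2, p3])
        cyc = find_active_cycle(tg)
        assert cyc is not None and cyc.size == 3
        parent = choose_parent(cyc, tg)
        assert parent is not cyc.top  # never exchanges with the top

    @pytest.mark.parametrize("seed", range(30))
    def test_exchange_never_creates_directed_cycle(self, seed):
        g, ops = mixed_instance(seed)
        tg = TrajectoryGraph.build(g, ops)
        while True:
            rec = resolve_step(tg)
            if rec is None:
                break
            assert tg.is_dag()


class TestExchanges:
    def test_dcj_dcj_exchange_shrinks_cycle_and_keeps_counts(self):
        g = tj.parse_genome(">A\n1 2 3 4 @")
        p1 = Dcj((adj("{1_h,2_t}"), adj("{2_h,3_t}")),
                 (adj("{1_h,3_t}"), adj("{2_h,2_t}")))
        p2 = Dcj((adj("{2_h,2_t}"), adj("{3_h,4_t}")),
                 (adj("{2_h,4_t}"), adj("{3_h,2_t}")))
        p3 = Dcj((adj("{1_h,3_t}"), adj("{3_h,2_t}")),
                 (adj("{1_h,2_t}"), adj("{3_h,3_t}")))
        tg = TrajectoryGraph.build(g, [p1, p2, p3])
        before = counts(n.content for n in tg.sinks())
        n_ops = len(tg.op_nodes())
        rec = resolve_step(tg)
        assert rec.kind == "dcj_dcj"
        assert rec.cycle_size_after == rec.cycle_size_before - 1
        assert len(tg.op_nodes()) == n_ops  # exchanges conserve op count
        tg.validate()
        assert counts(n.content for n in tg.sinks()) == before
        assert counts(tg.replay()) == before

    @pytest.mark.parametrize("seed", range(40))
    def test_exchange_replay_equivalence(self, seed):
        """Every mutation preserves the endpoint genomes (replay oracle)."""
        g, ops = mixed_instance(seed)
        tg = TrajectoryGraph.build(g, ops)
        target = counts(n.content for n in tg.sinks())
        while True:
            rec = resolve_step(tg)
            if rec is None:
                break
            tg.validate()
            assert counts(n.content for n in tg.sinks()) == target
            assert counts(tg.replay()) == target


class TestBaseCases:
    def test_inverse_pair_removed_entirely(self):
        g = tj.parse_genome(">A\n1 2 3 $")
        op = Dcj((adj("{1_h,2_t}"), adj("{2_h,3_t}")),
                 (adj("{1_h,2_h}"), adj("{2_t,3_t}")))
        new_ops, log = optimize_trajectory(g, [op, op.inverse()])
        assert new_ops == []
        assert [r.kind for r in log] == ["base_dcj_dcj"]

    def test_two_dcjs_with_distinct_io_become_one(self):
        g = tj.parse_genome(">A\n1 2 3 @")
        p1 = Dcj((adj("{1_h,2_t}"), adj("{2_h,3_t}")),
                 (adj("{1_h,2_h}"), adj("{2_t,3_t}")))
        p2 = Dcj((adj("{1_h,2_h}"), adj("{2_t,3_t}")),
                 (adj("{1_h,3_t}"), adj("{2_h,2_t}")))
        new_ops, log = optimize_trajectory(g, [p1, p2])
        assert len(new_ops) == 1
        assert isinstance(new_ops[0], Dcj)
        assert [r.kind for r in log] == ["base_dcj_dcj"]

    def test_dup_then_inverting_dcj_becomes_inverted_insert(self):
        g = tj.parse_genome(">A\n1 2 3 $")
        ops = tj.parse_trajectory(
            "DUPI segment=(2,3) target={3_h,0#2} inverted=0\n"
            "DCJ {3_h,2'_t} {3'_h,0#2} -> {3_h,3'_h} {2'_t,0#2}\n"
        )
        new_ops, log = optimize_trajectory(g, ops)
        assert len(new_ops) == 1
        assert isinstance(new_ops[0], DupInsert) and new_ops[0].inverted
        assert new_ops[0].target == adj("{3_h,0#2}")

    def test_dup_then_excising_dcj_becomes_circular_dup(self):
        g = tj.parse_genome(">A\n1 2 3 $")
        ops = tj.parse_trajectory(
            "DUPI segment=(2,3) target={3_h,0#2} inverted=0\n"
            "DCJ {3_h,2'_t} {3'_h,0#2} -> {3_h,0#2} {3'_h,2'_t}\n"
        )
        new_ops, log = optimize_trajectory(g, ops)
        assert len(new_ops) == 1
        assert isinstance(new_ops[0], DupCircular)
        assert new_ops[0].segment == ops[0].segment
        final = tj.adjacencies_to_genome(
            tj.TrajectoryGraph.build(g, new_ops).replay(new_ops)
        )
        assert final == tj.parse_genome(">B\n1 2 3 $\n2' 3' @")


class TestOptimizeTrajectory:
    def test_already_optimal_unchanged_length(self, example_genome, example_ops):
        new_ops, log = optimize_trajectory(example_genome, example_ops)
        assert len(new_ops) == len(example_ops)
        assert log == []

    @pytest.mark.parametrize("seed", range(25))
    def test_dcj_only_reaches_adjacency_graph_distance(self, seed):
        cfg = SimConfig(n_genes=5 + seed % 10, circular_fraction=1.0,
                        n_dcj=2 + seed % 5, redundancy_pairs=seed % 4, seed=seed)
        g = random_genome(cfg)
        ops = inflate_with_redundancy(g, random_trajectory(g, cfg), cfg)
        X = g.adjacencies()
        Y = [n.content for n in TrajectoryGraph.build(g, ops).sinks()]
        new_ops, _ = optimize_trajectory(g, ops)
        assert len(new_ops) == dcj_distance(X, Y)

    @pytest.mark.parametrize("seed", range(20))
    def test_mixed_strictly_shorter_same_dup_count(self, seed):
        g, ops = mixed_instance(seed, redundancy=2)
        n_dup = sum(not isinstance(o, Dcj) for o in ops)
        new_ops, log = optimize_trajectory(g, ops)
        assert len(new_ops) < len(ops)
        assert sum(not isinstance(o, Dcj) for o in new_ops) == n_dup
        # every base-case resolution strictly reduces the DCJ count
        dcj_now = sum(isinstance(o, Dcj) for o in ops)
        for rec in log:
            if rec.is_base:
                assert rec.dcj_count_after < dcj_now
            dcj_now = rec.dcj_count_after
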