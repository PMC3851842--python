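"""DCJ and duplication semantics, active-edge patterns, trajectory text I/O."""

import pytest

import trajgraph as tj
from trajgraph.genome_model import Extremity, GeneId
from trajgraph.operations import (
    Dcj,
    DupCircular,
    DupInsert,
    active_pattern,
    apply_dcj,
    apply_op,
    concretize_trajectory,
    format_trajectory,
    parse_adjacency,
    parse_trajectory,
)


def adj(tok):
    return parse_adjacency(tok)


def ext_multiset(adjs):
    out = []
    for a in adjs:
        out.extend(a)
    return sorted(out, key=Extremity.sort_key)


@pytest.fixture
def linear5():
    return tj.parse_genome(">A\n1 2 3 4 5 $")


class TestDcj:
    def test_two_nontrivial_outcomes(self):
        outs = Dcj.outcomes(adj("{1_h,2_t}"), adj("{3_h,4_t}"))
        assert len(outs) == 2
        as_sets = [frozenset(o) for o in outs]
        assert frozenset({adj("{1_h,3_h}"), adj("{2_t,4_t}")}) in as_sets
        assert frozenset({adj("{1_h,4_t}"), adj("{2_t,3_h}")}) in as_sets

    def test_repair_outcome_rejected(self):
        with pytest.raises(tj.InvalidOperationError):
            Dcj((adj("{1_h,2_t}"), adj("{3_h,4_t}")),
                (adj("{1_h,2_t}"), adj("{3_h,4_t}")))

    def test_extremity_conservation_enforced(self):
        with pytest.raises(tj.InvalidOperationError):
            Dcj((adj("{1_h,2_t}"), adj("{3_h,4_t}")),
                (adj("{1_h,3_h}"), adj("{2_t,5_t}")))

    def test_apply_removes_inputs_adds_outputs(self, linear5):
        state = set(linear5.adjacencies())
        op = Dcj((adj("{1_h,2_t}"), adj("{2_h,3_t}")),
                 (adj("{1_h,2_h}"), adj("{2_t,3_t}")))
        new = apply_dcj(state, op)
        assert adj("{1_h,2_h}") in new and adj("{1_h,2_t}") not in new
        assert ext_multiset(new) == ext_multiset(state)

    def test_apply_missing_input_raises(self, linear5):
        state = set(linear5.adjacencies())
        op = Dcj((adj("{1_h,3_t}"), adj("{2_h,2_t}")),
                 (adj("{1_h,2_t}"), adj("{2_h,3_t}")))
        with pytest.raises(tj.MissingAdjacencyError):
            apply_dcj(state, op)

    def test_involution_restores_state(self, linear5):
        state = set(linear5.adjacencies())
        op = Dcj((adj("{1_h,2_t}"), adj("{3_h,4_t}")),
                 (adj("{1_h,3_h}"), adj("{2_t,4_t}")))
        assert apply_dcj(apply_dcj(state, op), op.inverse()) == state

    def test_inversion_of_internal_segment(self):
        # inverting (4,5,2') inside (1,2,3,4,5,2',3',4')
        g = tj.parse_genome(">A\n1 2 3 4 5 2' 3' 4' $")
        state = set(g.adjacencies())
        op = Dcj((adj("{3_h,4_t}"), adj("{2'_h,3'_t}")),
                 (adj("{3_h,2'_h}"), adj("{4_t,3'_t}")))
        new = apply_dcj(state, op)
        got = tj.adjacencies_to_genome(new)
        assert got == tj.parse_genome(">B\n1 2 3 -2' -5 -4 3' 4' $")


class TestDupInsert:
    def seg(self, g, fams):
        by = {str(sg.gene): sg for c in g.chromosomes for sg in c.genes}
        return tuple(by[f] for f in fams)

    def test_insert_at_right_end(self, linear5):
        ops = concretize_trajectory(
            linear5.adjacencies(),
            [DupInsert(segment=self.seg(linear5, "234"),
                       target=adj("{5_h,0#2}"), inverted=False)],
        )
        state = apply_op(set(linear5.adjacencies()), ops[0])
        assert len(state) == 9
        got = tj.adjacencies_to_genome(state)
        assert got == tj.parse_genome(">B\n1 2 3 4 5 2' 3' 4' $")

    def test_inverted_insert(self, linear5):
        ops = concretize_trajectory(
            linear5.adjacencies(),
            [DupInsert(segment=self.seg(linear5, "234"),
                       target=adj("{5_h,0#2}"), inverted=True)],
        )
        state = apply_op(set(linear5.adjacencies()), ops[0])
        got = tj.adjacencies_to_genome(state)
        assert got == tj.parse_genome(">B\n1 2 3 4 5 -4' -3' -2' $")

    def test_single_gene_segment_adds_two_adjacencies(self, linear5):
        ops = concretize_trajectory(
            linear5.adjacencies(),
            [DupInsert(segment=self.seg(linear5, "3"),
                       target=adj("{5_h,0#2}"), inverted=False)],
        )
        state = apply_op(set(linear5.adjacencies()), ops[0])
        assert len(state) == len(linear5.adjacencies()) + 1
        assert tj.adjacencies_to_genome(state) == tj.parse_genome(
            ">B\n1 2 3 4 5 3' $"
        )

    def test_target_inside_segment_rejected(self, linear5):
        with pytest.raises(tj.OverlapError):
            DupInsert(segment=self.seg(linear5, "234"),
                      target=adj("{2_h,3_t}"), inverted=False)

    def test_noncontiguous_segment_rejected(self, linear5):
        op = DupInsert(
            segment=self.seg(linear5, "24"),
            copies=(GeneId("2", 1), GeneId("4", 1)),
            target=adj("{5_h,0#2}"), inverted=False,
        )
        with pytest.raises(tj.SegmentError):
            apply_op(set(linear5.adjacencies()), op)

    def test_originals_untouched(self, linear5):
        before = set(linear5.adjacencies())
        op = concretize_trajectory(
            linear5.adjacencies(),
            [DupInsert(segment=self.seg(linear5, "234"),
                       target=adj("{5_h,0#2}"), inverted=False)],
        )[0]
        after = apply_op(before, op)
        assert adj("{2_h,3_t}") in after and adj("{3_h,4_t}") in after


class TestDupCircular:
    def test_creates_circular_chromosome(self):
        g = tj.parse_genome(">A\n1 2 3 $")
        seg = tuple(c for c in g.chromosomes[0].genes if str(c.gene) in "23")
        op = concretize_trajectory(
            g.adjacencies(), [DupCircular(segment=seg)]
        )[0]
        state = apply_op(set(g.adjacencies()), op)
        got = tj.adjacencies_to_genome(state)
        assert got == tj.parse_genome(">B\n1 2 3 $\n2' 3' @")

    def test_single_gene_circle(self):
        g = tj.parse_genome(">A\n1 2 $")
        seg = (g.chromosomes[0].genes[1],)
        op = concretize_trajectory(g.adjacencies(), [DupCircular(segment=seg)])[0]
        state = apply_op(set(g.adjacencies()), op)
        closing = op.closing_adjacency()
        assert closing == adj("{2'_h,2'_t}")
        assert tj.adjacencies_to_genome(state) == tj.parse_genome(">B\n1 2 $\n2' @")


class TestActivePattern:
    def test_dcj_all_four_active(self):
        op = Dcj((adj("{1_h,2_t}"), adj("{3_h,4_t}")),
                 (adj("{1_h,3_h}"), adj("{2_t,4_t}")))
        pat = active_pattern(op)
        assert pat.active_in == frozenset(op.inputs)
        assert pat.active_out == frozenset(op.outputs)

    def test_dup_insert_one_in_two_out(self, linear5):
        by = {str(sg.gene): sg for c in linear5.chromosomes for sg in c.genes}
        op = concretize_trajectory(
            linear5.adjacencies(),
            [DupInsert(segment=(by["2"], by["3"], by["4"]),
                       target=adj("{5_h,0#2}"), inverted=False)],
        )[0]
        pat = active_pattern(op)
        assert pat.active_in == frozenset([op.target])
        assert pat.active_out == frozenset(op.junction_adjacencies())
        assert len(pat.active_out) == 2

    def test_dup_circular_single_active_out(self):
        g = tj.parse_genome(">A\n1 2 3 $")
        seg = g.chromosomes[0].genes[1:]
        op = concretize_trajectory(g.adjacencies(), [DupCircular(segment=seg)])[0]
        pat = active_pattern(op)
        assert pat.active_in == frozenset()
        assert pat.active_out == frozenset([op.closing_adjacency()])


class TestTrajectoryTextFormat:
    def test_round_trip(self, example_genome, example_ops):
        ops = concretize_trajectory(example_genome.adjacencies(), example_ops)
        text = format_trajectory(ops)
        again = parse_trajectory(text)
        assert again == ops
        assert format_trajectory(again) == text

    def test_bad_line_reports_position(self):
        with pytest.raises(tj.ParseError):
            parse_trajectory("FROB {1_h,2_t}")
        with pytest.raises(tj.ParseError):
            parse_trajectory("DCJ {1_h,2_t} {3_h,4_t}")

    def test_state_validity_preserved_along_worked_trajectory(
        self, example_genome, example_ops
    ):
        ops = concretize_trajectory(example_genome.adjacencies(), example_ops)
        state = set(example_genome.adjacencies())
        for op in ops:
            state = apply_op(state, op)
            seen = []
            for a in state:
                seen.extend(e for e in a if not e.is_null)
            assert len(seen) == len(set(seen))
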