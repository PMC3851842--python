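import pytest

import trajgraph as tj

# Worked example: a linear chromosome (1,2,3,4,5); a duplication inserts a
# copy of (2,3,4) at the right end, then one DCJ inverts (4,5,2') and one
# inverts (1,2), giving (-2,-1,3,-2',-5,-4,3',4').
EXAMPLE_GENOME_TEXT = ">A\n1 2 3 4 5 $\n"
EXAMPLE_OPS_TEXT = """\
DUPI segment=(2,3,4) target={5_h,0#2} inverted=0
DCJ {3_h,4_t} {2'_h,3'_t} -> {3_h,2'_h} {4_t,3'_t}
DCJ {0#1,1_t} {2_h,3_t} -> {0#1,2_h} {1_t,3_t}
"""
EXAMPLE_FINAL_TEXT = ">B\n-2 -1 3 -2' -5 -4 3' 4' $\n"


@pytest.fixture
def example_genome():
    return tj.parse_genome(EXAMPLE_GENOME_TEXT)


@pytest.fixture
def example_ops():
    return tj.parse_trajectory(EXAMPLE_OPS_TEXT)


@pytest.fixture
def example_graph(example_genome, example_ops):
    return tj.TrajectoryGraph.build(example_genome, example_ops)


@pytest.fixture
def example_final():
    return tj.parse_genome(EXAMPLE_FINAL_TEXT)
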