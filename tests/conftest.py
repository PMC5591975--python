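import pytest

from havec import HavecGraph, stipulated_family

# The illustrative single-read example: k=5, table size 11, two hash
# functions, level-1 vector size 3.
EXAMPLE_READ = "GGCAATTGTGTGTCG"
EXAMPLE_K = 5
EXAMPLE_M = 11
EXAMPLE_V = 3

# Stated hash values for the example's 5-mers.  Values are listed only for
# the probes the cascade reaches; TGTCG's second-function value (58) is a
# fixture choice: its first probe (56 % 11 = 1) finds index 1 already
# occupied once the insertion order is followed literally, so a second
# value landing on another occupied index (58 % 11 = 3) is needed for it
# to spill into the auxiliary vector.
EXAMPLE_HASHES = {
    (1, "GGCAA"): 57,
    (1, "GCAAT"): 27,
    (1, "CAATT"): 24, (2, "CAATT"): 36,
    (1, "AATTG"): 52,
    (1, "ATTGT"): 36, (2, "ATTGT"): 27,
    (1, "TTGTG"): 22,
    (1, "TGTGT"): 34, (2, "TGTGT"): 30,
    (1, "GTGTG"): 49, (2, "GTGTG"): 47,
    (1, "GTGTC"): 38, (2, "GTGTC"): 25,
    (1, "TGTCG"): 56, (2, "TGTCG"): 58,
    # never inserted, but queried (membership true-negative, predecessor
    # candidates); each lands on a slot left free (4, 6, 7, 9 or 10), so
    # the first probe already proves absence
    (1, "AAAAA"): 40,
    (1, "AGCAA"): 59, (1, "CGCAA"): 61, (1, "TGCAA"): 62,
    (1, "AGGCA"): 64, (1, "CGGCA"): 65, (1, "GGGCA"): 70, (1, "TGGCA"): 72,
    (1, "ATGTG"): 73, (1, "CTGTG"): 75,
    # phantom successor probed by the fault-injection comparison test
    (1, "TGTGA"): 81,
}


def make_example_graph(mode: str = "5byte") -> HavecGraph:
    g = HavecGraph(
        k=EXAMPLE_K, M=EXAMPLE_M, h=2, V=EXAMPLE_V,
        mode=mode, family=stipulated_family(EXAMPLE_HASHES, h=2),
    )
    g.build([EXAMPLE_READ])
    return g


@pytest.fixture
def example_graph() -> HavecGraph:
    return make_example_graph()


@pytest.fixture
def example_graph_counts() -> HavecGraph:
    return make_example_graph("6byte")
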