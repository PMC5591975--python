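import itertools
import random

import pytest

from havec import (
    HavecGraph,
    bases_from_bits,
    build_oracle,
    compare,
    decode_kmer,
    encode_kmer,
    min_table_size,
    random_genome,
    recommended_table_size,
    sample_reads,
)
from conftest import EXAMPLE_READ


# -- sizing validation ----------------------------------------------------

def test_minimum_table_size_boundaries():
    HavecGraph(k=32, M=2**31)                      # boundary accepted
    HavecGraph(k=25, M=2**17)
    with pytest.raises(ValueError, match="table too small"):
        HavecGraph(k=32, M=2**31 - 1)
    HavecGraph(k=16, M=1)                          # 2k <= 33: unconstrained
    assert min_table_size(32) == 2**31
    assert min_table_size(25) == 2**17
    assert min_table_size(16) == 1


def test_recommended_table_size():
    assert recommended_table_size(1000, 5) == 1400
    assert recommended_table_size(10, 32) == 2**31  # floor dominates


# -- worked example -------------------------------------------------------

def test_locate_worked_example(example_graph):
    g = example_graph
    loc = g.locate(encode_kmer("GCAAT"))
    assert (loc.kind, loc.table_index) == ("table", 5)
    loc = g.locate(encode_kmer("ATTGT"))
    assert (loc.kind, loc.bucket, loc.ht_index) == ("vector", 2, 5)
    assert g.locate(encode_kmer("AAAAA")).kind == "absent"


def test_membership_worked_example(example_graph):
    g = example_graph
    for s in ("GGCAA", "GCAAT", "CAATT", "AATTG", "ATTGT",
              "TTGTG", "TGTGT", "GTGTG", "GTGTC", "TGTCG"):
        assert g.contains(encode_kmer(s))


def test_successors_worked_example(example_graph):
    g = example_graph
    succ = g.successors_present(encode_kmer("GGCAA"))
    assert [decode_kmer(y) for y in succ] == ["GCAAT"]
    succ = g.successors_present(encode_kmer("TGTGT"))
    assert [decode_kmer(y) for y in succ] == ["GTGTC", "GTGTG"]
    assert g.successors_present(encode_kmer("TGTCG")) == []
    with pytest.raises(KeyError, match="not in graph"):
        g.successors_present(encode_kmer("AAAAA"))


def test_predecessors_worked_example(example_graph):
    g = example_graph
    preds = g.predecessors_present(encode_kmer("GCAAT"))
    assert [decode_kmer(y) for y in preds] == ["GGCAA"]
    assert g.predecessors_present(encode_kmer("GGCAA")) == []
    preds = g.predecessors_present(encode_kmer("TGTGT"))
    assert sorted(decode_kmer(y) for y in preds) == ["GTGTG", "TTGTG"]


def test_repeated_kmer_updates_not_duplicates(example_graph):
    # TGTGT occurs twice in the read: one location, both neighbours
    g = example_graph
    assert g.table_kmers + g.vector_kmers == 10
    bits = g.neighbour_mask(encode_kmer("TGTGT"))
    assert bases_from_bits(bits) == ["C", "G"]


def test_enumerate_worked_example(example_graph):
    names = sorted(decode_kmer(x) for x, _, _ in example_graph.enumerate_kmers())
    assert names == sorted(
        {"GGCAA", "GCAAT", "CAATT", "AATTG", "ATTGT",
         "TTGTG", "TGTGT", "GTGTG", "GTGTC", "TGTCG"}
    )


def test_build_report_and_stats(example_graph):
    s = example_graph.stats()
    assert s.table_kmers + s.vector_kmers == s.distinct_kmers == 10
    assert s.table_bytes == 55
    assert 0 < s.load_factor <= 1


def test_empty_and_duplicate_builds():
    g = HavecGraph(k=5, M=97, h=2, V=8, seed=1)
    rep = g.build([])
    assert (rep.reads, rep.observations, rep.distinct_kmers) == (0, 0, 0)
    rep = g.build([EXAMPLE_READ, EXAMPLE_READ])
    assert rep.distinct_kmers == 10
    assert rep.observations == 22


# -- counts and cutoff ----------------------------------------------------

def test_counts_worked_example(example_graph_counts):
    g = example_graph_counts
    assert g.count(encode_kmer("TGTGT")) == 2
    assert g.count(encode_kmer("GGCAA")) == 1
    assert g.count(encode_kmer("AAAAA")) == 0


def test_cutoff_membership(example_graph_counts):
    g = example_graph_counts
    survivors = [
        s for s in ("GGCAA", "GCAAT", "CAATT", "AATTG", "ATTGT",
                    "TTGTG", "TGTGT", "GTGTG", "GTGTC", "TGTCG")
        if g.contains(encode_kmer(s), cutoff=2)
    ]
    assert survivors == ["TGTGT"]  # the only 5-mer occurring twice


def test_cutoff_preserves_closure(example_graph_counts):
    # TGTGT survives cutoff 2 but its raw successors do not: the filtered
    # successor list must be empty so traversal never leaves the cutoff set
    g = example_graph_counts
    assert g.successors_present(encode_kmer("TGTGT"), cutoff=2) == []


def test_cutoff_requires_counts(example_graph):
    with pytest.raises(ValueError, match="counts unavailable"):
        example_graph.contains(encode_kmer("TGTGT"), cutoff=2)


def test_count_saturates_at_255():
    g = HavecGraph(k=3, M=101, h=2, mode="6byte", V=4, seed=0)
    g.build(["AAAA" * 150])  # AAA occurs ~600 times
    assert g.count(encode_kmer("AAA")) == 255


# -- exactness on synthetic data ------------------------------------------

def test_exhaustive_k5_sweep_no_errors():
    genome = random_genome(2000, seed=11)
    g = HavecGraph(k=5, M=1400, h=3, V=16, seed=2)
    g.build([genome])
    oracle = build_oracle([genome], 5)
    present = set(oracle.entries)
    for code in range(4**5):
        x = encode_kmer("".join("ACGT"[(code >> s) & 3]
                                for s in range(8, -2, -2)))
        assert g.contains(x) == (decode_kmer(x) in present)


@pytest.mark.parametrize("k", [5, 15, 27, 31, 32])
def test_oracle_agreement_across_k(k):
    genome = random_genome(5000, seed=k)
    reads = sample_reads(genome, 120, 100, error_rate=0.01, seed=k + 1)
    oracle = build_oracle(reads, k)
    M = recommended_table_size(len(oracle.entries), k)
    g = HavecGraph(k=k, M=M, h=4, V=64, mode="6byte", seed=k)
    g.build(reads)
    assert compare(g, oracle) == []


def test_neighbour_bits_match_oracle_exactly():
    genome = random_genome(3000, seed=5)
    reads = sample_reads(genome, 80, 90, error_rate=0.01, n_rate=0.002, seed=6)
    k = 15
    g = HavecGraph(k=k, M=4000, h=4, V=32, seed=7)
    g.build(reads)
    oracle = build_oracle(reads, k)
    for s, (succ, _) in oracle.entries.items():
        assert set(bases_from_bits(g.neighbour_mask(encode_kmer(s)))) == succ


def test_partition_no_double_storage():
    genome = random_genome(4000, seed=8)
    g = HavecGraph(k=11, M=900, h=2, V=8, seed=9)  # tight table: forces spill
    g.build([genome])
    kmers = [decode_kmer(x) for x, _, _ in g.enumerate_kmers()]
    assert len(kmers) == len(set(kmers)) == g.table_kmers + g.vector_kmers
    assert g.vector_kmers > 0  # the tight table really did spill
    assert set(kmers) == set(build_oracle([genome], 11).entries)


def test_order_invariance():
    genome = random_genome(2000, seed=12)
    reads = sample_reads(genome, 40, 80, seed=13)
    shuffled = list(reads)
    random.Random(14).shuffle(shuffled)
    g1 = HavecGraph(k=9, M=700, h=2, V=8, seed=15)
    g1.build(reads)
    g2 = HavecGraph(k=9, M=700, h=2, V=8, seed=15)
    g2.build(shuffled)
    oracle = build_oracle(reads, 9)
    assert compare(g1, oracle) == []
    assert compare(g2, oracle) == []
    for s in itertools.islice(oracle.entries, 200):
        x = encode_kmer(s)
        assert (sorted(map(decode_kmer, g1.successors_present(x)))
                == sorted(map(decode_kmer, g2.successors_present(x))))


def test_successor_closure():
    genome = random_genome(1500, seed=20)
    g = HavecGraph(k=7, M=2200, h=3, V=8, seed=21)
    g.build([genome])
    for x, _, _ in g.enumerate_kmers():
        for y in g.successors_present(x):
            assert g.contains(y)


def test_vector_count_shrinks_with_table_size():
    genome = random_genome(6000, seed=30)
    reads = sample_reads(genome, 100, 100, error_rate=0.01, seed=31)
    base_M = 5000
    counts = []
    for step in range(5):
        M = int(base_M * 1.05**step)
        g = HavecGraph(k=21, M=M, h=4, V=32, seed=32)
        g.build(reads)
        counts.append(g.vector_kmers)
    assert all(a >= b for a, b in zip(counts, counts[1:]))
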