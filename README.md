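# havec

**Exact, false-positive-free de Bruijn graph storage for genome assembly,
built on a quotienting hash table with an auxiliary spill vector.**

## The problem

De Bruijn graphs — nodes are the distinct k-mers of a read set, edges the
observed (k−1)-overlaps — are the workhorse of short-read genome assembly,
and their memory footprint is the bottleneck. Bloom-filter representations
are compact but probabilistic: a membership query can answer "present" for
a k-mer that was never seen, which introduces false nodes and false
branches into the graph.

This package stores the graph exactly, in about 5 bytes per k-mer. The
idea: hash a k-mer to a 2k-bit value *v* with one of an ordered family of
**bijective** hash functions H₁..H_h, and split it against the table size
M as

```
v = q·M + r,      r = v mod M  (the slot),   q = ⌊v/M⌋  (the quotient).
```

Two k-mers may share a slot *r*, but under the same hash function they can
never share the pair (r, q) — and since each Hᵢ is a bijection, the triple
(r, q, i) identifies exactly one k-mer. Each occupied slot therefore
stores, in a packed 40-bit entry:

| field | bits | meaning |
|---|---|---|
| neighbour bits | 4 | which of the 4 possible successor k-mers were observed |
| hash-function index | 3 | which Hᵢ filed this k-mer here (0 = free slot) |
| quotient | 33 | q, completing the fingerprint |

Insertion cascades: try H₁'s slot; if occupied, H₂'s, and so on. If all h
probes are occupied, the k-mer spills into a three-level **auxiliary
vector** (bucket = H_h's slot index mod V → per-slot-index sublist →
collided records); at sensible table sizes roughly one k-mer in a thousand
spills. A 6-byte mode appends a saturating occurrence count per k-mer so
abundance cutoffs can be applied at query time — the graph is built once
and reused for any cutoff.

The 33-bit quotient field requires M ≥ 2^(2k−33) (for k=32, M ≥ 2^31);
the constructor enforces this. Large tables are backed by lazily-committed
anonymous memory, so the zero-filled expanse costs physical memory only
where slots are written.

## Worked example

```python
from havec import HavecGraph, build_oracle, compare, encode_kmer, decode_kmer

g = HavecGraph(k=5, M=97, h=2, V=8, mode="6byte", seed=1)
report = g.build(["GGCAATTGTGTGTCG"])
print(report)
print([decode_kmer(y) for y in g.successors_present(encode_kmer("TGTGT"))])
print(g.count(encode_kmer("TGTGT")))
print(compare(g, build_oracle(["GGCAATTGTGTGTCG"], 5)))
```

prints

```
BuildReport(reads=1, observations=11, distinct_kmers=10, table_kmers=10, vector_kmers=0)
['GTGTC', 'GTGTG']
2
[]
```

The 15-base read yields 11 windows of length 5, of which 10 are distinct
(`TGTGT` occurs twice, hence count 2, and has both observed successors
recorded). The empty list from `compare` is the exactness guarantee: the
graph and a brute-force window scan agree on every k-mer, neighbour set
and count.

The same pipeline is available from the shell:

```
havec simulate --length 20000 --reads 400 --seed 1 --out reads.fa
havec build reads.fa --k 21 --mode 6byte --seed 1 --out g.havec
havec query --graph g.havec --kmer <21-mer>
havec verify --graph g.havec reads.fa
```

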