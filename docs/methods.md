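# Methods

## The data structure

A de Bruijn graph over a read set is fully determined by (a) the set of
distinct k-mers and (b), for each k-mer, which of its four possible
successors (drop the first base, append A/C/G/T) were actually observed
as the next window of some read. havec stores exactly that, nothing
more: no explicit edge objects, no read locations.

Every k-mer is encoded as a 2k-bit integer (A=0, C=1, G=2, T=3, first
base most significant). An ordered family of h hash functions H₁..H_h
maps codes to 2k-bit values; each Hᵢ is a **bijection** of the 2k-bit
integers, composed of invertible steps only (odd-multiplier
multiplication mod 2^2k and xor-shift rounds, parameters derived
deterministically from a 64-bit master seed via a splitmix64 stream).
Hashing within the 2k-bit domain — rather than a fixed 64-bit one — is
what makes the quotient bound below hold for every k, not just k=32;
hash values of small k-mers are small by construction.

A hash value v splits against the table size M as v = q·M + r. The slot
r stores the 40-bit entry `neighbour_bits(4) | hf_index(3) |
quotient(33)` (MSB-first field order within the word, bytes
little-endian). Since Hᵢ is injective, (r, q, i) pins down a single
k-mer: a probe matches only when both the stored function index and the
stored quotient equal the probe's, so a membership query can never
confuse two k-mers. This eliminates false positives structurally rather
than probabilistically, and it also makes the store enumerable: the
occupant of slot r is H_i⁻¹(q·M + r).

Insertion probes H₁, H₂, … in order and takes the first free slot.
Because slots are never vacated, meeting a free slot at probe i proves
the k-mer is absent from the entire structure (it would have been placed
there or earlier), so lookup and insertion are a single pass and later
hash functions are evaluated only when needed. When all h probes are
occupied the k-mer spills into the auxiliary vector: bucket
`r_h mod V` → sublist for table index `r_h` → record
(quotient, function index h, neighbour bits[, count]). Lists are
append-ordered and scanned linearly; they are short by construction.

## Parameters

- **k** (1..32): word length. 32 is the ceiling because codes are 2k
  bits and entries give the quotient 33 bits.
- **M**: table size. Must satisfy M ≥ 2^(2k−33) when 2k > 33 so every
  quotient fits its field (at k=32 the floor is 2^31). Memory is
  near-optimal at 1.25–1.5× the distinct-k-mer count;
  `recommended_table_size` uses 1.4 (midpoint) and never goes below the
  floor. The CLI applies the same default when `--table-size` is
  omitted.
- **h** (1..7): number of hash functions; default 4. The 3-bit field
  could represent 8 functions, but index 0 is the free-slot sentinel, so
  at most 7 are usable. More functions fill the table denser before
  spilling; each extra probe costs time only on collision-heavy paths.
- **V**: level-1 vector size; default `max(1024, M/1024)`. Spill rates
  are near one per thousand stored k-mers at sensible M, so this keeps
  buckets at a handful of entries. Any V ≥ 1 is correct — V only
  trades memory for bucket-scan length.
- **mode**: `5byte` (default) or `6byte`, which appends a per-k-mer
  occurrence count byte saturating at 255. Counts are recorded at build
  time; abundance cutoffs are applied at query time, so one build serves
  every cutoff between 1 and 255.

## Query semantics

`contains(x, cutoff)` is exact both ways. With a cutoff c > 1 (6-byte
mode only), a k-mer counts as present when its saturated count is ≥ c.
`successors_present` intersects the stored neighbour bits with the
cutoff-surviving k-mer set, so traversal never steps onto a suppressed
node — the filtered graph stays closed. The symmetric
`predecessors_present` checks the four candidate predecessors for a
matching stored bit. Neighbour bits are recorded toward k-mers that may
themselves fall below a cutoff; filtering at query time (rather than
dropping bits at build time) is the choice that keeps one build valid
for all cutoffs.

## Memory backing

Small tables live in one bytearray. Tables above 128 MiB are backed by
private anonymous memory maps in 128 MiB chunks: untouched pages read as
the kernel's shared zero page and cost no physical memory, so even the
k=32 minimum table (2^31 slots, 10 GiB of address space at 5 bytes each)
is practical — resident memory scales with the number of *written*
slots, roughly 4 KiB per touched page. Occupied-slot enumeration scans
the chunks as 64-bit words with numpy (a free slot is all-zero; an
occupied one never is), which sweeps a sparsely-filled k=32 table in
seconds.

## Synthetic data and what it covers

The generator draws uniform i.i.d. genomes and samples fixed-length
reads at uniform positions, with per-base substitution errors and
optional 'N' injection (to exercise the ambiguous-window skip rule:
any window containing a non-ACGT character is skipped entirely).
Substitution-only, no indels — what stresses this structure is the
number of distinct k-mers and the collision pattern, which substitutions
inflate just as indels would, with simpler bookkeeping. Uniform genomes
lack the repeat structure, coverage biases and quality artefacts of real
sequencing data; passing tests demonstrate exactness of storage and
query under any observation multiset (the guarantee is combinatorial,
not statistical), but say nothing about assembly quality downstream.
Reverse complements are not folded: each read contributes its literal
strand only, matching the construction procedure this package
implements; canonical-k-mer folding can be emulated by also feeding each
read's reverse complement.

## Verification strategy

A brute-force oracle — a plain dict built by literal window scanning,
no hashing — shares the window/skip implementation with the graph
builder (one code path, so the two sides cannot drift) and records each
k-mer's observed successor set and multiplicity. `compare` diffs a graph
against it: missing k-mers, extra k-mers (via full enumeration by hash
inversion), neighbour-set mismatches and count mismatches, each reported
with its k-mer. The test suite runs this comparison across word lengths
5..32 on randomized read sets, sweeps the complete 4^5 universe at k=5,
and replays a fixed single-read example with stipulated hash values
against its reference table layout entry by entry.

In that replay, the stated narrative and the stated hash values
disagree in one place: following the algorithm with the stated values,
the first doubly-occurring 5-mer lands in table index 1 (which is still
free when it first arrives), and it is the final 5-mer that spills to
the vector instead. The replay follows the algorithm; the entries whose
stated values are self-consistent (table indices 0, 2, 3, 5 and 8, and
the first spilled record) are asserted verbatim, and the fixture
stipulates one extra second-function hash value for the final 5-mer so
that its cascade is fully specified.

## Numerical and degenerate-input choices

- Lowercase bases are accepted and upper-cased (soft-masked FASTA);
  any other non-ACGT character voids the windows containing it.
- Reads shorter than k contribute nothing; an empty read set builds an
  empty graph that answers every query "absent".
- Counts start at 1 on first insertion and saturate at 255; saturation
  is also the cap the oracle applies when comparing.
- The serialized container is little-endian throughout with a trailing
  CRC-32 of everything before it; load verifies magic, checksum and
  payload length before reconstructing, and rebuilds the hash family
  from the stored master seed.
- Graphs built on a stipulated (lookup-table) hash family cannot be
  serialized — the family is a closed-world test fixture, not a
  reproducible function of a seed.

## Problem sizes used in the shipped checks

The randomized exactness suite builds twenty graphs from genomes of
10–100 kb at ~2× read coverage with 1% substitutions, four builds at
each k in {5, 15, 27, 31, 32}; the trend check grows an undersized
k=21 table in 5% steps over a fixed 30 kb read set. These sizes give
collision-rich tables (including genuinely spilling vectors) and
k=31/32 builds at their multi-GiB minimum table sizes, while the whole
suite stays in the minutes range on a single CPU.

## Known limitations

- Construction is single-threaded.
- No contig/unitig extraction, tip clipping or bubble popping — this is
  the storage layer an assembler would traverse, not an assembler.
- The table is sized once, up front; there is no live rehashing. An
  undersized table stays correct but spills more.
- The auxiliary vector grows without bound by design; pathological
  inputs (a table far smaller than the distinct-k-mer count) degrade
  speed, never correctness.
- SAM/BAM input is not read directly; convert to FASTA/FASTQ first.
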