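"""The de Bruijn graph store: cascading-hash insertion and exact queries.

Construction streams reads, extracts k-mer windows, and stores each
distinct k-mer in exactly one place: the first free slot among the table
indices its hash functions H_1..H_h produce, or — when every probe hits
an occupied slot — the auxiliary vector, filed under the last function's
index.  Because every hash function is injective on k-mer codes, the
stored (index, quotient, function) fingerprint identifies its k-mer
uniquely, so membership, successor and predecessor queries are exact:
no false positives and no false negatives.

Neighbour bits accumulate the bases observed to follow each k-mer, which
is all a de Bruijn graph edge is; in 6-byte mode a saturating count per
k-mer supports abundance cutoffs applied at query time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Tuple

from .aux_vector import AuxRecord, AuxVector
from .hash_family import index_and_quotient, make_family
from .kmer_codec import (
    EncodedKmer,
    MAX_K,
    decode_kmer,
    extract_kmers,
    neighbour_bit,
    predecessor_candidates,
    successor_codes,
)
from .packed_store import MODE_5BYTE, MODE_6BYTE, PackedTable, TableEntry

TABLE = "table"
VECTOR = "vector"
ABSENT = "absent"


@dataclass(frozen=True)
class Location:
    """Where a k-mer lives: a table slot, an aux-vector record, or nowhere."""

    kind: str
    table_index: Optional[int] = None
    bucket: Optional[int] = None
    ht_index: Optional[int] = None
    hf_index: Optional[int] = None


LOCATION_ABSENT = Location(ABSENT)


@dataclass
class BuildReport:
    reads: int = 0
    observations: int = 0
    distinct_kmers: int = 0
    table_kmers: int = 0
    vector_kmers: int = 0


@dataclass
class GraphStats:
    table_kmers: int
    vector_kmers: int
    distinct_kmers: int
    load_factor: float
    table_bytes: int
    vector_records: int


def min_table_size(k: int) -> int:
    """Smallest table size that keeps every quotient within 33 bits."""
    return 1 << (2 * k - 33) if 2 * k > 33 else 1


def recommended_table_size(expected_distinct: int, k: int, factor: float = 1.4) -> int:
    """Table size at *factor* times the expected distinct k-mers.

    Memory is near-optimal with the table 1.25-1.5x the number of unique
    k-mers; the result is never below the 33-bit-quotient minimum.
    """
    return max(math.ceil(factor * max(expected_distinct, 1)), min_table_size(k))


def default_vector_size(M: int) -> int:
    """Level-1 vector sizing: ~M/1024 buckets, at least 1024.

    The spill fraction is around 1/1000 of stored k-mers at sensible
    table sizes, so this keeps bucket lists very short.
    """
    return max(1024, M // 1024)


class HavecGraph:
    """Hash table + auxiliary vector representation of a de Bruijn graph.

    Parameters
    ----------
    k : word length, 1..32.
    M : hash table size; must be at least ``2^(2k-33)`` when 2k > 33.
    h : number of hash functions (1..7), probed in order.
    V : level-1 auxiliary vector size (default ``max(1024, M // 1024)``).
    mode : "5byte" (no counts) or "6byte" (saturating occurrence counts).
    family : a hash family; by default a seeded invertible family.
    """

    def __init__(
        self,
        k: int,
        M: int,
        h: int = 4,
        V: Optional[int] = None,
        mode: str = MODE_5BYTE,
        family=None,
        seed: int = 0,
    ):
        if not 1 <= k <= MAX_K:
            raise ValueError(f"k out of range: {k} (must be 1..{MAX_K})")
        floor = min_table_size(k)
        if M < floor:
            raise ValueError(
                f"table too small for 33-bit quotients (k={k}): "
                f"M={M} < 2^(2k-33)={floor}"
            )
        self.k = k
        self.M = M
        self.mode = mode
        self.family = family if family is not None else make_family(h, seed)
        self.h = self.family.h
        self.V = V if V is not None else default_vector_size(M)
        self.table = PackedTable(M, mode)
        self.aux = AuxVector(self.V)
        self.table_kmers = 0
        self.vector_kmers = 0

    # -- location ---------------------------------------------------------

    def _resolve(self, x: EncodedKmer):
        """Lazy cascading probe of x.

        Returns one of
          ("table", i, index, entry)      — x occupies this slot,
          ("free",  i, index, quotient)   — first free probed slot; since
                                            slots never free up, a free
                                            probe proves x is absent from
                                            the whole structure,
          ("aux",   index_h, q_h, record) — all probes occupied; record is
                                            x's vector record or None.

        Hash values are computed one probe at a time, so only the
        functions the cascade actually needs are ever evaluated.
        """
        index = quotient = 0
        for i in range(1, self.h + 1):
            v = self.family.hash_value(i, x)
            index, quotient = index_and_quotient(v, self.M)
            e = self.table.read_slot(index)
            if e.hf_index == 0:
                return ("free", i, index, quotient)
            if e.hf_index == i and e.quotient == quotient:
                return ("table", i, index, e)
        return ("aux", index, quotient, self.aux.lookup(index, quotient))

    def locate(self, x: EncodedKmer) -> Location:
        """Exact location of x: table slot, vector record, or absent.

        A table slot matches only when both its stored function index and
        quotient agree with the probe — by injectivity that slot can hold
        no k-mer other than x.
        """
        kind, a, b, c = self._resolve(x)
        if kind == "table":
            return Location(TABLE, table_index=b, hf_index=a)
        if kind == "aux" and c is not None:
            return Location(VECTOR, bucket=a % self.V, ht_index=a,
                            hf_index=self.h)
        return LOCATION_ABSENT

    # -- construction -----------------------------------------------------

    def insert_observation(
        self, x: EncodedKmer, following: Optional[str] = None
    ) -> Location:
        """Record one observation of x with its following base (if any).

        A known k-mer just gains the neighbour bit (and a count bump in
        6-byte mode).  A new k-mer takes the first free probed slot, or
        spills into the auxiliary vector when all h probes are occupied.
        """
        bit = neighbour_bit(following) if following is not None else 0
        kind, a, b, c = self._resolve(x)
        if kind == "table":  # known, in the table: update in place
            i, index = a, b
            if bit:
                self.table.or_neighbour_bit(index, bit)
            if self.mode == MODE_6BYTE:
                self.table.bump_count(index)
            return Location(TABLE, table_index=index, hf_index=i)
        if kind == "free":  # new k-mer, first free probed slot wins
            i, index, quotient = a, b, c
            count = 1 if self.mode == MODE_6BYTE else 0
            self.table.write_slot(
                index,
                TableEntry(neighbour_bits=bit, hf_index=i,
                           quotient=quotient, count=count),
            )
            self.table_kmers += 1
            return Location(TABLE, table_index=index, hf_index=i)
        last_index, last_q, rec = a, b, c
        if rec is not None:  # known, in the vector: update in place
            rec.neighbour_bits |= bit
            if self.mode == MODE_6BYTE and rec.count < 255:
                rec.count += 1
        else:  # all probes occupied: spill under the last function's index
            count = 1 if self.mode == MODE_6BYTE else 0
            self.aux.insert(
                last_index,
                AuxRecord(quotient=last_q, hf_index=self.h,
                          neighbour_bits=bit, count=count),
            )
            self.vector_kmers += 1
        return Location(
            VECTOR, bucket=last_index % self.V,
            ht_index=last_index, hf_index=self.h,
        )

    def build(self, reads: Iterable[str]) -> BuildReport:
        """Stream reads through window extraction and insertion."""
        report = BuildReport()
        for read in reads:
            report.reads += 1
            for x, following in extract_kmers(read, self.k):
                self.insert_observation(x, following)
                report.observations += 1
        report.table_kmers = self.table_kmers
        report.vector_kmers = self.vector_kmers
        report.distinct_kmers = self.table_kmers + self.vector_kmers
        return report

    # -- queries ----------------------------------------------------------

    def _entry_for(self, x: EncodedKmer) -> Optional[Tuple[Location, int, int]]:
        """(location, neighbour bits, count) for a present k-mer, else None."""
        kind, a, b, c = self._resolve(x)
        if kind == "table":
            loc = Location(TABLE, table_index=b, hf_index=a)
            return loc, c.neighbour_bits, c.count
        if kind == "aux" and c is not None:
            loc = Location(VECTOR, bucket=a % self.V, ht_index=a,
                           hf_index=self.h)
            return loc, c.neighbour_bits, c.count
        return None

    def _check_cutoff(self, cutoff: int) -> None:
        if cutoff > 1 and self.mode != MODE_6BYTE:
            raise ValueError("counts unavailable in 5-byte mode")

    def contains(self, x: EncodedKmer, cutoff: int = 1) -> bool:
        """Exact membership; with a cutoff, additionally count >= cutoff."""
        self._check_cutoff(cutoff)
        hit = self._entry_for(x)
        if hit is None:
            return False
        if cutoff > 1:
            return hit[2] >= cutoff
        return True

    def count(self, x: EncodedKmer) -> int:
        """Occurrence count of x, saturated at 255 (6-byte mode only)."""
        if self.mode != MODE_6BYTE:
            raise ValueError("counts unavailable in 5-byte mode")
        hit = self._entry_for(x)
        return hit[2] if hit is not None else 0

    def neighbour_mask(self, x: EncodedKmer) -> int:
        """The stored 4-bit following-base mask of a present k-mer."""
        hit = self._entry_for(x)
        if hit is None:
            raise KeyError(f"k-mer not in graph: {decode_kmer(x)}")
        return hit[1]

    def successors_present(self, x: EncodedKmer, cutoff: int = 1) -> List[EncodedKmer]:
        """Observed successors of x, restricted to k-mers passing the cutoff.

        A cutoff-suppressed neighbour is excluded so traversal stays
        closed: every returned k-mer satisfies ``contains`` at the same
        cutoff.
        """
        self._check_cutoff(cutoff)
        hit = self._entry_for(x)
        if hit is None or (cutoff > 1 and hit[2] < cutoff):
            raise KeyError(f"k-mer not in graph: {decode_kmer(x)}")
        return [
            y
            for y in successor_codes(x, hit[1])
            if self.contains(y, cutoff)
        ]

    def predecessors_present(self, x: EncodedKmer, cutoff: int = 1) -> List[EncodedKmer]:
        """Present k-mers whose recorded neighbours include x."""
        self._check_cutoff(cutoff)
        if not self.contains(x, cutoff):
            raise KeyError(f"k-mer not in graph: {decode_kmer(x)}")
        last_bit = 1 << (3 - (x.code & 3))
        out = []
        for y in predecessor_candidates(x):
            hit = self._entry_for(y)
            if hit is None or not hit[1] & last_bit:
                continue
            if cutoff > 1 and hit[2] < cutoff:
                continue
            out.append(y)
        return out

    # -- enumeration and stats --------------------------------------------

    def enumerate_kmers(self) -> Iterator[Tuple[EncodedKmer, int, int]]:
        """Yield (k-mer, neighbour bits, count) for every stored k-mer.

        Works by inverting each stored fingerprint: a slot holding
        (quotient q, function i) at index r encodes the hash value
        ``q*M + r``, and H_i^-1 of that value is the k-mer code.
        """
        if not getattr(self.family, "invertible", False):
            raise ValueError("not invertible: hash family lacks inversion")
        for index in self.table.occupied_indices():
            e = self.table.read_slot(index)
            v = e.quotient * self.M + index
            code = self.family.invert(e.hf_index, v, self.k)
            yield EncodedKmer(code, self.k), e.neighbour_bits, e.count
        for _, ht_index, rec in self.aux:
            v = rec.quotient * self.M + ht_index
            code = self.family.invert(rec.hf_index, v, self.k)
            yield EncodedKmer(code, self.k), rec.neighbour_bits, rec.count

    def stats(self) -> GraphStats:
        total_records, _, _ = self.aux.stats()
        return GraphStats(
            table_kmers=self.table_kmers,
            vector_kmers=self.vector_kmers,
            distinct_kmers=self.table_kmers + self.vector_kmers,
            load_factor=self.table_kmers / self.M,
            table_bytes=self.table.nbytes,
            vector_records=total_records,
        )


def create_graph(
    k: int,
    M: int,
    h: int = 4,
    V: Optional[int] = None,
    mode: str = MODE_5BYTE,
    family=None,
    seed: int = 0,
) -> HavecGraph:
    """Construct an empty graph, validating the minimum table size."""
    return HavecGraph(k=k, M=M, h=h, V=V, mode=mode, family=family, seed=seed)
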