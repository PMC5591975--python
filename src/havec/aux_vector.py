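"""Three-level auxiliary vector for k-mers whose table probes all failed.

Level 1 is a fixed array of V buckets addressed by ``ht_index mod V``,
where ht_index is the table index the *last* hash function produced.
Level 2 is the bucket's list of distinct ht_index sublists, and level 3
is each sublist's list of collided-k-mer records.  A record carries the
same fingerprint fields as a table entry — quotient, hash-function index
(always the last function), neighbour bits, and in 6-byte mode a
saturating count — so a (ht_index, quotient) pair identifies a k-mer
here exactly as (slot, quotient, function) does in the table.

Lists are append-ordered and scanned linearly; they stay tiny in
practice because the spill fraction is on the order of one k-mer in a
thousand at sensible table sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional, Tuple


@dataclass
class AuxRecord:
    quotient: int
    hf_index: int
    neighbour_bits: int = 0
    count: int = 0


class AuxVector:
    def __init__(self, V: int):
        if V < 1:
            raise ValueError("level-1 vector size must be >= 1")
        self.V = V
        # bucket -> list of (ht_index, level-3 record list)
        self.buckets: List[List[Tuple[int, List[AuxRecord]]]] = [
            [] for _ in range(V)
        ]

    def insert(self, ht_index: int, rec: AuxRecord) -> AuxRecord:
        """File *rec* under ht_index; dedup on quotient.

        Returns the stored record: *rec* itself if it was new, else the
        pre-existing record with the same quotient (left for the caller
        to update in place).
        """
        bucket = self.buckets[ht_index % self.V]
        for hti, records in bucket:
            if hti == ht_index:
                for existing in records:
                    if existing.quotient == rec.quotient:
                        return existing
                records.append(rec)
                return rec
        bucket.append((ht_index, [rec]))
        return rec

    def lookup(self, ht_index: int, quotient: int) -> Optional[AuxRecord]:
        """The unique record filed under (ht_index, quotient), or None."""
        for hti, records in self.buckets[ht_index % self.V]:
            if hti == ht_index:
                for rec in records:
                    if rec.quotient == quotient:
                        return rec
                return None
        return None

    def __iter__(self) -> Iterator[Tuple[int, int, AuxRecord]]:
        """Yield (bucket position, ht_index, record) for every record."""
        for pos, bucket in enumerate(self.buckets):
            for hti, records in bucket:
                for rec in records:
                    yield pos, hti, rec

    def stats(self) -> Tuple[int, int, int]:
        """(total records, max records per ht_index, max ht_indices per bucket)."""
        total = 0
        max_records = 0
        max_sublists = 0
        for bucket in self.buckets:
            max_sublists = max(max_sublists, len(bucket))
            for _, records in bucket:
                total += len(records)
                max_records = max(max_records, len(records))
        return total, max_records, max_sublists


def aux_insert(av: AuxVector, ht_index: int, rec: AuxRecord) -> AuxRecord:
    return av.insert(ht_index, rec)


def aux_lookup(av: AuxVector, ht_index: int, quotient: int) -> Optional[AuxRecord]:
    return av.lookup(ht_index, quotient)


def aux_stats(av: AuxVector) -> Tuple[int, int, int]:
    return av.stats()
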