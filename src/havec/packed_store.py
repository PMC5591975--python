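"""The packed hash table: bit-exact 5-byte (or 6-byte) entries.

Each of the M slots stores a 40-bit record, most significant field first:

    neighbour_bits (4) | hash-function index (3) | quotient (33)

The 4 neighbour bits record which bases were observed to follow the
occupant (bit 3 = A, bit 2 = C, bit 1 = G, bit 0 = T, mirroring the
base encoding).  The 3-bit function index is 1..7 for an occupied slot
and 0 for a free one, and the 33-bit quotient completes the occupant's
hash-value fingerprint.  In 6-byte (cutoff) mode a saturating occurrence
count byte follows the 40-bit word.

Entries are stored little-endian at exactly M*5 (or M*6) bytes — the
memory footprint the layout is designed for.  Small tables sit in one
bytearray; large tables are backed by anonymous memory maps split into
fixed-size chunks, so the zero-initialized expanse costs physical pages
only where slots are actually written.  A k=32 table at its minimum
size of 2^31 slots is addressable this way on ordinary hardware.
"""

from __future__ import annotations

import mmap
from dataclasses import dataclass
from typing import Iterator

MODE_5BYTE = "5byte"
MODE_6BYTE = "6byte"

QUOTIENT_BITS = 33
HF_BITS = 3
NEIGHBOUR_BITS = 4
ENTRY_BITS = QUOTIENT_BITS + HF_BITS + NEIGHBOUR_BITS  # 40

_Q_MAX = 1 << QUOTIENT_BITS

# chunking threshold: one bytearray below this, anonymous mmaps above
_CHUNK_BYTES = 128 << 20


@dataclass(frozen=True)
class TableEntry:
    neighbour_bits: int = 0
    hf_index: int = 0
    quotient: int = 0
    count: int = 0  # meaningful in 6-byte mode only

    @property
    def free(self) -> bool:
        return self.hf_index == 0


FREE_ENTRY = TableEntry()


def _entry_width(mode: str) -> int:
    if mode == MODE_5BYTE:
        return 5
    if mode == MODE_6BYTE:
        return 6
    raise ValueError(f"unknown mode: {mode!r}")


def pack_entry(e: TableEntry, mode: str) -> bytes:
    """Pack an entry into 5 (or 6) little-endian bytes."""
    if not 0 <= e.neighbour_bits <= 15:
        raise ValueError("neighbour bits out of range")
    if not 0 <= e.hf_index <= 7:
        raise ValueError("hash-function index out of range")
    if not 0 <= e.quotient < _Q_MAX:
        raise ValueError(f"quotient overflow: {e.quotient} >= 2^{QUOTIENT_BITS}")
    word = (e.neighbour_bits << 36) | (e.hf_index << 33) | e.quotient
    raw = word.to_bytes(5, "little")
    if mode == MODE_6BYTE:
        if not 0 <= e.count <= 255:
            raise ValueError("count out of range")
        return raw + bytes([e.count])
    if mode != MODE_5BYTE:
        raise ValueError(f"unknown mode: {mode!r}")
    return raw


def unpack_entry(raw: bytes, mode: str) -> TableEntry:
    width = _entry_width(mode)
    if len(raw) != width:
        raise ValueError(f"expected {width} bytes, got {len(raw)}")
    word = int.from_bytes(raw[:5], "little")
    return TableEntry(
        neighbour_bits=(word >> 36) & 0xF,
        hf_index=(word >> 33) & 0x7,
        quotient=word & (_Q_MAX - 1),
        count=raw[5] if mode == MODE_6BYTE else 0,
    )


class PackedTable:
    """M packed entries in contiguous little-endian byte storage."""

    def __init__(self, M: int, mode: str = MODE_5BYTE):
        if M < 1:
            raise ValueError("table size must be >= 1")
        self.M = M
        self.mode = mode
        self.width = _entry_width(mode)
        self.entries_per_chunk = max(1, _CHUNK_BYTES // self.width)
        total = M * self.width
        if M <= self.entries_per_chunk:
            self._chunks = [bytearray(total)]
        else:
            self._chunks = []
            remaining = M
            # MAP_PRIVATE anonymous memory: untouched pages read as the
            # shared zero page, so the table costs physical memory only
            # where slots are written
            flags = mmap.MAP_PRIVATE | mmap.MAP_ANONYMOUS
            while remaining > 0:
                n = min(remaining, self.entries_per_chunk)
                self._chunks.append(mmap.mmap(-1, n * self.width, flags=flags))
                remaining -= n

    @property
    def storage(self):
        """The backing buffer (single-chunk tables only)."""
        if len(self._chunks) != 1:
            raise ValueError("table is chunked; iterate chunks() instead")
        return self._chunks[0]

    def chunks(self) -> Iterator[bytes]:
        """The packed bytes in order, one chunk at a time."""
        for c in self._chunks:
            yield bytes(c)

    def load_bytes(self, data: bytes) -> None:
        """Overwrite all M entries from a flat byte string."""
        if len(data) != self.nbytes:
            raise ValueError("payload length mismatch")
        off = 0
        for c in self._chunks:
            n = len(c)
            c[:] = data[off:off + n]
            off += n

    def _locate(self, index: int):
        if not 0 <= index < self.M:
            raise IndexError(f"slot index out of range: {index}")
        ci, local = divmod(index, self.entries_per_chunk)
        return self._chunks[ci], local * self.width

    def read_slot(self, index: int) -> TableEntry:
        buf, off = self._locate(index)
        return unpack_entry(bytes(buf[off:off + self.width]), self.mode)

    def write_slot(self, index: int, e: TableEntry) -> None:
        buf, off = self._locate(index)
        buf[off:off + self.width] = pack_entry(e, self.mode)

    def is_free(self, index: int) -> bool:
        buf, off = self._locate(index)
        # hf_index bits are 33..35 of the 40-bit word: byte 4 bits 1..3
        return (buf[off + 4] >> 1) & 0x7 == 0

    def or_neighbour_bit(self, index: int, bit: int) -> None:
        """Set a following-base bit on an occupied slot; other fields kept."""
        buf, off = self._locate(index)
        if (buf[off + 4] >> 1) & 0x7 == 0:
            raise ValueError(f"update of free entry at index {index}")
        buf[off + 4] |= (bit & 0xF) << 4

    def bump_count(self, index: int) -> None:
        """Increment the occurrence count, saturating at 255 (6-byte mode)."""
        if self.mode != MODE_6BYTE:
            raise ValueError("counts unavailable in 5-byte mode")
        buf, off = self._locate(index)
        if (buf[off + 4] >> 1) & 0x7 == 0:
            raise ValueError(f"update of free entry at index {index}")
        c = buf[off + 5]
        if c < 255:
            buf[off + 5] = c + 1

    def occupied_indices(self) -> Iterator[int]:
        """Indices of occupied slots, in ascending order.

        A free slot is all-zero and an occupied one never is (its
        function index is >= 1), so occupied slots are exactly those
        containing a nonzero byte.  Chunks are scanned as 64-bit words
        with numpy, which makes the sweep cheap even for a huge,
        sparsely-written table whose untouched pages are all zero.
        """
        import numpy as np

        base = 0
        for buf in self._chunks:
            n = len(buf)
            head = n - n % 8
            words = np.frombuffer(memoryview(buf)[:head], dtype=np.uint64)
            candidates = set()
            for w in np.flatnonzero(words):
                lo = int(w) * 8
                for e in range(lo // self.width, min((lo + 7) // self.width + 1,
                                                     n // self.width)):
                    candidates.add(e)
            for off in range(head, n):
                if buf[off]:
                    candidates.add(off // self.width)
            entries_here = n // self.width
            for e in sorted(candidates):
                if e < entries_here and not self.is_free(base + e):
                    yield base + e
            base += entries_here

    @property
    def nbytes(self) -> int:
        return self.M * self.width


def new_table(M: int, mode: str = MODE_5BYTE) -> PackedTable:
    """Fresh table of M free (all-zero) entries."""
    return PackedTable(M, mode)
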