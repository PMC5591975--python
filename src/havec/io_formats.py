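"""Sequence input (FASTA/FASTQ, plain or gzip) and graph serialization.

Read parsing is delegated to Biopython's SeqIO; this module adds format
auto-detection (first byte: '>' FASTA, '@' FASTQ), gzip detection by
magic bytes, and error messages that name the offending record.

The ".havec" container is a little-endian binary file:

    magic "HAVEC\\x01" | k u8 | h u8 | mode u8 (5|6) | M u64 | V u64 |
    seed u64 | table_kmers u64 | vector_kmers u64 |
    M*width table bytes |
    aux payload: n_buckets u64, then per non-empty bucket
        bucket u64, n_sublists u64, then per sublist
            ht_index u64, n_records u64, then per record
                quotient u64, hf u8, bits u8, count u8 |
    crc32 u32 of everything before it

The header alone reconstructs the hash family (from the seed) and the
table geometry, so a loaded graph answers every query identically.
"""

from __future__ import annotations

import gzip
import struct
import zlib
from pathlib import Path
from typing import Iterator, Union

from Bio import SeqIO

from .aux_vector import AuxRecord
from .graph import HavecGraph
from .hash_family import make_family
from .packed_store import MODE_5BYTE, MODE_6BYTE

_MAGIC = b"HAVEC\x01"


def _open_text(path: Union[str, Path]):
    raw = open(path, "rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        import io

        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    import io

    return io.TextIOWrapper(raw)


def read_sequences(path: Union[str, Path]) -> Iterator[str]:
    """Yield sequences from a FASTA or FASTQ file, plain or gzipped.

    Format is detected from the first non-blank character; FASTQ quality
    lines are discarded.  Malformed records raise ``ValueError`` naming
    the record.
    """
    handle = _open_text(path)
    with handle:
        pos = handle.tell()
        first = handle.read(1)
        while first.isspace() and first:
            pos = handle.tell()
            first = handle.read(1)
        if not first:
            return
        handle.seek(pos)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ValueError(
                f"unrecognized sequence format in {path}: "
                f"first character {first!r}"
            )
        try:
            for record in SeqIO.parse(handle, fmt):
                yield str(record.seq)
        except ValueError as exc:
            raise ValueError(f"malformed {fmt} record in {path}: {exc}") from exc


def write_fasta(path: Union[str, Path], reads, prefix: str = "read") -> None:
    """Write reads to a plain FASTA file with numbered headers."""
    with open(path, "w") as fh:
        for n, seq in enumerate(reads, start=1):
            fh.write(f">{prefix}{n}\n{seq}\n")


def save_graph(g: HavecGraph, path: Union[str, Path]) -> None:
    """Serialize a graph built with a seeded hash family."""
    if not hasattr(g.family, "master_seed"):
        raise ValueError(
            "only graphs built with a seeded hash family can be saved"
        )
    mode_byte = 6 if g.mode == MODE_6BYTE else 5
    header = _MAGIC + struct.pack(
        "<BBBQQQQQ",
        g.k, g.h, mode_byte, g.M, g.V, g.family.master_seed,
        g.table_kmers, g.vector_kmers,
    )
    chunks = [header, *g.table.chunks()]
    nonempty = [
        (pos, bucket) for pos, bucket in enumerate(g.aux.buckets) if bucket
    ]
    chunks.append(struct.pack("<Q", len(nonempty)))
    for pos, bucket in nonempty:
        chunks.append(struct.pack("<QQ", pos, len(bucket)))
        for ht_index, records in bucket:
            chunks.append(struct.pack("<QQ", ht_index, len(records)))
            for rec in records:
                chunks.append(
                    struct.pack("<QBBB", rec.quotient, rec.hf_index,
                                rec.neighbour_bits, rec.count)
                )
    payload = b"".join(chunks)
    with open(path, "wb") as fh:
        fh.write(payload)
        fh.write(struct.pack("<I", zlib.crc32(payload)))


def load_graph(path: Union[str, Path]) -> HavecGraph:
    """Load a graph written by :func:`save_graph`, verifying the checksum."""
    data = Path(path).read_bytes()
    if len(data) < len(_MAGIC) + 43 + 4 or data[: len(_MAGIC)] != _MAGIC:
        raise ValueError(f"unrecognized graph file: {path}")
    payload, (crc,) = data[:-4], struct.unpack("<I", data[-4:])
    if zlib.crc32(payload) != crc:
        raise ValueError(f"corrupt graph file (checksum mismatch): {path}")
    off = len(_MAGIC)
    k, h, mode_byte, M, V, seed, table_kmers, vector_kmers = struct.unpack_from(
        "<BBBQQQQQ", payload, off
    )
    off += struct.calcsize("<BBBQQQQQ")
    mode = MODE_6BYTE if mode_byte == 6 else MODE_5BYTE
    g = HavecGraph(k=k, M=M, V=V, mode=mode, family=make_family(h, seed))
    width = g.table.width
    end = off + M * width
    if end > len(payload):
        raise ValueError(f"corrupt graph file (truncated table): {path}")
    g.table.load_bytes(payload[off:end])
    off = end
    try:
        (n_buckets,) = struct.unpack_from("<Q", payload, off)
        off += 8
        for _ in range(n_buckets):
            pos, n_sub = struct.unpack_from("<QQ", payload, off)
            off += 16
            for _ in range(n_sub):
                ht_index, n_rec = struct.unpack_from("<QQ", payload, off)
                off += 16
                records = []
                for _ in range(n_rec):
                    q, hf, bits, cnt = struct.unpack_from("<QBBB", payload, off)
                    off += 11
                    records.append(AuxRecord(q, hf, bits, cnt))
                g.aux.buckets[pos].append((ht_index, records))
    except struct.error as exc:
        raise ValueError(f"corrupt graph file (truncated payload): {path}") from exc
    g.table_kmers = table_kmers
    g.vector_kmers = vector_kmers
    return g
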