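"""2-bit k-mer encoding and window extraction.

A k-mer over {A,C,G,T} is packed into a ``2k``-bit integer, two bits per
base, first base in the most significant position (big-endian base-4).
The convention A=0, C=1, G=2, T=3 is fixed here and shared by every other
module, including the neighbour-bit layout of the packed hash table.

k is capped at 32 so a code always fits in 64 bits.
"""

from __future__ import annotations

from typing import Iterator, NamedTuple, Optional, Tuple

BASES = "ACGT"
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3,
              "a": 0, "c": 1, "g": 2, "t": 3}

MAX_K = 32


class AmbiguousBaseError(ValueError):
    """Raised when a character outside {A,C,G,T} is encoded."""


class EncodedKmer(NamedTuple):
    """A k-mer as a ``2k``-bit integer plus its length.

    Invariant: ``0 <= code < 4**k`` and ``1 <= k <= 32``.
    """

    code: int
    k: int

    def __str__(self) -> str:
        return decode_kmer(self)


def encode_base(b: str) -> int:
    """Map a single nucleotide to its 2-bit code (A=0, C=1, G=2, T=3)."""
    try:
        return _BASE_CODE[b]
    except KeyError:
        raise AmbiguousBaseError(f"ambiguous base {b!r}") from None


def decode_base(code: int) -> str:
    return BASES[code]


def encode_kmer(s: str) -> EncodedKmer:
    """Pack a DNA string into an :class:`EncodedKmer`.

    The first character occupies the most significant 2 bits.  Raises
    ``ValueError`` for k outside [1, 32] and :class:`AmbiguousBaseError`
    for non-ACGT characters.
    """
    k = len(s)
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k out of range: {k} (must be 1..{MAX_K})")
    code = 0
    for ch in s:
        code = (code << 2) | encode_base(ch)
    return EncodedKmer(code, k)


def decode_kmer(x: EncodedKmer) -> str:
    """Inverse of :func:`encode_kmer`."""
    code, k = x
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def extract_kmers(read: str, k: int) -> Iterator[Tuple[EncodedKmer, Optional[str]]]:
    """Yield every clean k-length window of *read* with its following base.

    One item per position p in ``0 .. len(read)-k``; the following base is
    ``read[p+k]`` when it exists and is unambiguous, else ``None``.  Any
    window containing a non-ACGT character is skipped entirely; scanning
    resumes past the offending base.  Lowercase input is accepted
    (soft-masked FASTA).  A read shorter than k yields nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(read)
    if n < k:
        return
    mask = (1 << (2 * k)) - 1
    code = 0
    valid = 0  # clean bases accumulated in the current window
    for p in range(n):
        c = _BASE_CODE.get(read[p])
        if c is None:
            valid = 0
            continue
        code = ((code << 2) | c) & mask
        valid += 1
        if valid >= k:
            nxt = read[p + 1].upper() if p + 1 < n else None
            if nxt is not None and nxt not in _BASE_CODE:
                nxt = None
            yield EncodedKmer(code, k), nxt


def successor_codes(x: EncodedKmer, bits: int) -> list[EncodedKmer]:
    """Successor k-mers selected by a 4-bit neighbour mask.

    For each set bit (base order A, C, G, T) the successor drops the first
    symbol of *x* and appends that base.  ``bits`` uses the packed-table
    layout: bit 3 = A, bit 2 = C, bit 1 = G, bit 0 = T.
    """
    code, k = x
    mask = (1 << (2 * k)) - 1
    suffix = (code << 2) & mask
    return [EncodedKmer(suffix | b, k) for b in range(4) if bits & (1 << (3 - b))]


def predecessor_candidates(x: EncodedKmer) -> list[EncodedKmer]:
    """The four k-mers that could precede *x* (prepend A, C, G, T)."""
    code, k = x
    prefix = code >> 2
    shift = 2 * (k - 1)
    return [EncodedKmer((b << shift) | prefix, k) for b in range(4)]


def neighbour_bit(base: str) -> int:
    """The 4-bit-mask bit for a following base (bit 3=A .. bit 0=T)."""
    return 1 << (3 - encode_base(base))


def bases_from_bits(bits: int) -> list[str]:
    """Decode a neighbour mask into bases, in A,C,G,T order."""
    return [BASES[b] for b in range(4) if bits & (1 << (3 - b))]
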