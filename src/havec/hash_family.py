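"""Ordered families of invertible hash functions over k-mer codes.

Each function is a bijective mixing permutation of the ``2k``-bit integers
(odd-multiplier multiply and xor-shift rounds, every step invertible on
the ring Z/2^(2k)).  Bijectivity is what makes the (table index, quotient,
function index) triple a perfect fingerprint of a k-mer — the structural
basis of exact, false-positive-free membership — and lets the graph
enumerate its k-mers by inverting stored fingerprints.

A hash value of a k-mer therefore occupies at most 2k bits, so with a
table of at least ``2^(2k-33)`` slots every quotient fits in 33 bits.

Function indices are 1-based: index 0 is the packed table's "free slot"
sentinel, which leaves at most 7 usable functions in the 3-bit field.
"""

from __future__ import annotations

from typing import Dict, NamedTuple, Tuple

from .kmer_codec import EncodedKmer, decode_kmer, encode_kmer

MAX_H = 7  # 3-bit field minus the 0 = free sentinel

_MASK64 = (1 << 64) - 1


def _splitmix64(state: int) -> Tuple[int, int]:
    """One step of the splitmix64 sequence: (new_state, output)."""
    state = (state + 0x9E3779B97F4A7C15) & _MASK64
    z = state
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return state, z ^ (z >> 31)


def _invert_xorshift(y: int, shift: int, width: int) -> int:
    """Invert ``x ^= x >> shift`` on *width*-bit integers."""
    x = y
    for _ in range(0, width, shift):
        x = y ^ (x >> shift)
    return x & ((1 << width) - 1)


class IndexQuotient(NamedTuple):
    index: int
    quotient: int


def index_and_quotient(v: int, M: int) -> IndexQuotient:
    """Split a hash value into (slot index, quotient) for table size M.

    ``v == quotient * M + index`` exactly.
    """
    if M < 1:
        raise ValueError("invalid table size")
    return IndexQuotient(v % M, v // M)


class HashFamily:
    """h deterministic bijections on the 2k-bit integers, indexed 1..h.

    Per-function parameters (two odd multipliers and three xor-shift
    amounts) are derived from ``master_seed``, so the same seed always
    reproduces the same family.
    """

    def __init__(self, h: int, master_seed: int):
        if not 1 <= h <= MAX_H:
            raise ValueError(
                f"hash-function count unsupported: {h} (must be 1..{MAX_H})"
            )
        self.h = h
        self.master_seed = master_seed & _MASK64
        state = self.master_seed
        self._params = []
        for _ in range(h):
            state, m1 = _splitmix64(state)
            state, m2 = _splitmix64(state)
            state, s = _splitmix64(state)
            self._params.append((m1 | 1, m2 | 1, s))

    def _shifts(self, s: int, width: int) -> Tuple[int, int, int]:
        # three shift amounts in [1, width-1]; for width 2 they are all 1
        span = max(1, width - 1)
        return (1 + (s % span),
                1 + ((s >> 8) % span),
                1 + ((s >> 16) % span))

    def hash_value(self, i: int, x: EncodedKmer) -> int:
        """Value of function i on k-mer x; lies in [0, 4^k)."""
        if not 1 <= i <= self.h:
            raise ValueError(f"hash function index out of range: {i}")
        m1, m2, s = self._params[i - 1]
        width = 2 * x.k
        mask = (1 << width) - 1
        s1, s2, s3 = self._shifts(s, width)
        v = x.code & mask
        v ^= v >> s1
        v = (v * (m1 & mask | 1)) & mask
        v ^= v >> s2
        v = (v * (m2 & mask | 1)) & mask
        v ^= v >> s3
        return v

    def invert(self, i: int, v: int, k: int) -> int:
        """Recover the k-mer code x with ``hash_value(i, x) == v``."""
        if not 1 <= i <= self.h:
            raise ValueError(f"hash function index out of range: {i}")
        m1, m2, s = self._params[i - 1]
        width = 2 * k
        mask = (1 << width) - 1
        s1, s2, s3 = self._shifts(s, width)
        mod = 1 << width
        inv2 = pow(m2 & mask | 1, -1, mod)
        inv1 = pow(m1 & mask | 1, -1, mod)
        x = _invert_xorshift(v & mask, s3, width)
        x = (x * inv2) & mask
        x = _invert_xorshift(x, s2, width)
        x = (x * inv1) & mask
        x = _invert_xorshift(x, s1, width)
        return x

    @property
    def invertible(self) -> bool:
        return True


def make_family(h: int, master_seed: int) -> HashFamily:
    """Construct a deterministic family of h invertible hash functions."""
    return HashFamily(h, master_seed)


class StipulatedFamily:
    """Closed-world hash family backed by an explicit lookup table.

    A test seam: maps ``(function index, k-mer string)`` to a stated hash
    value verbatim, and inverts by reverse lookup.  Any query outside the
    table is an error — the fixture is a closed world.
    """

    def __init__(self, table: Dict[Tuple[int, str], int], h: int):
        if not 1 <= h <= MAX_H:
            raise ValueError(
                f"hash-function count unsupported: {h} (must be 1..{MAX_H})"
            )
        self.h = h
        self._fwd: Dict[Tuple[int, int], int] = {}
        self._rev: Dict[Tuple[int, int], int] = {}
        for (i, kmer), v in table.items():
            code = encode_kmer(kmer).code
            self._fwd[(i, code)] = v
            self._rev[(i, v)] = code

    def hash_value(self, i: int, x: EncodedKmer) -> int:
        if not 1 <= i <= self.h:
            raise ValueError(f"hash function index out of range: {i}")
        try:
            return self._fwd[(i, x.code)]
        except KeyError:
            raise KeyError(
                f"unstipulated hash query: function {i}, k-mer {decode_kmer(x)}"
            ) from None

    def invert(self, i: int, v: int, k: int) -> int:
        try:
            return self._rev[(i, v)]
        except KeyError:
            raise KeyError(f"not invertible: function {i}, value {v}") from None

    @property
    def invertible(self) -> bool:
        return True


def stipulated_family(table: Dict[Tuple[int, str], int], h: int = 2) -> StipulatedFamily:
    """Build a :class:`StipulatedFamily` from an explicit value map."""
    return StipulatedFamily(table, h)
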