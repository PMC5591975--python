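"""Deterministic synthetic genomes and read samplers for testing.

Genomes are uniform i.i.d. base strings; reads are uniform substrings
with optional substitution errors and injected 'N' bases (to exercise
the ambiguous-window skip policy).  Substitution-only — no indels: what
stresses the store is the number of distinct k-mers, and substitutions
inflate that just as well while keeping coordinates trivial.
"""

from __future__ import annotations

from typing import List

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_genome(length: int, seed: int) -> str:
    """Uniform random DNA string, reproducible per seed."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def sample_reads(
    genome: str,
    n: int,
    read_len: int,
    error_rate: float = 0.0,
    n_rate: float = 0.0,
    seed: int = 0,
) -> List[str]:
    """Sample n reads of fixed length from uniform start positions.

    Each base is substituted (with a uniformly chosen different base)
    with probability *error_rate*, then replaced by 'N' with probability
    *n_rate*.  Reproducible per seed.
    """
    L = len(genome)
    if read_len > L:
        raise ValueError("read length exceeds genome length")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.encode(), dtype="S1")
    codes = np.zeros(L, dtype=np.uint8)
    for v, b in enumerate(b"ACGT"):
        codes[arr == bytes([b])] = v
    starts = rng.integers(0, L - read_len + 1, size=n)
    reads = []
    for s in starts:
        window = codes[s:s + read_len].copy()
        if error_rate > 0:
            hit = rng.random(read_len) < error_rate
            if hit.any():
                window[hit] = (window[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        out = _BASES[window]
        if n_rate > 0:
            mask = rng.random(read_len) < n_rate
            out = out.copy()
            out[mask] = b"N"
        reads.append(out.tobytes().decode())
    return reads
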