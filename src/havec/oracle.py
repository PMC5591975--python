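"""Brute-force exact reference for verification.

The oracle is a plain dict from each observed k-mer string to its
observed successor-base set and multiplicity, built by literal window
scanning with no hashing anywhere.  It shares the window/skip policy
with the graph through the single :func:`~havec.kmer_codec.extract_kmers`
implementation, so the two sides cannot silently diverge on edge cases
like ambiguous bases.

``compare`` is the headline check: a correctly built graph produces an
empty discrepancy report — no missing k-mer, no extra k-mer, no wrong
neighbour set, no wrong count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple

from .graph import HavecGraph
from .kmer_codec import bases_from_bits, decode_kmer, encode_kmer, extract_kmers
from .packed_store import MODE_6BYTE


@dataclass
class ExactOracle:
    k: int
    # k-mer string -> (successor base set, multiplicity)
    entries: Dict[str, Tuple[Set[str], int]] = field(default_factory=dict)


def build_oracle(reads: Iterable[str], k: int) -> ExactOracle:
    """Scan every read window literally; no hashing involved."""
    oracle = ExactOracle(k)
    entries = oracle.entries
    for read in reads:
        for x, following in extract_kmers(read, k):
            s = decode_kmer(x)
            succ, mult = entries.get(s, (None, 0))
            if succ is None:
                succ = set()
            if following is not None:
                succ.add(following)
            entries[s] = (succ, mult + 1)
    return oracle


def compare(g: HavecGraph, oracle: ExactOracle, cutoff: int = 1) -> List[str]:
    """Discrepancies between the graph and the exact reference.

    Empty list iff key sets, neighbour sets and (6-byte mode) capped
    counts all agree under the cutoff.  Every discrepancy names its
    k-mer.
    """
    if g.k != oracle.k:
        raise ValueError(f"k mismatch: graph {g.k}, oracle {oracle.k}")
    report: List[str] = []
    counts = g.mode == MODE_6BYTE

    def capped(mult: int) -> int:
        return min(mult, 255)

    surviving = {
        s for s, (_, mult) in oracle.entries.items()
        if not counts or capped(mult) >= cutoff
    }
    for s, (succ, mult) in oracle.entries.items():
        x = encode_kmer(s)
        want = s in surviving
        got = g.contains(x, cutoff if counts else 1)
        if got != want:
            kind = "false negative" if want else "cutoff leak"
            report.append(f"{kind}: {s}")
            continue
        if not want:
            continue
        graph_succ = {decode_kmer(y)[-1] for y in g.successors_present(x, cutoff if counts else 1)}
        want_succ = {b for b in succ if s[1:] + b in surviving}
        if graph_succ != want_succ:
            report.append(
                f"neighbour mismatch: {s} stored {sorted(graph_succ)} "
                f"expected {sorted(want_succ)}"
            )
        if counts and g.count(x) != capped(mult):
            report.append(
                f"count mismatch: {s} stored {g.count(x)} expected {capped(mult)}"
            )
    for x, bits, _ in g.enumerate_kmers():
        s = decode_kmer(x)
        if s not in oracle.entries:
            report.append(f"false positive: {s}")
            continue
        # stored raw bits must never exceed what was observed
        extra = set(bases_from_bits(bits)) - oracle.entries[s][0]
        if extra:
            report.append(f"phantom neighbour bits: {s} -> {sorted(extra)}")
    return report
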