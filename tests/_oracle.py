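"""Independent brute-force oracles used only by the test suite.

The alignment oracle enumerates every rotation of the monomer on both
strands in pure Python, applying the same tie rule as the mapper (fewer
mismatches, sense before antisense, smaller start). It shares no code with
the vectorized dimer search it checks.
"""

from typing import Optional


def _revcomp(seq: str) -> str:
    pairs = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(pairs[b] for b in reversed(seq))


def oracle_align(seq: str, monomer: str, max_mismatches: int) -> Optional[tuple[int, str, int]]:
    """Best (mismatches, strand, 1-based start) by exhaustive rotation search."""
    L = len(monomer)
    if len(seq) > L or len(seq) == 0:
        return None
    best = None
    for strand_rank, strand, s in ((0, "sense", seq), (1, "antisense", _revcomp(seq))):
        for r in range(L):
            rotation = monomer[r:] + monomer[:r]
            mism = sum(a != b for a, b in zip(s, rotation[: len(s)]))
            if mism > max_mismatches:
                continue
            key = (mism, strand_rank, r + 1)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    mism, rank, start = best
    return mism, ("sense" if rank == 0 else "antisense"), start


def oracle_trim(seq: str, adapter: str, min_overlap: int, max_mismatch_rate: float) -> int:
    """Length of the suffix to cut, by enumerating every suffix/prefix overlap."""
    best = 0
    for k in range(min_overlap, min(len(seq), len(adapter)) + 1):
        mism = sum(a != b for a, b in zip(seq[-k:], adapter[:k]))
        if mism <= max_mismatch_rate * k:
            best = max(best, k)
    return best
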