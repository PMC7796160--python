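"""Ungapped alignment of small RNA reads to satellite consensus dimers.

Satellite DNA is organized as head-to-tail tandem arrays of a short monomer
(e.g. 360 bp for the TCAST1B subfamily of *Tribolium castaneum*). Mapping
reads to a *dimer* (the monomer concatenated with itself) lets reads that
span the monomer junction align contiguously; reported start coordinates are
collapsed modulo the monomer length, so every placement lies in ``[1, L]``.

Reads are 17-36 nt and satellite copies diverge by substitutions, so the
aligner is deliberately ungapped: every offset of the read (and of its
reverse complement) along the dimer is scored by Hamming distance. This
keeps an exhaustive rotation-search oracle feasible and the behaviour fully
specified, including tie-breaking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidAlphabetError, InvalidParameterError

__all__ = [
    "SatelliteConsensus",
    "Alignment",
    "build_dimer",
    "align_read",
    "map_reads",
    "assign_subfamily",
    "rna_to_dna",
    "revcomp",
    "default_max_mismatches",
    "read_consensus_fasta",
    "write_alignment_tsv",
    "write_alignment_sam",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> code; anything unexpected (incl. N) gets 4+ and never matches
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
_ENC[ord("N")] = 5  # N mismatches everything, including another N


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    """Convert an RNA (or mixed) sequence to DNA by replacing U with T.

    Probe and primer sequences are published in RNA alphabet while reads are
    stored as DNA; this puts them in one alphabet. Raises
    :class:`InvalidAlphabetError` for symbols outside ``{A,C,G,T,U,N}``.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTUN")
    if bad:
        raise InvalidAlphabetError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    return seq.replace("U", "T")


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SatelliteConsensus:
    """A named satellite subfamily monomer; the coordinate frame for all profiling.

    Attributes
    ----------
    name:
        Subfamily name, e.g. ``TCAST1B``.
    monomer:
        Consensus monomer sequence over ``{A,C,G,T}``.
    """

    name: str
    monomer: str

    def __post_init__(self) -> None:
        mono = self.monomer.upper()
        if not mono:
            raise InvalidParameterError("consensus monomer must be non-empty")
        bad = set(mono) - set("ACGT")
        if bad:
            raise InvalidAlphabetError(f"consensus contains non-ACGT symbols: {sorted(bad)}")
        object.__setattr__(self, "monomer", mono)

    @property
    def length(self) -> int:
        return len(self.monomer)

    @property
    def dimer(self) -> str:
        return build_dimer(self)


def build_dimer(consensus: SatelliteConsensus) -> str:
    """Monomer concatenated with itself (length 2L), the mapping reference."""
    if not consensus.monomer:
        raise InvalidParameterError("cannot build a dimer from an empty monomer")
    return consensus.monomer * 2


@dataclass(frozen=True)
class Alignment:
    """A read placed on a consensus: strand, modulo-monomer start, mismatches.

    ``start`` is 1-based and always in ``[1, L]``; ``strand == "sense"`` means
    the read sequence matches the published consensus strand.
    """

    read_id: str
    consensus_name: str
    strand: str  # "sense" | "antisense"
    start: int
    read_length: int
    mismatches: int


@lru_cache(maxsize=64)
def _dimer_enc(monomer: str) -> np.ndarray:
    return _ENC[np.frombuffer((monomer * 2).encode("ascii"), dtype=np.uint8)]


def _mismatch_profile(dimer_enc: np.ndarray, read_enc: np.ndarray) -> np.ndarray:
    windows = sliding_window_view(dimer_enc, len(read_enc))
    return (windows != read_enc).sum(axis=1)


def align_read(read, consensus: SatelliteConsensus, max_mismatches: int = 2) -> Optional[Alignment]:
    """Best ungapped placement of a read (or its reverse complement) on the dimer.

    All ``2L - len + 1`` offsets are scored on both strands; the winner is the
    placement with the fewest mismatches, provided it does not exceed
    ``max_mismatches``. Ties are broken by (fewer mismatches, sense before
    antisense, smaller collapsed start). Returns ``None`` when unmapped.

    ``read`` is any object with ``id`` and ``sequence`` attributes
    (:class:`satrna.preprocess.SmallRnaRead` in the pipeline).
    """
    seq = read.sequence
    L = consensus.length
    if len(seq) == 0:
        return None
    if len(seq) > L:
        warnings.warn(
            f"read {read.id} ({len(seq)} nt) longer than monomer ({L} bp); unmapped",
            stacklevel=2,
        )
        return None
    dimer = _dimer_enc(consensus.monomer)
    fwd = _encode(seq)
    best: Optional[tuple] = None
    for strand_rank, strand, enc in ((0, "sense", fwd), (1, "antisense", _encode(revcomp(seq)))):
        prof = _mismatch_profile(dimer, enc)
        m = int(prof.min())
        if m > max_mismatches:
            continue
        for off in np.flatnonzero(prof == m):
            key = (m, strand_rank, (int(off) % L) + 1)
            if best is None or key < best[:3]:
                best = (*key, strand)
    if best is None:
        return None
    mism, _rank, start, strand = best
    return Alignment(
        read_id=read.id,
        consensus_name=consensus.name,
        strand=strand,
        start=start,
        read_length=len(seq),
        mismatches=mism,
    )


def map_reads(
    reads: Iterable, consensus: SatelliteConsensus, max_mismatches: int = 2
) -> tuple[list[Alignment], list[str]]:
    """Align a batch of reads; returns (alignments, ids of unmapped reads)."""
    alignments: list[Alignment] = []
    unmapped: list[str] = []
    for read in reads:
        aln = align_read(read, consensus, max_mismatches=max_mismatches)
        if aln is None:
            unmapped.append(read.id)
        else:
            alignments.append(aln)
    return alignments, unmapped


def assign_subfamily(
    read, consensus_set: Sequence[SatelliteConsensus], max_mismatches: int = 2
) -> Optional[Alignment]:
    """Align against every consensus and keep the single best placement.

    Subfamilies (e.g. TCAST1A vs TCAST1B) share most of their sequence; a read
    is counted once, for the consensus where it aligns with fewest mismatches.
    Equal scores are broken by lexicographic consensus name so the assignment
    is deterministic.
    """
    if not consensus_set:
        raise InvalidParameterError("consensus_set must contain at least one consensus")
    names = [c.name for c in consensus_set]
    if len(set(names)) != len(names):
        raise InvalidParameterError("consensus names must be unique")
    best: Optional[Alignment] = None
    for consensus in sorted(consensus_set, key=lambda c: c.name):
        aln = align_read(read, consensus, max_mismatches=max_mismatches)
        if aln is None:
            continue
        if best is None or aln.mismatches < best.mismatches:
            best = aln
    return best


def default_max_mismatches(read_length: int, rate: float = 0.10) -> int:
    """Mismatch allowance for long-RNA fragments: ceil(rate * length)."""
    if read_length < 1:
        raise InvalidParameterError("read_length must be >= 1")
    return math.ceil(rate * read_length)


# ---------------------------------------------------------------------------
# I/O


def read_consensus_fasta(path) -> list[SatelliteConsensus]:
    """Load satellite consensus monomers from a FASTA file."""
    from Bio import SeqIO

    records = [
        SatelliteConsensus(name=rec.id, monomer=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InvalidParameterError(f"no consensus sequences found in {path}")
    return records


def write_alignment_tsv(alignments: Iterable[Alignment], path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("read_id\tconsensus\tstrand\tstart\tlength\tmismatches\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.consensus_name}\t{a.strand}\t{a.start}\t{a.read_length}\t{a.mismatches}\n"
            )


def read_alignment_tsv(path) -> list[Alignment]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        Alignment(
            read_id=str(r.read_id),
            consensus_name=str(r.consensus),
            strand=str(r.strand),
            start=int(r.start),
            read_length=int(r.length),
            mismatches=int(r.mismatches),
        )
        for r in df.itertuples()
    ]


def write_alignment_sam(
    alignments: Iterable[Alignment],
    consensus_set: Sequence[SatelliteConsensus],
    reads: Mapping[str, str],
    path,
) -> None:
    """Emit alignments as plain-text SAM against the dimer references.

    Coordinates are the uncollapsed dimer placement that corresponds to the
    collapsed start, i.e. the read is guaranteed to fit without wrapping
    (placements near the junction use the first monomer copy). CIGAR is
    all-match; NM carries the mismatch count.
    """
    by_name = {c.name: c for c in consensus_set}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c in consensus_set:
            fh.write(f"@SQ\tSN:{c.name}_dimer\tLN:{2 * c.length}\n")
        for a in alignments:
            seq = reads.get(a.read_id, "*")
            flag = 0 if a.strand == "sense" else 16
            if a.strand == "antisense" and seq != "*":
                seq = revcomp(seq)
            cigar = f"{a.read_length}M"
            ref = f"{a.consensus_name}_dimer"
            if a.consensus_name not in by_name:
                raise InvalidParameterError(f"alignment references unknown consensus {a.consensus_name}")
            fh.write(
                f"{a.read_id}\t{flag}\t{ref}\t{a.start}\t255\t{cigar}\t*\t0\t0\t{seq}\t*\tNM:i:{a.mismatches}\n"
            )
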