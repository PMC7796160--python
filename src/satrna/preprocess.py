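"""Small RNA FASTQ preprocessing: quality filter, 3' adapter trim, length filter.

The filtering rules mirror a standard small-RNA library cleanup: reads must
exceed a mean per-base Phred quality of 20 (strict inequality), the 3'
sequencing adapter is removed by suffix/prefix overlap, and only inserts of
17-36 nt are retained. All steps conserve reads (kept + rejected = input) and
are idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import InvalidParameterError

__all__ = [
    "SmallRnaRead",
    "QcReport",
    "filter_by_quality",
    "trim_adapter",
    "filter_by_length",
    "preprocess_reads",
    "read_fastq",
    "write_fastq",
]

logger = logging.getLogger(__name__)

PHRED_OFFSET = 33


@dataclass(frozen=True)
class SmallRnaRead:
    """One sequenced small RNA read.

    U is converted to T on ingest so RNA-alphabet probe sequences and DNA
    reads live in one alphabet; the original alphabet is not retained.
    """

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QcReport:
    """Per-stage read bookkeeping for one library."""

    n_input: int = 0
    n_passed_quality: int = 0
    n_trimmed: int = 0
    n_passed_length: int = 0

    def to_tsv(self, path, comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if comment:
                fh.write(f"# {comment}\n")
            fh.write("metric\tcount\n")
            fh.write(f"input\t{self.n_input}\n")
            fh.write(f"passed_quality\t{self.n_passed_quality}\n")
            fh.write(f"trimmed\t{self.n_trimmed}\n")
            fh.write(f"passed_length\t{self.n_passed_length}\n")


def _phred_scores(quality: str) -> list[int]:
    scores = [ord(c) - PHRED_OFFSET for c in quality]
    if any(s < 0 or s > 93 for s in scores):
        raise ValueError("quality symbol outside Phred+33 range")
    return scores


def filter_by_quality(
    reads: Iterable[SmallRnaRead], min_mean_phred: float = 20.0, mode: str = "mean"
) -> tuple[list[SmallRnaRead], int]:
    """Keep reads whose quality is strictly above ``min_mean_phred``.

    ``mode="mean"`` (default) compares the mean per-base Phred score;
    ``mode="min"`` requires every base to exceed the threshold. Malformed
    records (quality/sequence length mismatch, symbols outside Phred+33) are
    rejected and logged rather than raised.

    Returns (kept reads, rejected count).
    """
    if mode not in ("mean", "min"):
        raise InvalidParameterError(f"unknown quality mode: {mode!r}")
    kept: list[SmallRnaRead] = []
    rejected = 0
    for read in reads:
        try:
            if len(read.quality) != len(read.sequence):
                raise ValueError("quality length does not match sequence length")
            scores = _phred_scores(read.quality)
            if not scores:
                raise ValueError("empty read")
            stat = sum(scores) / len(scores) if mode == "mean" else min(scores)
        except ValueError as exc:
            logger.warning("rejecting read %s: %s", read.id, exc)
            rejected += 1
            continue
        if stat > min_mean_phred:
            kept.append(read)
        else:
            rejected += 1
    return kept, rejected


def trim_adapter(
    read: SmallRnaRead,
    adapter: str,
    min_overlap: int = 3,
    max_mismatch_rate: float = 0.1,
) -> SmallRnaRead:
    """Remove the 3' adapter by longest suffix(read)/prefix(adapter) overlap.

    The longest suffix of the read that matches a prefix of the adapter with
    overlap >= ``min_overlap`` and mismatch rate <= ``max_mismatch_rate`` is
    cut off together with its quality symbols; if no overlap qualifies the
    read is returned unchanged.
    """
    if not adapter:
        raise InvalidParameterError("adapter must be non-empty when trimming is requested")
    if min_overlap < 1:
        raise InvalidParameterError("min_overlap must be >= 1")
    adapter = adapter.upper().replace("U", "T")
    seq = read.sequence
    for k in range(min(len(seq), len(adapter)), min_overlap - 1, -1):
        mism = sum(a != b for a, b in zip(seq[-k:], adapter[:k]))
        if mism <= max_mismatch_rate * k:
            return replace(read, sequence=seq[:-k], quality=read.quality[:-k])
    return read


def filter_by_length(
    reads: Iterable[SmallRnaRead], min_len: int = 17, max_len: int = 36
) -> tuple[list[SmallRnaRead], int]:
    """Keep reads with ``min_len <= length <= max_len`` (inclusive bounds)."""
    if min_len > max_len:
        raise InvalidParameterError("min_len must not exceed max_len")
    reads = list(reads)
    kept = [r for r in reads if min_len <= len(r) <= max_len]
    return kept, len(reads) - len(kept)


def preprocess_reads(
    reads: Sequence[SmallRnaRead],
    adapter: str = "",
    min_mean_phred: float = 20.0,
    quality_mode: str = "mean",
    min_len: int = 17,
    max_len: int = 36,
    min_overlap: int = 3,
    max_mismatch_rate: float = 0.1,
) -> tuple[list[SmallRnaRead], QcReport]:
    """Full cleanup: quality filter -> adapter trim -> length filter."""
    reads = list(reads)
    report = QcReport(n_input=len(reads))
    passed_q, _ = filter_by_quality(reads, min_mean_phred=min_mean_phred, mode=quality_mode)
    report.n_passed_quality = len(passed_q)
    if adapter:
        trimmed = [trim_adapter(r, adapter, min_overlap, max_mismatch_rate) for r in passed_q]
        report.n_trimmed = sum(1 for a, b in zip(passed_q, trimmed) if len(b) < len(a))
    else:
        trimmed = passed_q
    passed_len, _ = filter_by_length(trimmed, min_len=min_len, max_len=max_len)
    report.n_passed_length = len(passed_len)
    return passed_len, report


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33), via Biopython


def read_fastq(path) -> list[SmallRnaRead]:
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + PHRED_OFFSET) for q in rec.letter_annotations["phred_quality"])
        reads.append(SmallRnaRead(id=rec.id, sequence=str(rec.seq), quality=qual))
    return reads


def write_fastq(reads: Iterable[SmallRnaRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
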