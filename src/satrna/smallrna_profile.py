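"""Small RNA statistics on satellite-mapped reads.

Given alignments to a satellite consensus, this module computes the figures
of merit that characterize satellite small RNA populations:

* per-length, per-strand size histograms;
* siRNA/piRNA classification by length and the piRNA/siRNA count ratio
  (26-30 nt over 21-22 nt, both strands pooled);
* sense-strand and dominant-strand fractions per class;
* 5'-anchored position frequency matrices (sequence-logo input) in RNA
  alphabet, for the 1U-bias statistic;
* positional profiles of read 5' ends along the monomer (circular
  coordinates) and hotspot-region detection on those profiles.

Two size-window conventions coexist in the field and both are exposed:
``"ratio"`` mode (siRNA 21-22 nt, piRNA 26-30 nt — the windows the ratio is
defined on) and ``"histogram-group"`` mode (siRNA group 20-23 nt, piRNA
group 26-31 nt — the windows the size histograms are described with).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, NotComputableError
from .tandem_mapper import Alignment, SatelliteConsensus

__all__ = [
    "SizeHistogram",
    "ClassSummary",
    "StartProfile",
    "HotspotRegion",
    "classify_by_size",
    "size_histogram",
    "pirna_sirna_ratio",
    "strand_fractions",
    "position_frequency_matrix",
    "positional_start_profile",
    "detect_hotspots",
    "five_prime_position",
    "summarize",
]

MIN_LEN, MAX_LEN = 17, 36

SIRNA_RATIO_WINDOW = (21, 22)
PIRNA_RATIO_WINDOW = (26, 30)
SIRNA_GROUP_WINDOW = (20, 23)
PIRNA_GROUP_WINDOW = (26, 31)


def classify_by_size(length: int, mode: str = "ratio") -> str:
    """Classify a read length as siRNA, piRNA or other.

    ``mode="ratio"``: siRNA iff 21-22 nt, piRNA iff 26-30 nt (the windows the
    piRNA/siRNA ratio is defined on). ``mode="histogram-group"``: siRNA group
    20-23 nt, piRNA group 26-31 nt.
    """
    if mode == "ratio":
        si, pi = SIRNA_RATIO_WINDOW, PIRNA_RATIO_WINDOW
    elif mode == "histogram-group":
        si, pi = SIRNA_GROUP_WINDOW, PIRNA_GROUP_WINDOW
    else:
        raise InvalidParameterError(f"unknown size-classification mode: {mode!r}")
    if si[0] <= length <= si[1]:
        return "siRNA"
    if pi[0] <= length <= pi[1]:
        return "piRNA"
    return "other"


@dataclass
class SizeHistogram:
    """Mapped-read counts by (length 17-36 nt, strand)."""

    counts: pd.DataFrame  # index: length; columns: sense, antisense

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def class_count(self, window: tuple[int, int]) -> int:
        lo, hi = window
        return int(self.counts.loc[lo:hi].to_numpy().sum())

    def to_tsv(self, path, comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if comment:
                fh.write(f"# {comment}\n")
            self.counts.to_csv(fh, sep="\t", index_label="length")


def size_histogram(alignments: Iterable[Alignment]) -> SizeHistogram:
    """Per-length per-strand counts over the 17-36 nt range."""
    idx = range(MIN_LEN, MAX_LEN + 1)
    counts = pd.DataFrame(0, index=idx, columns=["sense", "antisense"])
    for a in alignments:
        if MIN_LEN <= a.read_length <= MAX_LEN:
            counts.loc[a.read_length, a.strand] += 1
        else:
            raise InvalidParameterError(
                f"alignment length {a.read_length} outside the {MIN_LEN}-{MAX_LEN} nt range"
            )
    return SizeHistogram(counts=counts)


def pirna_sirna_ratio(hist: SizeHistogram) -> float:
    """piRNA/siRNA count ratio: 26-30 nt over 21-22 nt, both strands pooled."""
    pirna = hist.class_count(PIRNA_RATIO_WINDOW)
    sirna = hist.class_count(SIRNA_RATIO_WINDOW)
    if sirna == 0:
        raise NotComputableError("siRNA (21-22 nt) count is zero; ratio undefined")
    return pirna / sirna


@dataclass
class ClassSummary:
    """Headline class statistics for one mapped library."""

    sirna_count: int
    pirna_count: int
    ratio: Optional[float]
    sense_fraction_sirna: Optional[float]
    dominant_strand_fraction_sirna: Optional[float]
    sense_fraction_pirna: Optional[float]
    dominant_strand_fraction_pirna: Optional[float]


def strand_fractions(
    alignments: Iterable[Alignment], rna_class: str, mode: str = "ratio"
) -> tuple[float, float]:
    """(sense fraction, dominant-strand fraction) for one size class."""
    sense = anti = 0
    for a in alignments:
        if classify_by_size(a.read_length, mode=mode) == rna_class:
            if a.strand == "sense":
                sense += 1
            else:
                anti += 1
    if sense + anti == 0:
        raise NotComputableError(f"no {rna_class} alignments; strand fractions undefined")
    f = sense / (sense + anti)
    return f, max(f, 1.0 - f)


def position_frequency_matrix(
    alignments: Iterable[Alignment],
    reads: Mapping[str, str],
    k: int,
) -> pd.DataFrame:
    """Base frequencies over the first ``k`` nt of each aligned read.

    Reads are taken in their sequenced (5'->3') orientation and reported in
    RNA alphabet (T shown as U), matching sequence-logo conventions. Rows are
    positions 1..k and sum to 1; rows without coverage are NaN.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    counts = np.zeros((k, 4), dtype=float)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    for a in alignments:
        seq = reads[a.read_id]
        if len(seq) < k:
            raise InvalidParameterError(
                f"read {a.read_id} shorter than k={k}; choose k <= min read length"
            )
        for pos in range(k):
            j = base_index.get(seq[pos])
            if j is not None:
                counts[pos, j] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, np.nan)
    return pd.DataFrame(freqs, index=range(1, k + 1), columns=["A", "C", "G", "U"])


def five_prime_position(alignment: Alignment, monomer_length: int) -> int:
    """Monomer coordinate (1-based, circular) of the read's 5' end.

    Sense reads start at ``alignment.start``; for antisense reads the 5' end
    sits at the rightmost consensus coordinate of the placement.
    """
    if alignment.strand == "sense":
        return alignment.start
    return ((alignment.start + alignment.read_length - 2) % monomer_length) + 1


@dataclass
class StartProfile:
    """Counts of read 5' ends at each monomer position for one class/strand."""

    consensus_name: str
    rna_class: str
    strand: str
    counts: np.ndarray  # length L, position i holds starts at coordinate i+1

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def positional_start_profile(
    alignments: Iterable[Alignment],
    consensus: SatelliteConsensus,
    rna_class: str,
    strand: str,
    mode: str = "ratio",
) -> StartProfile:
    """Distribution of read 5' ends along the monomer for one class and strand."""
    if strand not in ("sense", "antisense"):
        raise InvalidParameterError("strand must be sense or antisense")
    L = consensus.length
    counts = np.zeros(L, dtype=np.int64)
    for a in alignments:
        if a.consensus_name != consensus.name:
            raise InvalidParameterError(
                f"alignment to {a.consensus_name} mixed into a {consensus.name} profile"
            )
        if a.strand != strand:
            continue
        if classify_by_size(a.read_length, mode=mode) != rna_class:
            continue
        counts[five_prime_position(a, L) - 1] += 1
    return StartProfile(consensus_name=consensus.name, rna_class=rna_class, strand=strand, counts=counts)


@dataclass
class HotspotRegion:
    """A monomer interval holding a disproportionate share of 5' ends."""

    strand: str
    start: int  # 1-based inclusive
    end: int
    read_fraction: float


def detect_hotspots(
    profile: StartProfile,
    min_width: int = 10,
    min_fraction: Optional[float] = None,
    smoothing_window: int = 5,
) -> list[HotspotRegion]:
    """Call contiguous regions of elevated 5'-end density on a circular profile.

    The profile is smoothed with a centered circular moving sum of width
    ``smoothing_window``; positions whose smoothed value is at least
    ``min_fraction`` of the strand total are called and merged into runs
    (circularly, so a run may span the monomer junction). Runs narrower than
    ``min_width`` are discarded. ``min_fraction=None`` defaults to 1.5x the
    uniform expectation for the smoothing window, i.e.
    ``1.5 * smoothing_window / L``.

    A run that wraps the junction is reported as two intervals (start <= end
    always holds) whose combined width is used for the ``min_width`` test.
    """
    counts = np.asarray(profile.counts, dtype=float)
    L = len(counts)
    total = counts.sum()
    if L == 0:
        raise InvalidParameterError("empty profile")
    if total == 0:
        return []
    if smoothing_window < 1 or smoothing_window > L:
        raise InvalidParameterError("smoothing_window out of range")
    if min_fraction is None:
        min_fraction = 1.5 * smoothing_window / L
    # centered circular moving sum
    from scipy.ndimage import uniform_filter1d

    smoothed = uniform_filter1d(counts, size=smoothing_window, mode="wrap") * smoothing_window
    called = smoothed >= min_fraction * total
    if not called.any():
        return []
    if called.all():
        return [HotspotRegion(profile.strand, 1, L, 1.0)]
    # rotate so index 0 is uncalled; runs then never straddle the array ends
    shift = int(np.flatnonzero(~called)[0])
    rolled = np.roll(called, -shift)
    regions: list[HotspotRegion] = []
    in_run = False
    run_start = 0
    for i in range(L + 1):
        flag = rolled[i] if i < L else False
        if flag and not in_run:
            in_run, run_start = True, i
        elif not flag and in_run:
            in_run = False
            width = i - run_start
            if width < min_width:
                continue
            lo = (run_start + shift) % L  # 0-based inclusive
            hi = (i - 1 + shift) % L
            if lo <= hi:
                pieces = [(lo, hi)]
            else:  # wraps the junction
                pieces = [(lo, L - 1), (0, hi)]
            for a, b in pieces:
                frac = counts[a : b + 1].sum() / total
                regions.append(HotspotRegion(profile.strand, a + 1, b + 1, float(frac)))
    regions.sort(key=lambda r: r.start)
    return regions


# ---------------------------------------------------------------------------
# aggregate summary


def summarize(
    alignments: Sequence[Alignment],
    reads: Mapping[str, str],
    mode: str = "ratio",
) -> ClassSummary:
    """Headline statistics (counts, ratio, strand fractions) for one library."""
    hist = size_histogram(alignments)
    sirna = hist.class_count(SIRNA_RATIO_WINDOW if mode == "ratio" else SIRNA_GROUP_WINDOW)
    pirna = hist.class_count(PIRNA_RATIO_WINDOW if mode == "ratio" else PIRNA_GROUP_WINDOW)
    try:
        ratio = pirna_sirna_ratio(hist)
    except NotComputableError:
        ratio = None

    def _fractions(cls: str):
        try:
            return strand_fractions(alignments, cls, mode=mode)
        except NotComputableError:
            return None, None

    sf_si, dom_si = _fractions("siRNA")
    sf_pi, dom_pi = _fractions("piRNA")
    return ClassSummary(
        sirna_count=sirna,
        pirna_count=pirna,
        ratio=ratio,
        sense_fraction_sirna=sf_si,
        dominant_strand_fraction_sirna=dom_si,
        sense_fraction_pirna=sf_pi,
        dominant_strand_fraction_pirna=dom_pi,
    )


def write_summary_json(summary: ClassSummary, path, extra: Optional[dict] = None) -> None:
    payload = {
        "sirna_count": summary.sirna_count,
        "pirna_count": summary.pirna_count,
        "pirna_sirna_ratio": summary.ratio,
        "sense_fraction_sirna": summary.sense_fraction_sirna,
        "dominant_strand_fraction_sirna": summary.dominant_strand_fraction_sirna,
        "sense_fraction_pirna": summary.sense_fraction_pirna,
        "dominant_strand_fraction_pirna": summary.dominant_strand_fraction_pirna,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_hotspots_tsv(regions: Sequence[HotspotRegion], path, comment: str | None = None) -> None:
    """BED-like hotspot table; coordinates are 1-based inclusive."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("strand\tstart\tend\tread_fraction\n")
        for r in regions:
            fh.write(f"{r.strand}\t{r.start}\t{r.end}\t{r.read_fraction:.6f}\n")


def write_profile_tsv(profile: StartProfile, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("position\tcount\n")
        for i, c in enumerate(profile.counts, start=1):
            fh.write(f"{i}\t{int(c)}\n")
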