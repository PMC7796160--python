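"""Synthetic data with recorded ground truth for every pipeline input.

The generator emulates the small-RNA landscape of a tandem satellite locus:

* consensus monomers (random composition at a chosen GC fraction) and
  diverged subfamily variants;
* small RNA populations with two size classes — 21-22 nt double-strand
  symmetric siRNAs and 26-30 nt single-strand-dominant piRNAs with a 5'-U
  bias — whose 5' ends cluster in configurable hotspot regions of the
  monomer, sampled from the circular tandem repetition of the monomer so
  junction-spanning reads arise naturally;
* two-condition negative-binomial count matrices with known fold changes
  and per-sample depth factors;
* exponential-then-plateau qPCR fluorescence curves with known efficiency
  and starting concentration.

Every emitted read/feature/curve has a matching entry in a
:class:`TruthRecord`, so parameter-recovery tests can compare pipeline
estimates against configured truth. Identical seed and configuration give
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .preprocess import SmallRnaRead
from .qpcr_quant import AmplificationCurve
from .tandem_mapper import SatelliteConsensus, revcomp

__all__ = [
    "Hotspot",
    "SimulationConfig",
    "ReadTruth",
    "TruthRecord",
    "generate_monomer",
    "derive_subfamily",
    "simulate_small_rna_reads",
    "simulate_counts",
    "simulate_qpcr_curve",
    "class_mix_for_ratio",
    "DEFAULT_SIRNA_LENGTH_WEIGHTS",
    "DEFAULT_PIRNA_LENGTH_WEIGHTS",
    "DEFAULT_HOTSPOTS",
]

_BASES = np.array(list("ACGT"))

# siRNA lengths peak at 21 nt; piRNA lengths peak at 28 nt — the canonical
# size structure of satellite-derived small RNAs in T. castaneum embryos.
DEFAULT_SIRNA_LENGTH_WEIGHTS: dict[int, float] = {20: 0.15, 21: 0.50, 22: 0.25, 23: 0.10}
DEFAULT_PIRNA_LENGTH_WEIGHTS: dict[int, float] = {
    26: 0.10,
    27: 0.20,
    28: 0.30,
    29: 0.25,
    30: 0.10,
    31: 0.05,
}


@dataclass(frozen=True)
class Hotspot:
    """A monomer interval (1-based, inclusive) from which read 5' ends derive."""

    start: int
    end: int
    strand: str  # "sense" | "antisense"
    weight: float = 1.0


# Prominent read-origin regions of the 360 bp TCAST1B-like monomer: three
# sense blocks and one antisense block, uniformly weighted within each block.
DEFAULT_HOTSPOTS: tuple[Hotspot, ...] = (
    Hotspot(30, 70, "sense", 1.0),
    Hotspot(220, 260, "sense", 1.0),
    Hotspot(310, 340, "sense", 1.0),
    Hotspot(180, 240, "antisense", 1.0),
)


@dataclass
class SimulationConfig:
    """All knobs of the small-RNA read simulator, with study-like defaults."""

    seed: int = 0
    monomer_length: int = 360
    gc_fraction: float = 0.5
    subfamily_divergence: float = 0.10
    n_reads: int = 10_000
    # defaults give an expected piRNA(26-30)/siRNA(21-22) ratio of ~2.5,
    # the maternally deposited early-embryo ratio
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"siRNA": 0.32, "piRNA": 0.63, "other": 0.05}
    )
    sirna_length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIRNA_LENGTH_WEIGHTS)
    )
    pirna_length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PIRNA_LENGTH_WEIGHTS)
    )
    sense_fraction_sirna: float = 0.5
    sense_fraction_pirna: float = 0.8
    u1_prob_pirna: float = 0.75
    hotspots: tuple[Hotspot, ...] = DEFAULT_HOTSPOTS
    read_error_rate: float = 0.0
    adapter_seq: str = ""

    def validate(self) -> None:
        if self.monomer_length < 1:
            raise InvalidParameterError("monomer_length must be >= 1")
        if self.n_reads < 0:
            raise InvalidParameterError("n_reads must be >= 0")
        for name in (
            "gc_fraction",
            "subfamily_divergence",
            "sense_fraction_sirna",
            "sense_fraction_pirna",
            "u1_prob_pirna",
            "read_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")
        for label, dist in (
            ("class_mix", self.class_mix),
            ("sirna_length_weights", self.sirna_length_weights),
            ("pirna_length_weights", self.pirna_length_weights),
        ):
            if any(w < 0 for w in dist.values()):
                raise InvalidParameterError(f"{label} weights must be non-negative")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise InvalidParameterError(f"{label} must sum to 1 within 1e-9")
        if set(self.class_mix) - {"siRNA", "piRNA", "other"}:
            raise InvalidParameterError("class_mix keys must be siRNA/piRNA/other")
        if any(l < 20 or l > 23 for l in self.sirna_length_weights):
            raise InvalidParameterError("sirna_length_weights support is 20-23 nt")
        if any(l < 26 or l > 31 for l in self.pirna_length_weights):
            raise InvalidParameterError("pirna_length_weights support is 26-31 nt")
        for h in self.hotspots:
            if h.strand not in ("sense", "antisense"):
                raise InvalidParameterError(f"hotspot strand must be sense/antisense: {h}")
            if not (1 <= h.start <= h.end <= self.monomer_length):
                raise InvalidParameterError(f"hotspot interval outside [1, monomer_length]: {h}")
            if h.weight < 0:
                raise InvalidParameterError("hotspot weights must be non-negative")
        if self.adapter_seq and set(self.adapter_seq.upper()) - set("ACGT"):
            raise InvalidParameterError("adapter_seq must be a DNA string")

    @property
    def expected_pirna_sirna_ratio(self) -> float:
        """Configured ratio of 26-30 nt to 21-22 nt reads implied by the mix."""
        pi = self.class_mix.get("piRNA", 0.0) * sum(
            w for l, w in self.pirna_length_weights.items() if 26 <= l <= 30
        )
        si = self.class_mix.get("siRNA", 0.0) * sum(
            w for l, w in self.sirna_length_weights.items() if 21 <= l <= 22
        )
        return math.inf if si == 0 else pi / si


def class_mix_for_ratio(
    ratio: float,
    other: float = 0.05,
    sirna_length_weights: Optional[Mapping[int, float]] = None,
    pirna_length_weights: Optional[Mapping[int, float]] = None,
) -> dict[str, float]:
    """Class mix whose expected piRNA(26-30)/siRNA(21-22) count ratio is ``ratio``.

    Accounts for the part of each length distribution that falls outside the
    ratio windows (siRNA mass at 20/23 nt, piRNA mass at 31 nt).
    """
    if ratio <= 0:
        raise InvalidParameterError("ratio must be positive")
    if not 0 <= other < 1:
        raise InvalidParameterError("other fraction must lie in [0, 1)")
    sw = dict(sirna_length_weights or DEFAULT_SIRNA_LENGTH_WEIGHTS)
    pw = dict(pirna_length_weights or DEFAULT_PIRNA_LENGTH_WEIGHTS)
    p_si = sum(w for l, w in sw.items() if 21 <= l <= 22)
    p_pi = sum(w for l, w in pw.items() if 26 <= l <= 30)
    rel = ratio * p_si / p_pi  # required piRNA/siRNA class-probability ratio
    si = (1.0 - other) / (1.0 + rel)
    return {"siRNA": si, "piRNA": (1.0 - other) - si, "other": other}


@dataclass
class ReadTruth:
    """Ground truth for one simulated read."""

    rna_class: str  # siRNA | piRNA | other
    strand: str  # sense | antisense | .
    start: int  # 1-based leftmost monomer coordinate of the aligned segment (0 for "other")
    five_prime_pos: int  # monomer coordinate of the read's 5' end (0 for "other")
    length: int  # insert length before adapter
    first_base_is_u: bool
    u1_changed_template: bool  # True when the 5'-base draw differs from the template base
    n_errors: int


@dataclass
class TruthRecord:
    """Everything a recovery test needs, keyed the same way as the outputs."""

    reads: dict[str, ReadTruth] = field(default_factory=dict)
    dataset: dict = field(default_factory=dict)
    mutations: list[int] = field(default_factory=list)  # 1-based diverged positions
    features: dict[str, float] = field(default_factory=dict)  # feature -> fold change
    curves: dict[str, dict] = field(default_factory=dict)  # well -> {n0, efficiency, ...}

    def to_json(self, path) -> None:
        payload = {
            "reads": {k: asdict(v) for k, v in self.reads.items()},
            "dataset": self.dataset,
            "mutations": self.mutations,
            "features": self.features,
            "curves": self.curves,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            reads={k: ReadTruth(**v) for k, v in payload.get("reads", {}).items()},
            dataset=payload.get("dataset", {}),
            mutations=list(payload.get("mutations", [])),
            features=payload.get("features", {}),
            curves=payload.get("curves", {}),
        )


# ---------------------------------------------------------------------------
# consensus sequences


def generate_monomer(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Random monomer of the given length and GC composition (deterministic per seed)."""
    if length < 1:
        raise InvalidParameterError("monomer length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise InvalidParameterError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def derive_subfamily(monomer: str, divergence: float, seed: int = 0) -> tuple[str, list[int]]:
    """Diverged subfamily variant of a monomer.

    Each position is substituted (to one of the three other bases) with
    probability ``divergence``. Returns the variant and the 1-based list of
    substituted positions, so the realized Hamming distance is known exactly.
    """
    if not 0.0 <= divergence <= 1.0:
        raise InvalidParameterError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = list(monomer)
    mutated: list[int] = []
    hits = rng.random(len(seq)) < divergence
    for i in np.flatnonzero(hits):
        alternatives = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alternatives[rng.integers(0, 3)]
        mutated.append(int(i) + 1)
    return "".join(seq), mutated


# ---------------------------------------------------------------------------
# small RNA reads


def _substitute(base: str, rng: np.random.Generator) -> str:
    alternatives = [b for b in "ACGT" if b != base]
    return alternatives[rng.integers(0, 3)]


def simulate_small_rna_reads(
    config: SimulationConfig, consensus: SatelliteConsensus
) -> tuple[list[SmallRnaRead], TruthRecord]:
    """Simulate a small RNA library from the tandem circularization of a monomer.

    Per read: class from ``class_mix``; strand from the class's sense
    fraction; the 5' end position from the hotspot blocks of that strand
    (uniform within a block, blocks weighted) or uniform over the monomer
    when the strand has no block; length from the class's distribution.
    The read sequence is the corresponding substring of the infinite tandem
    repeat (reverse-complemented for antisense), so junction-spanning reads
    occur naturally. piRNA 5' bases are drawn so that the marginal
    probability of a 5' U equals ``u1_prob_pirna`` exactly; a draw that
    changes the template base is recorded in the truth (such reads carry one
    mismatch against the consensus). Per-base substitution errors and the 3'
    adapter are applied last. Qualities are constant Q37.

    "other" reads come from a random sequence unrelated to the consensus and
    exercise unmapped-read handling downstream.
    """
    config.validate()
    L = consensus.length
    max_len = max(
        max(config.sirna_length_weights, default=23), max(config.pirna_length_weights, default=31)
    )
    if L < max_len:
        raise InvalidParameterError("consensus shorter than the longest configured read length")
    # a strand with listed hotspots but zero total weight cannot be sampled
    for strand in ("sense", "antisense"):
        spots = [h for h in config.hotspots if h.strand == strand]
        if spots and sum(h.weight for h in spots) <= 0:
            raise InvalidParameterError(f"hotspots on {strand} strand have zero total weight")

    rng = np.random.default_rng(config.seed)
    tandem = consensus.monomer * (2 + max_len // L)
    # unrelated background for the "other" class
    decoy = "".join(np.random.default_rng(rng.integers(0, 2**31)).choice(_BASES, size=max(2 * L, 200)))

    class_names = ["siRNA", "piRNA", "other"]
    class_p = [config.class_mix.get(c, 0.0) for c in class_names]
    spots_by_strand = {
        s: [h for h in config.hotspots if h.strand == s] for s in ("sense", "antisense")
    }

    reads: list[SmallRnaRead] = []
    truth = TruthRecord()
    for i in range(config.n_reads):
        read_id = f"sr{i:06d}"
        cls = class_names[rng.choice(3, p=class_p)]
        if cls == "other":
            length = int(rng.integers(18, 31))
            pos = int(rng.integers(0, len(decoy) - length))
            seq = decoy[pos : pos + length]
            entry = ReadTruth(cls, ".", 0, 0, length, seq[0] == "T", False, 0)
        else:
            if cls == "siRNA":
                sense_frac = config.sense_fraction_sirna
                lengths = sorted(config.sirna_length_weights)
                weights = [config.sirna_length_weights[l] for l in lengths]
            else:
                sense_frac = config.sense_fraction_pirna
                lengths = sorted(config.pirna_length_weights)
                weights = [config.pirna_length_weights[l] for l in lengths]
            strand = "sense" if rng.random() < sense_frac else "antisense"
            length = int(lengths[rng.choice(len(lengths), p=weights)])
            spots = spots_by_strand[strand]
            if spots:
                w = np.array([h.weight for h in spots], dtype=float)
                h = spots[rng.choice(len(spots), p=w / w.sum())]
                pos5 = int(rng.integers(h.start, h.end + 1))
            else:
                pos5 = int(rng.integers(1, L + 1))
            if strand == "sense":
                start = pos5
                seq = tandem[start - 1 : start - 1 + length]
            else:
                start = ((pos5 - length) % L) + 1
                seq = revcomp(tandem[start - 1 : start - 1 + length])
            u1_changed = False
            first_u = seq[0] == "T"
            if cls == "piRNA":
                template_first = seq[0]
                if rng.random() < config.u1_prob_pirna:
                    first = "T"
                else:
                    first = template_first if template_first != "T" else "ACG"[rng.integers(0, 3)]
                u1_changed = first != template_first
                seq = first + seq[1:]
                first_u = first == "T"
            n_err = 0
            if config.read_error_rate > 0:
                chars = list(seq)
                hits = rng.random(length) < config.read_error_rate
                for j in np.flatnonzero(hits):
                    chars[j] = _substitute(chars[j], rng)
                    n_err += 1
                seq = "".join(chars)
                first_u = seq[0] == "T"
            entry = ReadTruth(cls, strand, start, pos5, length, first_u, u1_changed, n_err)
        if config.adapter_seq:
            seq = seq + config.adapter_seq.upper()
        reads.append(SmallRnaRead(id=read_id, sequence=seq, quality="F" * len(seq)))
        truth.reads[read_id] = entry

    truth.dataset = {
        "consensus_name": consensus.name,
        "monomer_length": L,
        "expected_pirna_sirna_ratio": config.expected_pirna_sirna_ratio,
        "sense_fraction_sirna": config.sense_fraction_sirna,
        "sense_fraction_pirna": config.sense_fraction_pirna,
        "u1_prob_pirna": config.u1_prob_pirna,
        "class_mix": dict(config.class_mix),
        "n_reads": config.n_reads,
    }
    return reads, truth


# ---------------------------------------------------------------------------
# two-condition counts


def simulate_counts(
    n_per_group: int,
    baseline_mean,
    fold_change,
    dispersion: float = 0.0,
    depth_factors: Optional[Sequence[float]] = None,
    seed: int = 0,
    features: Optional[Sequence[str]] = None,
    group_labels: tuple[str, str] = ("control", "HS_30min"),
) -> tuple[pd.DataFrame, dict[str, str], TruthRecord]:
    """Negative-binomial two-group count matrix with known per-feature fold changes.

    ``baseline_mean`` and ``fold_change`` may be scalars or per-feature
    sequences. Group-2 feature means are baseline x fold x per-sample depth
    factor. ``dispersion=0`` produces the deterministic Poisson-limit
    fixture: counts are the expected means rounded to the nearest integer.

    Returns (counts DataFrame features x samples, sample->group mapping, truth).
    """
    if n_per_group < 1:
        raise InvalidParameterError("n_per_group must be >= 1")
    if dispersion < 0:
        raise InvalidParameterError("dispersion must be >= 0")
    baseline = np.atleast_1d(np.asarray(baseline_mean, dtype=float))
    fold = np.atleast_1d(np.asarray(fold_change, dtype=float))
    n_features = max(len(baseline), len(fold))
    baseline = np.broadcast_to(baseline, (n_features,))
    fold = np.broadcast_to(fold, (n_features,))
    if np.any(baseline <= 0):
        raise InvalidParameterError("baseline_mean must be positive")
    if np.any(fold <= 0):
        raise InvalidParameterError("fold_change must be positive")
    if features is None:
        features = [f"feature_{i + 1}" for i in range(n_features)]
    if len(features) != n_features:
        raise InvalidParameterError("features length does not match baseline/fold length")

    group_a, group_b = group_labels
    samples = [f"{group_a}_{j + 1}" for j in range(n_per_group)] + [
        f"{group_b}_{j + 1}" for j in range(n_per_group)
    ]
    groups = {s: (group_a if j < n_per_group else group_b) for j, s in enumerate(samples)}
    if depth_factors is None:
        depth = np.ones(2 * n_per_group)
    else:
        depth = np.asarray(depth_factors, dtype=float)
        if depth.shape != (2 * n_per_group,) or np.any(depth <= 0):
            raise InvalidParameterError("depth_factors must be 2*n_per_group positive values")

    mean = baseline[:, None] * np.ones((1, 2 * n_per_group))
    mean[:, n_per_group:] *= fold[:, None]
    mean *= depth[None, :]

    rng = np.random.default_rng(seed)
    if dispersion == 0:
        counts = np.rint(mean).astype(int)
    else:
        r = 1.0 / dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    df = pd.DataFrame(counts, index=list(features), columns=samples)
    truth = TruthRecord(
        features={f: float(fc) for f, fc in zip(features, fold)},
        dataset={
            "n_per_group": n_per_group,
            "dispersion": dispersion,
            "depth_factors": depth.tolist(),
            "group_labels": list(group_labels),
        },
    )
    return df, groups, truth


# ---------------------------------------------------------------------------
# qPCR curves


def simulate_qpcr_curve(
    n0: float,
    efficiency: float,
    n_cycles: int = 40,
    plateau: float = 1.0,
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    seed: int = 0,
    well_id: str = "w1",
    target: str = "",
    sample: str = "",
) -> tuple[AmplificationCurve, TruthRecord]:
    """Exponential-then-plateau amplification curve with known E and N0.

    Fluorescence at cycle c is ``min(n0 * E**c, plateau) + baseline + noise``
    with Gaussian noise of standard deviation ``noise_sd``.
    """
    if not 1.0 < efficiency <= 2.0:
        raise InvalidParameterError("efficiency must lie in (1, 2]")
    if n0 <= 0 or n0 >= plateau:
        raise InvalidParameterError("n0 must satisfy 0 < n0 < plateau")
    if n_cycles < 10:
        raise InvalidParameterError("n_cycles must be >= 10")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1)
    signal = np.minimum(n0 * efficiency ** cycles.astype(float), plateau)
    fluor = signal + baseline + (rng.normal(0.0, noise_sd, n_cycles) if noise_sd > 0 else 0.0)
    curve = AmplificationCurve(
        cycles=tuple(int(c) for c in cycles),
        fluorescence=tuple(float(f) for f in fluor),
        well_id=well_id,
        target=target,
        sample=sample,
    )
    truth = TruthRecord(
        curves={
            well_id: {
                "n0": float(n0),
                "efficiency": float(efficiency),
                "plateau": float(plateau),
                "baseline": float(baseline),
                "noise_sd": float(noise_sd),
            }
        }
    )
    return curve, truth


# ---------------------------------------------------------------------------
# file emission helpers


def write_consensus_fasta(consensus_set: Sequence[SatelliteConsensus], path) -> None:
    with open(path, "w") as fh:
        for c in consensus_set:
            fh.write(f">{c.name}\n")
            for i in range(0, c.length, 70):
                fh.write(c.monomer[i : i + 70] + "\n")


def write_counts_tsv(counts: pd.DataFrame, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        counts.to_csv(fh, sep="\t", index_label="feature")
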