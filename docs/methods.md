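# Methods

## The analysis model

The package treats a satellite locus as the infinite tandem repetition of a
single consensus monomer of length L (e.g. 360 bp for a TCAST1B-like
subfamily, 359 bp for a TCAST2A-like one). All positional statements are made
in circular monomer coordinates, 1-based and inclusive. Reads are mapped
against the consensus *dimer* — the monomer concatenated with itself — so a
read that spans the junction between two monomer copies aligns contiguously;
any placement starting in the second copy is collapsed modulo L and
deduplicated, so each read contributes exactly one alignment with a start in
`[1, L]`.

Small RNA classes are defined by read length. Two window conventions are
exposed because both are in common use: the **ratio** windows (siRNA 21–22
nt, piRNA 26–30 nt) define the piRNA/siRNA count ratio, and the
**histogram-group** windows (20–23 nt and 26–31 nt) describe the two modes of
the size distribution. The ratio pools both strands. Strand structure is
summarized as the sense fraction and the dominant-strand fraction
`max(f, 1−f)`; base composition as a position frequency matrix over the first
k nt of the reads in sequenced orientation, reported in RNA alphabet, whose
first row carries the 1U-bias statistic.

## Alignment

The mapper is an exhaustive ungapped scorer: every one of the `2L − len + 1`
offsets of the read, and of its reverse complement, along the dimer is scored
by Hamming distance (vectorized over offsets). The best placement wins if its
mismatch count does not exceed `max_mismatches` (default 2 for small RNAs;
for long-RNA fragments the helper `default_max_mismatches` allows
`ceil(10% · length)`). Ties are broken deterministically: fewer mismatches,
sense before antisense, smaller collapsed start. Subfamily assignment aligns
a read against every consensus and keeps the single best alignment, breaking
equal scores by lexicographic consensus name, so each read is counted once.

Indels are not modelled: at 17–36 nt against a consensus, satellite copy
divergence is substitution-dominated, and the restriction keeps an exact
brute-force oracle (every rotation of the monomer, both strands, pure Python)
feasible — the test suite checks exact agreement, including ties, on random
and planted reads.

Consequences worth knowing: reads drawn from a window that is identical in
two subfamilies cross-assign to the lexicographically first name, and since
shorter reads are more likely to fall in conserved windows, *per-subfamily*
class ratios are biased relative to the library-wide truth. Library-level
statistics should therefore be computed over all subfamilies pooled (the
end-to-end tests do exactly this).

## Preprocessing

Quality filtering retains a read iff its mean per-base Phred score is
strictly greater than the threshold (default 20). The strictness and the
per-read mean are deliberate interpretations; a per-base-minimum mode is
available (`mode="min"`). Malformed records are rejected and logged, never
raised. Adapter trimming removes the longest suffix of the read matching a
prefix of the 3' adapter with overlap ≥ `min_overlap` (default 3) and
mismatch rate ≤ `max_mismatch_rate` (default 0.1). Length filtering keeps
17–36 nt inclusive. All filters conserve reads (kept + rejected = input) and
are idempotent.

## Hotspot detection

Start profiles (counts of 5' ends per monomer position, per class and
strand; for antisense reads the 5' end is the rightmost consensus coordinate
of the placement) are smoothed with a centered circular moving sum of width
`smoothing_window` (default 5 bp). Positions whose smoothed value reaches
`min_fraction` of the strand total are called and merged into runs; the
default threshold is 1.5× the uniform expectation (`1.5·w/L`). Runs narrower
than `min_width` (default 10 bp) are discarded; a run that wraps the monomer
junction is reported as two intervals (so `start ≤ end` always holds) whose
combined width is used for the width test. With these defaults the detector's
region boundaries land within ±2–3 bp of simulated block edges (the smoothing
window extends calls by up to `⌊w/2⌋` positions).

## Expression quantification

Counts are one per read (fragments count once when mates share a read id).
Size factors are median-of-ratios: the reference is the per-feature geometric
mean over samples, features containing any zero are excluded, and
`s_j = median_i(K_ij / ref_i)`. Factors are defined up to a common scale;
all downstream statements are scale-free. Fold change is the ratio of
pseudocount-stabilized group means of normalized counts (pseudocount default
0.5). The reported p-value is a Welch t-test on log2 normalized counts and is
flagged approximate on the result object: no negative-binomial shrinkage or
Wald machinery is replicated, because the quantification design — counting on
consensus dimers, depth normalization, normalized-mean ratios — is the object
of interest here, not the differential-expression estimator. FPKM is
`count / (length_kb · total/10⁶)`.

Median-of-ratios needs a majority of non-changing features to anchor the
reference. With a single induced satellite on a small stable panel the group
medians shift slightly and folds are underestimated by a few percent; the
recovery harnesses therefore place the satellite on a backbone of stable
background features spanning typical expression levels (10 in the unit tests,
30 in the acceptance script), emulating whole-library normalization.

## qPCR quantification

The baseline is the mean fluorescence of the first `n_baseline_cycles`
(default 5) cycles, which must precede the exponential rise. Efficiency is
estimated by the window-of-linearity approach: among all windows of
`window_len` (default 5, sensible range 4–6) consecutive cycles whose
corrected fluorescence is strictly positive and within 3–90% of the curve
maximum — the upper log-linear region, where signal dominates baseline noise
and plateau compression has not begun — the window maximizing the r² of
log10(F) against cycle is chosen and `E = 10^slope`. If no window satisfies
the signal bounds the search falls back to all-positive windows; a flat or
non-increasing best window raises a non-amplifying error rather than
returning E ≤ 1. Cq is the fractional threshold crossing found by log-linear
interpolation, and `N0 = threshold / E^Cq` in arbitrary fluorescence units.
The default threshold is 10% of the corrected plateau, clamped into the
best-fit window's fluorescence range; on noiseless curves N0 is independent
of the threshold within the exponential region. Technical replicates are
averaged on the N0 scale; relative expression divides the target/reference N0
ratio by its control-condition counterpart, and ChIP levels divide IP by
input N0.

The error in N0 is approximately `Cq · ΔE/E`, so efficiency accuracy
dominates. Under the simulator's realistic machine-noise setting (Gaussian
noise with SD 5×10⁻⁴ of the plateau, baseline 5% of plateau, N0 well below
detection so the baseline window is flat), recovery is within ±0.05 of E and
±20% of N0 across E ∈ {1.7, 1.85, 2.0}.

## What the simulator does and does not emulate

`satsim` generates: random-composition monomers at a chosen GC fraction;
subfamily variants by per-site substitution at a configured divergence (with
the mutated positions recorded, so realized Hamming distances are exact);
small RNA libraries with per-class length distributions (siRNA peaking at 21
nt, piRNA at 28 nt), per-class sense fractions, hotspot-weighted 5' start
positions (defaults: sense blocks 30–70, 220–260, 310–340; antisense
180–240), per-base substitution errors, a constant-Q37 quality string and an
optional 3' adapter; negative-binomial two-group count matrices (dispersion 0
means deterministic rounded means — a useful exact fixture); and
exponential-then-plateau qPCR curves `min(N0·E^c, plateau) + baseline +
noise`.

The piRNA 5' base is drawn so that the *marginal* probability of a 5' U
equals `u1_prob_pirna` exactly (T with probability u1, otherwise the template
base, or a random non-T base when the template is already T). A draw that
changes the template base is recorded per read; such reads carry exactly one
mismatch against the consensus and still map at their true start under the
default mismatch allowance. Reads of the background ("other") class come from
an unrelated random sequence and exercise unmapped handling.

Not emulated: indel sequencing errors, quality-value/error coupling,
ping-pong (10-nt 5' overlap) amplification signatures, chimeric reads, PCR
duplicates, and any genome context beyond the tandem array. Passing recovery
tests therefore demonstrates correctness of the statistics under
substitution-only noise and a single-locus model — not robustness to
structural artifacts of real libraries.

## Default parameters at a glance

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| quality threshold | 20, strict, per-read mean | Phred | standard small-RNA QC cutoff |
| length window | 17–36 inclusive | nt | small-RNA insert range |
| `max_mismatches` (small RNA) | 2 | mismatches | tolerates subfamily divergence at 17–36 nt |
| ratio windows | 21–22 vs 26–30 | nt | siRNA/piRNA definitions |
| histogram groups | 20–23 vs 26–31 | nt | distribution modes |
| hotspot smoothing / width / threshold | 5 / 10 / 1.5× uniform | bp | resolves ≥10 bp blocks against a flat background |
| pseudocount | 0.5 | normalized counts | stabilizes zero-count features |
| qPCR window length | 5 | cycles | window-of-linearity convention (4–6) |
| qPCR signal bounds | 3–90% of max | — | upper log-linear region |
| qPCR threshold | 10% of plateau | fluorescence | mid-exponential crossing |
| simulated class mix | siRNA 0.32 / piRNA 0.63 / other 0.05 | — | implies ratio ≈ 2.5 (early-embryo condition) |
| simulated sense fractions | siRNA 0.5, piRNA 0.8 | — | double- vs single-stranded precursors |
| simulated `u1_prob_pirna` | 0.75 | — | strong but not absolute 1U bias |
| simulated qPCR noise | 5×10⁻⁴ of plateau | fluorescence | realistic instrument noise |

## Problem sizes used by the validation harnesses

Parameter-recovery tests use 50,000-read libraries over 10 seeds; the
mapper/oracle agreement check uses 1,000 random read–monomer pairs at L ≤
100; fold-change recovery uses 20 replicate matrices at 50 samples per group
and NB dispersion 0.05; qPCR round trips use 40-cycle curves, 10 seeds per
efficiency. The acceptance script simulates 30,000-read libraries per
condition and triplicate curve sets. These sizes make binomial sampling error
comfortably smaller than the tolerances being checked.

## Known limitations

* Exhaustive ungapped scoring is O(L · len) per read — appropriate for
  consensus-scale references, not genomes.
* Per-subfamily statistics are biased by conserved-window cross-assignment
  (see Alignment above); pool subfamilies for library-level quantities.
* The approximate p-value is anti-conservative for very small groups with
  strong mean–variance coupling; it is a screening aid, not a substitute for
  a count-model test.
* qPCR efficiency is assumed cycle-invariant within the fitted window;
  curves with drifting efficiency will bias N0.
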