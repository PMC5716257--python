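# Methods

## The homology signal

`introscan` models introgression detection as one-dimensional signal
segmentation. The observable is, for each reference position, the fraction
of covering reads whose aligned base matches the reference. That fraction
is derived purely from the `MD` tag of each alignment record, which encodes
match run-lengths, mismatched reference bases and deleted reference bases
in reference space. Insertions in the read consume no reference bases,
never appear in `MD`, and are deliberately ignored: the score vector lives
in reference coordinates, and only reference-consuming events belong in it.
CIGAR strings are not consulted.

Two assumptions underlie the score:

* the reference is structurally homologous to the recurrent parent's
  genome, so the background signal is high (near 1 minus the sequencing
  error rate plus residual parent/reference divergence);
* introgressed segments diverge from the reference at many positions
  (intronic/intergenic drift between the parent species) and/or lose
  coverage, so their per-base score is depressed over a contiguous range.

**Column-mean convention.** The per-position score is the mean over the
reads that actually cover the position — not a mean over a fixed maximum
read depth. Averaging over a fixed depth would scale every score by
coverage/depth and make a homology threshold in the 0.85–0.95 range
meaningless at any realistic coverage. Zero-coverage positions score 0
exactly, which is how large unaligned regions (deletions relative to the
reference, strongly diverged insertions) pull the smoothed signal down.

## Smoothing

1. **Moving average** with an all-ones window of length `w` (default
   1000 bp), normalized to a mean. Only fully-overlapping windows are
   emitted, so the output length is `L − w + 1`: a 10,000-point input at
   `w = 300` yields exactly 9,701 points. The truncation costs `w − 1`
   points at the chromosome ends — order 10⁻⁵ of a chromosome-scale
   sequence, and tests confirm it does not perturb region recovery.
   Implementation is a cumulative-sum difference (exact, O(L)), clipped
   into [0, 1] against accumulated float error.
2. **LOWESS** (tricube-weighted local linear regression, via statsmodels)
   with fit window `frac · L_c` points. Defaults: `frac = 0.05`, three
   robustifying iterations, and an interpolation delta of 0.1% of the
   signal length (fitted anchors every ~`0.001·L` positions, linear
   interpolation between them). The delta and robustness settings are the
   standard way to make LOWESS affordable at chromosome scale — the naive
   fit is O(`frac · L²`) — and both are configurable; with `delta = 0` the
   classical pointwise fit is recovered. Fitted values are clipped into
   [0, 1], the documented range of the homology signal.

Signal index 0 is anchored at reference position 1 (left-aligned windows).
The alternative (centering windows) would shift coordinates by `w/2`;
with `w` three to four orders of magnitude smaller than a chromosome the
choice is immaterial, and left-anchoring keeps region starts at coordinate
1 representable.

For toy chromosomes the model scales `w` down to `L/10` with a warning
rather than failing; the low-pass window must stay small against the
features of interest.

## Region calling

The classifier is a strict threshold: a region opens at the first signal
position with `h < t` and closes at the last position before `h ≥ t`.
Ties (`h == t`) are outside the call. A region still open at the end of
the signal closes at the final *signal* coordinate, not the chromosome
end — the truncated tail was never examined and is not claimed. No minimum
region length is imposed by default (`--min-length` exists as an optional
screen). Calls are emitted as 1-based inclusive intervals internally and
0-based half-open BED externally.

Useful consequences, verified as properties in the test suite: calls are
exactly the connected components of `{h < t}`; and the set of called
positions is non-decreasing in `t`, so raising the threshold can only grow
(never move) calls.

## Evaluation and tuning

Region-level confusion counts need a negative class. The package defines
negatives as the syntenic blocks *not* selected for introgression in a
simulated hybrid — the natural units the simulated genome is assembled
from. This denominator is a package design choice (a fixed-size tiling of
the genome is the obvious alternative) and the evaluation accepts any
disjoint negative set. A truth region overlapped by ≥ 1 bp of any call is
a TP; a call overlapping no truth is a FP; rates with undefined
denominators are reported as missing rather than 0.

**Loci accuracy** measures positional fidelity: the fraction of recovered
truths whose best-overlapping call (largest overlap, ties to the leftmost)
has its center within ±5% of the true-center *coordinate*. Interpreting
the tolerance as 5% of the center coordinate (rather than of region
length) follows the metric's illustration on simulated data; the tolerance
is a parameter for users who prefer the other reading.

**ROC scan.** LOWESS is recomputed per `frac` (the low-pass stage is
shared across the grid), thresholding per `t`, and metrics are pooled
across genomes and chromosomes. The selected operating point is the pair
with the greatest TPR among rows with FPR exactly 0 — the greatest
sensitivity before the onset of false positives. If every row has false
positives the scan falls back to maximizing TPR − FPR, with a warning.
Default grids: `frac ∈ {0.05, 0.01}`, `t ∈ {0.85, 0.90, 0.95}` — thresholds
in 5% steps around a 90% background homology, and `frac` values small
enough to keep the LOWESS window affordable at chromosome scale.

## The simulator

`generate_toy_parents` builds a uniform-random maternal genome and a
paternal genome diverged from it by i.i.d. substitutions at a configurable
per-base rate (default 0.10, a plant congener-scale divergence), with
optional small (1–3 bp) indels. Syntenic blocks are placed one per
equal-width slot across each chromosome, which keeps them disjoint,
separated, and away from the ends; coordinates map identically between
parents when the indel rate is 0.

`make_simulated_hybrids` splices the paternal sequence of randomly selected
blocks into the maternal background. Selection is Bernoulli per block
(default p = 0.5) or a fixed count; spliced lengths may differ, downstream
coordinates shift accordingly, and the truth log (arguments, seed, chosen
blocks, hybrid-coordinate truth regions, length deltas) makes the run
reproducible and the hybrid reconstructible.

`simulate_reads` draws fragments uniformly (length-weighted across
chromosomes), reports both 75 bp ends of each 500 bp fragment (R2
reverse-complemented in FASTQ), and applies i.i.d. substitution errors at
2% per base. `emit_truth_alignments` then writes each read at its true
coordinate as a proper-paired SAM record with an all-match CIGAR and an MD
tag computed against the scoring reference. Aligning hybrid-derived reads
to the maternal reference this way reproduces, by construction, the
mismatch statistics the detector keys on.

**What this emulates and what it does not.** The simulation captures the
signal-generating mechanism: contiguous blocks of elevated mismatch rate
on an otherwise homologous background, at controlled depth, with known
truth. It does not emulate read mapping itself — no mapping ambiguity,
repeats, soft-clipping, indel alignment artifacts, coverage bias, or
quality-dependent errors — nor CNVs or structural variation beyond block
replacement. Passing the recovery tests therefore demonstrates the
correctness of the scoring/smoothing/calling chain under the stated noise
model, not robustness to alignment pathologies of real data; for real use
the detector consumes externally produced, MD-tagged, duplicate-removed
BAMs.

## Problem sizes used in the packaged studies

The packaged end-to-end study runs on a 1 Mbp single-chromosome genome at
10% parental divergence, 8 syntenic blocks of 50–70 kbp with 3
introgressed, and 15× read depth (100,000 pairs); the coverage-degradation
study reruns it at 100/80/60/40/20% of the reads (15× down to 3×). These
sizes exercise every code path at full parameter defaults (`w` = 1 kbp,
`frac` = 0.05, `t` = 0.90) while keeping a complete run in tens of seconds;
block sizes are kept at or above the LOWESS fit window (`0.05 × 1 Mbp =
50 kbp`) since the fit cannot preserve a dip much narrower than its window
— the same scaling a user should respect when choosing `frac` for real
chromosomes.

## Known limitations

* Events invisible in reference space are invisible to the method: CNVs
  whose extra copies are absent from the reference, and indels larger than
  what fits within a single aligned read.
* Sensitivity degrades with depth; below roughly 10× the score track
  acquires enough zero-coverage positions that shallow introgressions can
  be missed (the low-coverage study tracks this), while the fidelity (PPV)
  of calls that are made remains high.
* Introgressions much smaller than `frac · L_c` are smoothed away;
  detecting them requires a smaller `frac`, at the cost of noise
  sensitivity and run time.
* The threshold classifier reports no confidence measure on call
  boundaries; boundary placement depends on the signal slopes at the
  threshold crossings.
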