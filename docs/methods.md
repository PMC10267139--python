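# Methods

`atacfoot` implements the chromatin-accessibility comparison machinery used
to contrast fetal-state (cord-blood, CB) and adult-state (bone-marrow, BM)
erythroid cells by ATAC-seq: a universal peak atlas, a negative-binomial
differential-accessibility test, GC-matched motif enrichment, and
transposase-bias-corrected transcription-factor footprinting. Every stage
runs on synthetic data with planted ground truth, so the properties the
pipeline claims (bias absorption, de-confounding, calibration) are checked
end to end without any external download.

## Peak atlas and normalisation

Per sample, the top `top_k` (default 50 000) peaks by caller score are
reduced to fixed windows `[summit − 250, summit + 250)` and union-merged
across samples (abutting windows merge; ties at the `top_k` boundary break
by genomic order). The per-sample *peak score* is the number of single-base
cut sites falling in each atlas interval; a fragment-overlap mode is
deliberately out of scope because the footprinting stage works in cut-site
currency and the package keeps one coordinate system.

Scores are normalised by a closed-form negative-binomial
variance-stabilising transform

    g(n) = log2( q + 1/(2α) + sqrt( q(q + 1/α) + 1/(4α²) ) ),   q = n/s,

with median-of-ratios size factors `s` and a single common dispersion `α`
fit by maximum likelihood on the scaled counts. A full mean–dispersion
trend (as the reference R implementation fits) is unnecessary here: the
downstream uses of the normalised scores — the 80th-percentile maximum
filter and threshold classification — are rank-driven, and the transform is
strictly monotone per sample for any `α`. The percentile filter keeps peaks
whose cross-sample maximum reaches the `q`-quantile (linear interpolation,
`≥` at the boundary; default q = 0.80). Whether the filter sees raw or VST
scores is selectable; VST is the default.

## Differential accessibility

Counts per peak are modelled as NB with a log link, offsets
`log(size factor)`, and a design of intercept + source indicator +
categorical covariates (population stage; dataset batch for cell-line
comparisons). Because the design is shared, IRLS is batched across peaks.
Population is encoded categorically: it is ordinal in principle, but no
trend model is assumed.

Dispersion: per-peak Cox–Reid-adjusted profile MLE on a log grid
(40 points, 1e-6…5, parabolic refinement), then a 50/50 **arithmetic**
blend with the pooled common CR-MLE. The arithmetic midpoint is a
deliberate choice: a log-space midpoint collapses for peaks whose
dispersion MLE degenerates to zero (sample variance below the Poisson
floor, common at 6–12 samples), which makes their Wald tests strongly
anti-conservative; blending on the natural scale keeps such peaks near
half the common dispersion and yields a measured type-I fraction of
~0.055 at p < 0.05 on a 2000-peak null with 12 samples.

The Wald statistic on the source coefficient (converted to log2) gives a
two-sided normal p-value; BH adjustment runs over tested peaks only
(all-zero peaks are untestable and excluded from the denominator). No
independent filtering and no fold-change shrinkage are applied — labels use
raw Wald output with the thresholds FDR < 0.1, |log2FC| > log2(1.25) for
differential peaks and p > 0.1, |log2FC| < log2(1.25) for the background
set. Both the 0.1 and an alternative 0.05 FDR threshold are plain
parameters.

## Motif scanning and GC-matched enrichment

PWM matches are scored as log2 likelihood ratios against the background
composition; zero probabilities receive a 1e-4 pseudo-probability. Match
p-values are exact: column scores are discretised to 1/1000 bit and the
null score distribution is built by dynamic-programming convolution, so
`p(s) = P(score ≥ s)` needs no simulation and is monotone in the score.
The genome-wide defaults are p ≤ 1e-4 and at most 500 000 instances per
motif (best-by-p, ties by coordinate). A motif of width W cannot score
below p = 4^-W, so widths ≤ 6 can never reach 1e-4; the pipeline therefore
scans each motif at `max(1e-4, 1.2 × max-score p)`, which retains exactly
the consensus tier for short motifs.

Enrichment per direction is a one-sided (greater) Fisher exact test on
binary motif presence (≥ 1 instance overlapping the peak) in differential
versus background peaks, BH-corrected across motifs within a direction.
The background is GC-matched: GC values of the pooled
differential + background peaks are cut into 20 equal-occupancy quantile
bins ("equally sized" is read as equal occupancy; equal width is available
by flag; bin edges derive from the union), and 2500 background peaks are
drawn so the selected bin proportions equal the differential set's. The
draw is an exact stratified allocation (largest-remainder rounding, uniform
within bin) rather than a single weighted draw without replacement: when
the requested sample is a sizable fraction of the pool, sequential weighted
sampling saturates in heavy bins and leaves residual GC confounding
(measured false-positive rate ~0.25 instead of ~0.05 in the confounded-null
experiment). Bins whose allocation exceeds the pool are reported and their
excess redistributed proportionally.

## Hexamer bias correction and footprinting

Tn5 inserts with a strong local sequence preference, modelled at hexamer
resolution. Three ingredients:

* **Genome model** — sliding-window hexamer proportions over the genome,
  excluding blacklist-overlapping and N-containing windows.
* **Positional model** — per motif, the hexamer at every offset
  −250…+250 around the motif center over all instances, oriented by
  instance strand, each position row scaled to mean 1 over the 4096
  hexamers.
* **Cut factors** — per sample, the hexamer share at cut sites divided by
  the genomic share, renormalised to sum 1.

The hexamer anchored at a cut/position `p` is the reference window
`[p − 3, p + 3)`; for minus-strand cuts and minus-oriented instances the
same window is reverse-complemented. This register is symmetric about the
insertion bond between `p − 1` and `p`, which is the physically meaningful
axis for a transposase acting on duplex DNA; the correction's validity
depends on applying one register consistently across all three models, not
on the register itself. Motif centers are `start + floor(W/2)`.

Expected profile: `e = positional @ factors`, normalised to sum 1.
Footprint score: both the observed per-position cut counts (pooled over cut
strands, oriented by instance strand, all instances counted including
overlapping ones) and the expected profile are scaled to mean 1 and the
score is `log2(observed/expected)`; positions with zero observed or
expected are masked. Summary statistics for motif width W:

* base region `|pos| ≤ W/2 + 5`; flank `min(18, W/2 + 10) ≤ |pos| ≤ 50`;
  background `200 ≤ |pos| ≤ 250` (102 positions).
* `FPD = trimmed_mean(base) − mean(flank)` (10% trimmed each tail,
  `floor(0.1 k)` values); `FA = mean(flank) − mean(background)`.

The `min()` in the flank inner edge is implemented literally; for W > 26 it
lets the base region overlap the flank, and a `widest_inner` flag switches
to `max()` for users who consider that a transcription error. FA and FPD
are invariant to sequencing depth by construction (mean-1 normalisation).

A structural caveat surfaced by the synthetic studies: for short motifs,
the hexamers inside the motif occur in the genome mostly *at* motif
instances, so when a large fraction of instances is protected the cut
factors themselves absorb part of the footprint (the expected profile dips
with the observed one). The effect is strongest at window positions whose
hexamer lies fully inside the motif and vanishes as unbound instances
dominate — the situation in real genomes. The planted-footprint benchmark
sizes its instance counts so the residual signal still separates cleanly
from decoy noise.

## Synthetic data

The generator emulates: i.i.d. genomes with controllable GC; planted
consensus motif instances (consensus, not PWM-sampled, so planted
instances always pass the scanner deterministically); cut sites drawn from
a multinomial whose position weights are the hexamer bias table times a
flat protection factor inside protected instances (no shoulder effect —
the simplest model producing the FPD signature); cut strands i.i.d.
Bernoulli(1/2); and NB count matrices with planted source log2
fold-changes, lognormal size factors, random per-population effects and an
optional GC confound. The bias table is lognormal (σ = 0.5, about an order
of magnitude across hexamers, comparable to real Tn5 preference) and
reverse-complement symmetric — the enzyme reads the duplex, so its
preference cannot depend on strand.

Not emulated: read-level artefacts (FASTQ, fragment lengths, duplicates),
diploid genomes, chromatin-state autocorrelation along the genome,
position-dependent protection ("shoulders"), and motif degeneracy in
planted instances. Tests passing on this generator therefore demonstrate
the *computational* properties of the pipeline (the correction absorbs
exactly the bias class it models; matching removes exactly the planted
confound), not robustness to every artefact of real libraries.

Reference experiment sizes, chosen as the package's standard benchmark
conditions: bias null on a 2 Mb genome at 1e6 cuts with 3000 planted
instances per motif; planted-footprint ranking on a 400 kb genome at 4e6
cuts per condition with protection factor 0.2, NFI instance counts
200/300/400 (13/6/5-mer) and twenty 8-mer decoys × 300 instances;
GC-confound experiment with 800 differential peaks (GC shift +0.05,
σ = 0.06) against a pool of 20 000, 2500 matched draws, 100 repeats; NB
calibration on 2000 peaks × 12 samples (2 sources × populations 3–5 × 2
replicates, dispersion 0.02) and recovery of balanced ±2 log2FC effects
with 3 vs 3 samples. Recovery effects are planted symmetrically because a
30% one-directional differential fraction biases median-of-ratios size
factors — a property of the normalisation itself, visible in any
implementation.

## Numerical choices and degenerate inputs

* IRLS: up to 30 iterations, tolerance 1e-10 on coefficients, linear
  predictor clipped to ±30; initialisation from `log(max(y, 0.5))`.
* Size factors fall back to ignoring zeros in the geometric reference when
  no peak has all-positive counts.
* Rank-deficient designs abort with the aliased columns named; windows
  with < 2 samples per contrast level abort.
* `gc_matched_sample` returns the whole pool (with a warning) when the
  pool is not larger than the request; all-N peaks have undefined GC and
  are excluded.
* Scanner tie-breaks: instance cap keeps best by p, then coordinate;
  planting ties in consensus columns resolve to the alphabetically first
  base.
* All generators and samplers take explicit integer seeds and are
  bit-reproducible.

## Limitations

* Footprinting currently assumes a single-contig genome (sufficient for
  the synthetic studies; multi-contig support would only require keying
  the per-base tracks by chromosome).
* The NB test targets threshold classification, not numerical parity with
  DESeq2: no dispersion prior width estimation, no independent filtering,
  no lfc shrinkage.
* The naive summit picker bundled with the generator is plumbing for
  simulated tracks; real analyses should supply peak-caller output
  (narrowPeak).
* Exact PWM p-values assume a zeroth-order background; dinucleotide
  backgrounds are out of scope.
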