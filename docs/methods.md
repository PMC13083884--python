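# Methods

This note documents the models, conventions and design choices behind
`poisedpol`, in the spirit of a methods appendix: what each procedure
assumes, which parameters matter, and what the synthetic-data tests do and
do not demonstrate about real data.

## Coordinates and windows

All internal coordinates are 0-based half-open; GTF input is converted at
the file boundary.  The TSS of a plus-strand gene is `start`, of a
minus-strand gene `end − 1`; multi-TSS genes carry an explicit `tss_list`
and every distance-based classification takes the minimum over TSSs.  The
promoter-proximal window is the first 5% of the gene from the TSS in the
direction of transcription, the gene body runs from 30% of gene length to
the TES; window lengths use round-half-away-from-zero with a 1 bp minimum,
so the two windows never overlap for genes ≥ 4 bp.  "±2 kb of the TSS"
means the closed symmetric window `[tss − 2000, tss + 2000]`, clipped at
chromosome edges.  Coverage tracks are stored as dense per-base arrays per
chromosome (a degenerate step function); the bedGraph writer run-length
encodes and omits zero runs.

## Peak calling

The caller is deliberately a *simplified* MACS-like procedure, not a
reimplementation of MACS3: the replicate-consensus classification downstream
is the scientific content, and the caller only needs to be calibrated and
local-background aware.

* Sliding windows (default 200 bp, half-window step) are tested against a
  Poisson null with per-bp rate λ = max(genome-wide mean, local means over
  ±5 kb and ±10 kb, and — when an IgG/control track is supplied — the
  control's local means including at the test-window scale, depth-matched).
  Including the fine scale from the control is what suppresses enrichment
  shared between treatment and control.
* Window sums and λ are divided by the track's "quantum" (its smallest
  positive value) before the Poisson tail test.  Poisson tests are not
  scale invariant; for any positive multiple of an integer-count track this
  normalization restores exactly the counts, making peak calls invariant
  under rescaling.
* Window p-values are BH-corrected genome-wide; windows with q ≤ FDR are
  merged across gaps ≤ 100 bp.  Each merged candidate is trimmed to its
  enriched core — the maximum-sum run of per-base excess over λ, searched
  over the candidate plus one window margin — because the union of
  significant windows overstates an enrichment's width by up to a window on
  each side.  Trimmed candidates shorter than 150 bp are discarded; the
  summit is the leftmost maximum.
* FDR presets: 0.01 (default) and 0.1 are both retained; the two values
  correspond to two calibrations in routine use and neither is privileged
  by the implementation.

On pure Poisson noise the fraction of the genome inside called peaks stays
far below the nominal FDR (the acceptance script measures it at ~0 across
20 seeds); the test bound (≤ 2× nominal) is deliberately loose.

## Consensus classification

A gene is poised / accessible / factor-bound when the relevant assay shows
a peak summit within ±2 kb of at least one of its TSSs in ≥ `min_reps` (2)
of the biological replicates.  The call is monotone: adding a qualifying
replicate can only turn a negative into a positive.

## Normalization

* RPM: values × 10⁶ / mapped reads.  Tracks carry a normalization state and
  refuse double normalization.
* Nascent-transcription spike scaling: factor = ploidy × spike reads /
  mapped reads ("as-stated", the published direction, which scales signal up
  with more spike-in), or ploidy × 10⁶ / spike reads ("reciprocal", the
  conventional direction).  Both modes are implemented because the published
  formula's direction is unusual; the mode is recorded in track metadata.
  The ploidy factor is 0.5 for haploid round-spermatid libraries.
* Tagmentation-assay spike scaling: factor = 10,000 / E. coli reads.
* Between-condition comparisons (knockout vs control) use spike scaling,
  not RPM: per-million normalization absorbs a genuine global loss of
  signal into the library size, biasing fold changes toward 1, whereas a
  constant-material spike-in preserves it.

## Pausing metrics

The pausing index divides per-bp densities (not raw sums) because the
promoter and body windows differ in length; the ratio of raw sums is
available as `mode="reads"`.  Genes with zero body signal return a missing
index and are excluded (never zero-filled) from downstream rank statistics.
The Ser5P pause ratio uses the strand-aware 30-nt window +31..+60 from the
TSS (1-based inclusive offsets) over the same 30%→TES body window.  Both
statistics are invariant under rescaling the track.  Metagene matrices pad
off-chromosome bases with NaN and average with NaN exclusion.

## Statistics

* Paired Wilcoxon signed-rank: zero differences dropped; for n ≤ 25 the
  exact two-sided p is computed by dynamic programming over all 2ⁿ sign
  assignments of the (possibly tied, average) ranks — doubling ranks makes
  them integers, so the null distribution is an exact convolution.  For
  larger n the tie-corrected normal approximation is used.  The exact
  branch is hand-written because standard exact routines refuse tied ranks.
* BH FDR and Fisher's exact test delegate to statsmodels and scipy; the
  test suite cross-checks them against hand step-up computation and
  hypergeometric tail summation.
* Fold-change comparisons report the median per-gene ratio (A+ε)/(B+ε) with
  ε = 0.01 normalized units; the median is invariant to common rescaling of
  both conditions.
* Quartile stratification sorts ascending by occupancy (ties broken by
  gene id) into Q1 = ⌈n/4⌉ lowest, Q4 = ⌊n/4⌋ highest, Q2&Q3 the rest —
  sizes (251, 500, 250), (144, 288, 143), (82, 163, 81) for n = 1001, 575,
  326.
* Multi-TSS promoter signal uses the TSS with maximal signal (the
  representative promoter); averaging over TSSs is available behind a flag.

## Motif enrichment

Only known-motif enrichment is implemented; de-novo discovery is out of
scope.  The CCAAT-box motif `RRCCAATSRS` is scanned as an IUPAC pattern on
both strands with overlapping hits allowed; a sequence `N` matches no
specific code.  A region (±75 bp around a peak summit) "has" the motif if
it contains ≥ 1 hit; enrichment versus background promoters is a one-sided
Fisher exact test, with Haldane 0.5 correction of the odds ratio when a
cell is zero, and BH correction across a motif panel.  This is simpler
than the motif-caller it replaces (which weights hit counts and builds its
own background); only the binary region-level call is modeled.

## Single-cell rules

QC keeps RNA cells with ≥ 500 detected genes and < 5% mitochondrial UMIs,
and ATAC cells with ≥ 1000 fragments and TSS score ≥ 4.  The TSS score is
an explicit stand-in for the unnamed per-cell enrichment computation in
common toolkits: fragment-end insertions within ±50 bp of TSSs per bp,
divided by the insertion rate in two 100-bp background windows centered
±1950 bp from the TSS, with +1 added to the background count so sparse
cells score finitely.  Uniform random insertions score ≈ 1.  Differential
classes use a two-sided rank-sum test across cells on depth-normalized
counts (counts × median library / cell library; log-normalize-to-10k is
available) with the published class boundaries FC ≤ 0.5 / ≥ 2 at
FDR ≤ 0.05; the test statistic itself is a documented choice, since only
the thresholds are fixed by the classification.

## The synthetic-data generator

The generator emulates the study design so the pipeline can be validated
against known labels.  Defaults are the study conditions: 600 genes, three
replicates per condition, 2×10⁵ reads per track, knockout reduction
θ = 0.75 at bound promoters (occupancy gradient 0.83 → 0.67 in gradient
mode), pausing enrichment 2 in SpG versus 1 in later stages, spike-in
counts jittered ±5%.

* Genome: i.i.d. uniform A/C/G/T; gene lengths log-normal (median ~3 kb,
  σ = 0.45, clipped to 1.2–15 kb), ≥ 5 kb spacing, random strand.  Category
  fractions 0.15 / 0.35 / 0.25 / 0.25 (mitosis / meiosis-I /
  spermiogenesis / control); 70% of meiotic and spermiogenic genes are
  poised, 40% of poised genes are bound, echoing the observed proportions.
* Tracks: expected per-base rate = background (0.005 reads/bp before depth
  scaling) + stage×category gene-body rate + a Gaussian promoter bump
  (σ = 75 bp at the TSS).  For nascent transcription the bump area solves
  promoter-window density = r × body density exactly, so the recovered
  pausing index converges to the designed r; poised genes carry a modest
  engaged-Pol II body signal in SpG (one expression unit) so the index is
  defined there, while non-poised promoters sit near background.  For
  accessibility/occupancy assays the bump is a fixed expected mass
  (~60 reads before depth scaling, several hundred after), which satisfies
  the ≥ 50 reads/promoter regime the fold-change recovery assumes;
  occupancy-assay bumps scale with the gene's true occupancy.
* Knockout: the promoter bump of each bound gene is multiplied by its true
  θ.  Depth is anchored on the control condition, so the knockout library
  genuinely yields fewer genomic reads; forcing both conditions to equal
  depth would re-inflate the knockout signal and bias recovered fold
  changes toward 1 (by ~10% when bound promoters dominate the library).
* Randomness: one seed with named substreams per (assay, stage, condition,
  replicate), so adding a replicate never perturbs the others; reads are
  Poisson per base.
* Motifs: every bound promoter receives one sampled realization of the
  CCAAT-box motif within ±75 bp of the TSS; all other promoter windows are
  scrubbed of chance hits (collisions logged).
* Single cells: per-gene log-normal baseline (mean ~6 UMIs/gene), 10% of
  genes deregulated at true FC 3 or 1/3, 10% of cells injected as QC
  failures (low detected genes or high mitochondrial fraction, low
  fragments, low TSS score).  Fragment tables place 80% of fragments at
  open promoters (knockout-reduced at bound genes) and 20% uniformly.

### What passing tests show — and what they do not

The generator produces idealized data: uniform base composition (no CpG
islands or mappability structure), single-fragment-length reads, no batch
effects, no replicate-level biological variance beyond Poisson noise,
promoter bumps that are exactly Gaussian, and ground-truth labels that are
mutually consistent by construction (accessible ⇔ poised; bound ⇒ poised).
Recovery of θ to ±0.05 and ≥ 95% label agreement therefore demonstrate
that the *estimators and classification rules* are correct and calibrated
under the designed noise model — not that real libraries meet these
conditions.  On real data, peak-caller calibration, normalization choices
and fragment models all contribute additional error that these tests do not
probe.

## Problem sizes

The validation analyses run at the design scale of the study they emulate:
600 genes (≈ 5 Mb genome) for label, pausing and gradient recovery; 834
genes with all meiotic/spermiogenic genes bound (≈ 500 bound promoters) for
uniform-θ recovery; 2 Mb × 20 seeds for noise false-discovery measurement.
These sizes keep the full suite and the acceptance script within a few
minutes on one CPU while leaving each estimate's sampling error well inside
the tested tolerances.

## Known limitations

* The peak caller's score is the BH q-value of its best window, not a
  model-based score; it is not intended to reproduce any external caller's
  scores or boundaries exactly.
* Enhancer derivation treats ≥ 1 bp overlap as overlap and removes whole
  peaks (no trimming); the minimum-overlap convention is a stated choice.
* The control-gene rule ("within 2× across stages") is an explicit
  assumption; the published analysis reports only the resulting set size.
* Between-condition fold changes assume spike-in material is constant per
  sample; violations (e.g. cell-count differences) propagate directly into
  the estimate, as with any spike-in design.
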