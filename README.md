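# poisedpol

Quantitative analysis of **promoter poising** in pre-meiotic male germ cells:
identifying genes whose promoters carry paused RNA polymerase II, accessible
chromatin and a CCAAT-box transcription factor *before* their transcriptional
activation in meiosis, and measuring how promoter accessibility and paused
Pol II respond to knockout of that factor.

The package is written for computational biologists working with
PRO-seq / ATAC-seq / CUT&RUN / CUT&Tag coverage data from staged germ-cell
populations (spermatogonia SpG, spermatocyte stages L/Z, P/D, SpI, round
spermatids RS).  It runs end-to-end on synthetic coverage data with known
ground truth, so every classification rule and effect-size estimate can be
validated against the labels that generated the data.

## What it computes

**Gene categories from absolute transcript abundance.**  Molecules of a
transcript per cell are obtained by ERCC spike-in scaling,

    abundance = reads x 623,291,645 / (n_cells x ERCC reads),

and genes are classified by stage fold changes (pseudocount ε): *mitosis*
(SpG ≥ 4x all later stages), *meiosis-I* (P/D ≥ 4x all other stages),
*spermiogenesis* (P/D ≥ 4x SpG, within 2x of SpII and RS), and a *control*
set whose abundance stays within 2x across stages.

**Poised / accessible / bound promoter calls.**  A simplified MACS-like
Poisson caller tests sliding windows against
λ = max(genome mean, ±5 kb and ±10 kb local means, IgG control), applies
Benjamini–Hochberg correction, merges significant windows and trims each
candidate to its enriched core (candidates < 150 bp are dropped).  A gene is
called poised / accessible / factor-bound when a peak summit lies within
±2 kb of at least one of its TSSs in ≥ 2 of 3 biological replicates.

**Pausing metrics.**  The pausing index is the signal density over the
promoter-proximal window (TSS to 5% of gene length) divided by the density
over the gene body (30% of length to the TES); the Ser5P pause ratio uses
the +31..+60 nt window.  Metagene matrices resample each gene into fixed
flanks plus length-normalized body bins, oriented 5'→3'.

**Knockout comparisons.**  Promoter signal is the mean normalized coverage
at ±200 bp of the TSS (±500 bp / ±2 kb selectable).  Knockout / control
fold change is the median per-gene ratio (A+ε)/(B+ε) with a two-sided
Wilcoxon matched-pairs signed-rank p-value (exact permutation distribution
for n ≤ 25, tie-corrected normal approximation above); bound promoters are
stratified into occupancy quartiles Q1 / Q2&Q3 / Q4 of sizes
⌈n/4⌉ / n−⌈n/4⌉−⌊n/4⌋ / ⌊n/4⌋.

**Motif enrichment.**  IUPAC scanning of the CCAAT-box motif `RRCCAATSRS`
(both strands, overlapping hits) in ±75 bp around peak summits, with a
one-sided Fisher exact test against background promoters and BH correction
across motifs.

**Single-cell rules.**  RNA QC (≥ 500 genes, < 5% mitochondrial UMIs), ATAC
QC (≥ 1000 fragments, TSS score ≥ 4), UMI deduplication, the Tn5 +4/−5
shift, pseudobulk ±200 bp promoter accessibility, and threshold-based
differential classes (FC ≤ 0.5 or ≥ 2 at FDR ≤ 0.05).

**Ground-truth generator.**  `SimulationDesign` / `make_genome` /
`simulate_tracks` / `simulate_cells` produce a genome with planted motifs,
stage- and category-structured multi-replicate coverage with Poisson read
noise and spike-in counts, and single-cell tables — with every label
(category, poised, bound, occupancy quartile, true reduction θ) recorded.

## Worked example

```python
import poisedpol as pp

design = pp.SimulationDesign()          # 600 genes, 3 replicates, 2e5 reads/track
study = pp.make_genome(design, seed=1)

# classify genes from simulated engaged-polymerase coverage (SpG, 3 replicates)
from poisedpol.workflows import consensus_status
poised_calls = consensus_status(study, "proseq", "SpG")
truth = study.truth
label_genes = truth["category"].isin(["meiosis_I", "spermiogenesis"])
agreement = (poised_calls[label_genes] == truth.loc[label_genes, "poised"]).mean()
print(f"poised consensus calls: {int(poised_calls[label_genes].sum())} of {int(label_genes.sum())} genes")
print(f"agreement with ground truth: {100 * agreement:.1f}%")

# pausing index of one poised gene, averaged over replicates
gene = study.genes_by_flag("poised")[0]
indexes = []
for rep in (1, 2, 3):
    track, _ = pp.simulate_tracks(study, "proseq", "SpG", "control", rep)
    indexes.append(pp.pausing_index(track, gene))
print(f"{gene.gene_id} pausing index (mean of 3 replicates): {pp.replicate_average(indexes):.2f}")
```

Output:

```
poised consensus calls: 244 of 360 genes
agreement with ground truth: 97.8%
g0001 pausing index (mean of 3 replicates): 2.25
```

244 of the 360 meiosis-I/spermiogenesis genes carry an engaged-Pol II peak
within ±2 kb of a TSS in at least two replicates; 97.8% of the calls match
the generator's poised labels.  The example gene was simulated with a
promoter pausing enrichment of 2 in SpG, and its recovered index (2.25)
reflects that plus Poisson counting noise.

A command-line interface wraps the same steps
(`poisedpol simulate | callpeaks | report | config`); each stage appends a
provenance record (input digests, seed, version) to `run_log.jsonl`.

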