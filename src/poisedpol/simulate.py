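"""Ground-truth synthetic data generator.

Emulates the study design the pipeline analyses: a small genome carrying
non-overlapping genes in four expression categories (mitosis, meiosis-I,
spermiogenesis, control), multi-replicate coverage tracks for nascent
transcription (PRO-seq-like), chromatin accessibility (ATAC-like), factor
occupancy (CUT&RUN-like with an IgG control) and Pol II Ser5P (CUT&Tag-like),
plus single-cell count/fragment tables.

Structure of a simulated track: expected per-base rate = background
+ stage-dependent gene-body rate + a Gaussian promoter bump (sd 75 bp,
centered at the TSS).  For nascent transcription the bump area is solved so
that the promoter-window density equals r x the body density (r is the
designed pausing enrichment), making the recovered pausing index converge to
r.  For accessibility/occupancy assays the bump is a fixed expected read
mass per promoter.  In the knockout condition the promoter bump of each
factor-bound gene is multiplied by that gene's true reduction theta.  Reads
are drawn Poisson per base after scaling the expected rate to the designed
depth; spike-in read counts are jittered +/-5% around the design value.

Every bound-gene promoter receives one planted CCAAT-box (RRCCAATSRS)
realization within +/-75 bp of the TSS; unbound promoter windows are
scrubbed of chance hits (collisions logged).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import GeneModel, GenomeSequence, promoter_window
from .coverage import CoverageTrack, LibraryStats
from .motifs import IUPAC, NFYA_MOTIF, MotifModel, iupac_scan

logger = logging.getLogger(__name__)

__all__ = ["SimulationDesign", "SimulatedStudy", "make_genome",
           "simulate_tracks", "simulate_cells"]

PROSEQ_STAGES = ("SpG", "SpI", "RS")
ATAC_STAGES = ("SpG", "L/Z", "P/D")

# gene-body rate multipliers (x body_rate reads/bp) per assay stage
_PROSEQ_BODY = {
    "mitosis": {"SpG": 3.0, "SpI": 1.0, "RS": 0.5},
    "meiosis_I": {"SpG": None, "SpI": 3.0, "RS": 1.0},  # None: poised-dependent
    "spermiogenesis": {"SpG": None, "SpI": 2.0, "RS": 2.0},
    "control": {"SpG": 1.0, "SpI": 1.0, "RS": 1.0},
}
_POISED_SPG_BODY = 1.0  # poised genes carry modest engaged signal in SpG
_NONPOISED_SPG_BODY = 0.1  # closed promoters: body signal near background


@dataclass
class SimulationDesign:
    """Ground-truth design of the synthetic study.

    Defaults are the study conditions: 600 genes, three biological
    replicates per condition, 2e5 reads per track, knockout reduction
    theta = 0.75 at bound promoters with an occupancy gradient
    0.83 (Q1) .. 0.67 (Q4) when ``theta_mode="gradient"``, and a pausing
    enrichment of 2 in SpG against 1 in later stages.
    """

    n_genes: int = 600
    gene_len_log_mean: float = float(np.log(3000.0))
    gene_len_log_sd: float = 0.45
    gene_len_min: int = 1200
    gene_len_max: int = 15000
    gene_spacing: int = 5000
    category_fractions: dict = field(default_factory=lambda: {
        "mitosis": 0.15, "meiosis_I": 0.35, "spermiogenesis": 0.25, "control": 0.25,
    })
    poised_fraction: float = 0.7
    bound_fraction: float = 0.4
    pausing_r: dict = field(default_factory=lambda: {"SpG": 2.0, "SpI": 1.0, "RS": 1.0})
    theta: float = 0.75
    theta_q1: float = 0.83
    theta_q4: float = 0.67
    theta_mode: str = "uniform"  # or "gradient"
    depth: int = 200_000
    replicates: int = 3
    spikein_reads: int = 10_000
    background_rate: float = 0.005  # expected reads/bp before depth scaling
    body_rate: float = 0.05  # expected reads/bp of one expression unit
    bump_sd: float = 75.0
    promoter_bump_reads: float = 60.0  # ATAC/CUT&RUN/CUT&Tag bump mass
    occupancy_log_sd: float = 0.5
    # single-cell block
    n_cells: int = 200
    sc_mean_umis_per_gene: float = 6.0
    sc_dereg_fraction: float = 0.10
    sc_dereg_fc: float = 3.0
    sc_qc_fail_rate: float = 0.10
    chrom_name: str = "chrS"

    def __post_init__(self):
        total = sum(self.category_fractions.values())
        if total > 1 + 1e-9 or any(f < 0 for f in self.category_fractions.values()):
            raise ValueError("category fractions must be in [0,1] and sum <= 1")
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for frac in (self.poised_fraction, self.bound_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class SimulatedStudy:
    """A realized genome with gene models and per-gene ground truth.

    ``truth`` columns: category, poised, bound, occupancy, quartile, theta.
    Poised/bound labels are defined over meiosis-I and spermiogenesis genes
    (the categories the poised classification applies to).
    """

    design: SimulationDesign
    genome: GenomeSequence
    genes: list[GeneModel]
    truth: pd.DataFrame
    seed: int

    def genes_by_flag(self, column: str, value=True) -> list[GeneModel]:
        wanted = set(self.truth.index[self.truth[column] == value])
        return [g for g in self.genes if g.gene_id in wanted]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent child stream: adding a stream never perturbs others."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(name.encode())])


def _largest_remainder_counts(fractions: dict, n: int) -> dict:
    raw = {k: f * n for k, f in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - np.floor(raw[k]), reverse=True)[:short]:
        counts[k] += 1
    return counts


def _sample_motif(rng: np.random.Generator, motif: str = NFYA_MOTIF) -> str:
    return "".join(rng.choice(list(IUPAC[c].replace("N", ""))) for c in motif)


def make_genome(design: SimulationDesign, seed: int = 0) -> SimulatedStudy:
    """Build the genome sequence, gene models and ground-truth labels."""
    rng = _substream(seed, "genome")

    counts = _largest_remainder_counts(design.category_fractions, design.n_genes)
    leftover = design.n_genes - sum(counts.values())
    counts["control"] = counts.get("control", 0) + leftover
    categories = [c for c, n in counts.items() for _ in range(n)]
    rng.shuffle(categories)

    lengths = np.exp(rng.normal(design.gene_len_log_mean, design.gene_len_log_sd,
                                design.n_genes))
    lengths = np.clip(lengths, design.gene_len_min, design.gene_len_max).astype(int)

    chrom_len = int(lengths.sum() + design.gene_spacing * (design.n_genes + 1))
    base_codes = rng.integers(0, 4, size=chrom_len)
    seq = bytearray(np.frombuffer(b"ACGT", dtype=np.uint8)[base_codes].tobytes())

    genes, truth_rows = [], []
    pos = design.gene_spacing
    for i, (cat, length) in enumerate(zip(categories, lengths)):
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(gene_id=f"g{i:04d}", chrom=design.chrom_name,
                         start=pos, end=pos + int(length), strand=strand,
                         category_hint=cat)
        genes.append(gene)
        pos += int(length) + design.gene_spacing
        truth_rows.append({"gene_id": gene.gene_id, "category": cat})
    truth = pd.DataFrame(truth_rows).set_index("gene_id")

    # poised / bound labels among meiosis-I and spermiogenesis genes
    truth["poised"] = False
    truth["bound"] = False
    for cat in ("meiosis_I", "spermiogenesis"):
        ids = list(truth.index[truth["category"] == cat])
        n_poised = int(round(design.poised_fraction * len(ids)))
        poised_ids = list(rng.choice(ids, size=n_poised, replace=False)) if n_poised else []
        truth.loc[poised_ids, "poised"] = True
    poised_ids = list(truth.index[truth["poised"]])
    n_bound = int(round(design.bound_fraction * len(poised_ids)))
    bound_ids = list(rng.choice(poised_ids, size=n_bound, replace=False)) if n_bound else []
    truth.loc[bound_ids, "bound"] = True

    # occupancy, quartiles and per-gene knockout reduction theta
    truth["occupancy"] = np.nan
    truth["quartile"] = ""
    truth["theta"] = 1.0
    if bound_ids:
        occ = rng.lognormal(mean=0.0, sigma=design.occupancy_log_sd, size=len(bound_ids))
        truth.loc[bound_ids, "occupancy"] = occ
        order = sorted(bound_ids, key=lambda g: (truth.at[g, "occupancy"], g))
        n = len(order)
        n_q1, n_q4 = -(-n // 4), n // 4
        truth.loc[order[:n_q1], "quartile"] = "Q1"
        truth.loc[order[n_q1 : n - n_q4], "quartile"] = "Q2Q3"
        truth.loc[order[n - n_q4 :], "quartile"] = "Q4"
        if design.theta_mode == "uniform":
            truth.loc[bound_ids, "theta"] = design.theta
        elif design.theta_mode == "gradient":
            ranks = {g: i for i, g in enumerate(order)}
            span = max(n - 1, 1)
            for g in bound_ids:
                frac = ranks[g] / span
                truth.at[g, "theta"] = design.theta_q1 + frac * (design.theta_q4 - design.theta_q1)
        else:
            raise ValueError(f"unknown theta_mode {design.theta_mode!r}")

    _plant_and_scrub_motifs(seq, genes, truth, rng)

    genome = GenomeSequence(sequences={design.chrom_name: seq.decode()})
    if pos > chrom_len:
        raise ValueError("genome too small to place genes")
    return SimulatedStudy(design=design, genome=genome, genes=genes,
                          truth=truth, seed=int(seed))


def _plant_and_scrub_motifs(seq: bytearray, genes, truth, rng,
                            flank: int = 75) -> None:
    """Plant one motif realization per bound promoter; scrub all other
    promoter windows of chance hits."""
    motif = MotifModel(NFYA_MOTIF)
    mlen = len(motif.iupac)
    collisions = 0
    for gene in genes:
        tss = gene.canonical_tss
        lo, hi = max(0, tss - flank), min(len(seq), tss + flank + 1)
        if truth.at[gene.gene_id, "bound"]:
            realization = _sample_motif(rng)
            start = int(rng.integers(lo, hi - mlen))
            seq[start : start + mlen] = realization.encode()
            # clear chance hits elsewhere in the window, keeping the plant
            for _ in range(20):
                window = seq[lo:hi].decode()
                hits = iupac_scan(window, motif)
                extra = [h for h in hits if abs((lo + h.start) - start) >= mlen]
                if not extra:
                    break
                collisions += 1
                for h in extra:
                    for k in range(mlen):
                        p = lo + h.start + k
                        if not (start <= p < start + mlen):
                            seq[p] = ord(rng.choice(list("ACGT")))
        else:
            for _ in range(20):
                window = seq[lo:hi].decode()
                hits = iupac_scan(window, motif)
                if not hits:
                    break
                collisions += 1
                for h in hits:
                    p = lo + h.start + rng.integers(0, mlen)
                    seq[p] = ord(rng.choice(list("ACGT")))
    if collisions:
        logger.info("motif planting: scrubbed %d chance-hit windows", collisions)


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

def _bump_profile(length: int, center: int, area: float, sd: float) -> np.ndarray:
    """Expected-read profile of a Gaussian promoter bump clipped to the
    chromosome (mass evaluated per base over +/- 5 sd)."""
    lo = max(0, int(center - 5 * sd))
    hi = min(length, int(center + 5 * sd) + 1)
    x = np.arange(lo, hi)
    mass = norm.pdf(x, loc=center, scale=sd) * area
    out = np.zeros(length)
    out[lo:hi] = mass
    return out


def _promoter_mass_fraction(gene: GeneModel, sd: float,
                            promoter_fraction: float = 0.05) -> float:
    """Fraction of a TSS-centered Gaussian falling inside the promoter window."""
    win = promoter_window(gene, promoter_fraction)
    tss = gene.canonical_tss
    a, b = win.start - tss, win.end - tss
    return float(norm.cdf(b, scale=sd) - norm.cdf(a, scale=sd))


def _proseq_rate(study: SimulatedStudy, stage: str) -> np.ndarray:
    d = study.design
    L = study.genome.chrom_sizes[d.chrom_name]
    rate = np.full(L, d.background_rate)
    r_stage = d.pausing_r.get(stage, 1.0)
    for gene in study.genes:
        row = study.truth.loc[gene.gene_id]
        mult = _PROSEQ_BODY[row["category"]][stage]
        if mult is None:
            mult = _POISED_SPG_BODY if row["poised"] else _NONPOISED_SPG_BODY
        body = mult * d.body_rate
        rate[gene.start : gene.end] += body
        paused = row["poised"] and stage == "SpG"
        r = r_stage if paused else 1.0
        if r > 1 and body > 0:
            win = promoter_window(gene)
            phi = _promoter_mass_fraction(gene, d.bump_sd)
            if phi > 0:
                area = (r - 1.0) * body * len(win) / phi
                rate += _bump_profile(L, gene.canonical_tss, area, d.bump_sd)
    return rate


def _bump_rate(study: SimulatedStudy, select, amplitude, condition: str) -> np.ndarray:
    """Background plus promoter bumps for the genes chosen by ``select``;
    ``amplitude(row)`` gives the expected bump read mass, reduced by the
    gene's theta in the knockout condition when the gene is bound."""
    d = study.design
    L = study.genome.chrom_sizes[d.chrom_name]
    rate = np.full(L, d.background_rate)
    for gene in study.genes:
        row = study.truth.loc[gene.gene_id]
        if not select(row):
            continue
        area = amplitude(row)
        if condition == "cko" and row["bound"]:
            area *= row["theta"]
        if area > 0:
            rate += _bump_profile(L, gene.canonical_tss, area, d.bump_sd)
    return rate


def _expected_rate(study: SimulatedStudy, assay: str, stage: str,
                   condition: str) -> np.ndarray:
    d = study.design
    bump = d.promoter_bump_reads
    if assay == "proseq":
        return _proseq_rate(study, stage)
    if assay == "atac":
        if stage == "SpG":
            select = lambda r: r["poised"] or r["category"] == "mitosis"
        elif stage == "L/Z":
            select = lambda r: r["poised"]
        else:  # P/D: non-poised meiotic promoters open upon expression
            select = lambda r: r["poised"] or r["category"] in ("meiosis_I", "spermiogenesis")
        return _bump_rate(study, select, lambda r: bump, condition)
    if assay == "cutrun":
        scale = 1.0 if stage == "SpG" else 0.5
        return _bump_rate(
            study, lambda r: r["bound"],
            lambda r: bump * scale * r["occupancy"], condition,
        )
    if assay == "igg":
        L = study.genome.chrom_sizes[d.chrom_name]
        return np.full(L, d.background_rate)
    if assay == "cuttag":
        L = study.genome.chrom_sizes[d.chrom_name]
        rate = np.full(L, d.background_rate)
        for gene in study.genes:
            row = study.truth.loc[gene.gene_id]
            if not row["poised"]:
                continue
            rate[gene.start : gene.end] += 0.2 * d.body_rate
            area = bump
            if condition == "cko" and row["bound"]:
                area *= row["theta"]
            rate += _bump_profile(
                study.genome.chrom_sizes[d.chrom_name],
                gene.canonical_tss, area, d.bump_sd,
            )
        return rate
    raise ValueError(f"unknown assay {assay!r}")


def simulate_tracks(
    study: SimulatedStudy,
    assay: str,
    stage: str = "SpG",
    condition: str = "control",
    replicate: int = 1,
    seed: int | None = None,
) -> tuple[CoverageTrack, LibraryStats]:
    """Draw one replicate coverage track plus its library statistics.

    The random stream is keyed by (assay, stage, condition, replicate), so
    adding a replicate never perturbs the others.
    """
    d = study.design
    seed = study.seed if seed is None else seed
    rng = _substream(seed, f"track:{assay}:{stage}:{condition}:{replicate}")
    rate = _expected_rate(study, assay, stage, condition)
    # depth is anchored on the control condition: a knockout library with
    # less genomic material yields fewer genomic reads, which the spike-in
    # normalization (constant spike material) can then correct for
    ref = rate if condition == "control" else _expected_rate(study, assay, stage, "control")
    rate = rate * (d.depth / ref.sum())
    values = rng.poisson(rate).astype(float)
    spike = int(round(d.spikein_reads * rng.uniform(0.95, 1.05)))
    label = f"{assay}_{stage}_{condition}_rep{replicate}".replace("/", "")
    track = CoverageTrack(values={d.chrom_name: values}, library_label=label)
    stats = LibraryStats(
        mapped_reads=int(values.sum()),
        spikein_reads=spike,
        ploidy_factor=0.5 if (assay == "proseq" and stage == "RS") else 1.0,
        assay=assay,
    )
    return track, stats


# ---------------------------------------------------------------------------
# Single-cell tables
# ---------------------------------------------------------------------------

def simulate_cells(study: SimulatedStudy, seed: int | None = None) -> dict:
    """Two conditions of cells with known deregulated genes and injected
    QC failures.

    Returns a dict with gene x cell count tables (``counts_control``,
    ``counts_cko``), a per-cell QC table (``cell_qc``; truth column
    ``qc_fail_injected``), a fragments table for pseudobulk work
    (``fragments``), per-cell type labels (``cell_types``) and the per-gene
    expression truth (``sc_truth`` with the true fold change cko/control).
    """
    d = study.design
    seed = study.seed if seed is None else seed
    rng = _substream(seed, "cells")
    gene_ids = [g.gene_id for g in study.genes]
    n_genes = len(gene_ids)

    base = rng.lognormal(np.log(d.sc_mean_umis_per_gene), 0.6, size=n_genes)
    true_fc = np.ones(n_genes)
    n_dereg = int(round(d.sc_dereg_fraction * n_genes))
    dereg_idx = rng.choice(n_genes, size=n_dereg, replace=False)
    half = n_dereg // 2
    true_fc[dereg_idx[:half]] = d.sc_dereg_fc
    true_fc[dereg_idx[half:]] = 1.0 / d.sc_dereg_fc

    n_fail = int(round(d.sc_qc_fail_rate * d.n_cells))
    tables, qc_rows = {}, []
    for cond, fc in (("control", np.ones(n_genes)), ("cko", true_fc)):
        counts = np.empty((n_genes, d.n_cells), dtype=np.int64)
        for j in range(d.n_cells):
            fail = j < n_fail
            size_factor = rng.uniform(0.7, 1.4) * (0.08 if fail else 1.0)
            lam = base * fc * size_factor
            counts[:, j] = rng.poisson(lam)
            total = int(counts[:, j].sum())
            mito_rate = 0.08 if (fail and rng.random() < 0.5) else 0.01
            mito = int(rng.binomial(total, mito_rate)) if total else 0
            qc_rows.append({
                "cell_barcode": f"{cond}_c{j:03d}",
                "condition": cond,
                "n_genes_detected": int((counts[:, j] > 0).sum()),
                "total_umis": total,
                "mito_umis": mito,
                "n_fragments": int(rng.poisson(300 if fail else 3000)),
                "tss_score": float(rng.normal(2.0 if fail else 11.3, 0.5)),
                "qc_fail_injected": fail,
            })
        tables[cond] = pd.DataFrame(
            counts, index=gene_ids,
            columns=[f"{cond}_c{j:03d}" for j in range(d.n_cells)],
        )
    cell_qc = pd.DataFrame(qc_rows).set_index("cell_barcode")

    fragments, labels = _simulate_fragments(study, cell_qc, rng)

    sc_truth = pd.DataFrame({"gene_id": gene_ids, "true_fc": true_fc}).set_index("gene_id")
    return {
        "counts_control": tables["control"],
        "counts_cko": tables["cko"],
        "cell_qc": cell_qc,
        "fragments": fragments,
        "cell_types": labels,
        "sc_truth": sc_truth,
    }


def _simulate_fragments(study: SimulatedStudy, cell_qc: pd.DataFrame, rng,
                        frags_per_cell: int = 60):
    """Accessibility fragments: mostly promoter-proximal at open promoters
    (knockout-reduced at bound genes), the rest uniform background."""
    d = study.design
    chrom_len = study.genome.chrom_sizes[d.chrom_name]
    open_rows = study.truth[(study.truth["poised"]) | (study.truth["category"] == "mitosis")]
    open_genes = [g for g in study.genes if g.gene_id in set(open_rows.index)]
    weights = {}
    for cond in ("control", "cko"):
        w = np.array([
            study.truth.at[g.gene_id, "theta"]
            if (cond == "cko" and study.truth.at[g.gene_id, "bound"]) else 1.0
            for g in open_genes
        ])
        weights[cond] = w / w.sum()
    rows = []
    keep = cell_qc[~cell_qc["qc_fail_injected"]]
    for barcode, row in keep.iterrows():
        cond = row["condition"]
        n_prom = int(0.8 * frags_per_cell)
        choices = rng.choice(len(open_genes), size=n_prom, p=weights[cond])
        for idx in choices:
            tss = open_genes[idx].canonical_tss
            center = int(tss + rng.normal(0, d.bump_sd))
            flen = int(rng.integers(80, 160))
            s = max(0, center - flen // 2)
            rows.append((d.chrom_name, s, min(chrom_len, s + flen), barcode,
                         f"u{rng.integers(0, 1 << 30):08x}"))
        for _ in range(frags_per_cell - n_prom):
            s = int(rng.integers(0, chrom_len - 200))
            flen = int(rng.integers(80, 160))
            rows.append((d.chrom_name, s, s + flen, barcode,
                         f"u{rng.integers(0, 1 << 30):08x}"))
    fragments = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                            "cell_barcode", "umi"])
    labels = pd.Series(
        {b: f"SpG_{cell_qc.at[b, 'condition']}" for b in keep.index},
        name="cell_type",
    )
    return fragments, labels
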