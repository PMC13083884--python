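"""Single-cell processing rules: QC filters, UMI deduplication, the Tn5
insertion shift, a TSS enrichment score, pseudobulk promoter accessibility,
and threshold-based differential expression classification.

Clustering, embedding and cell-type annotation are out of scope; cells enter
with their (possibly unknown) type labels already assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .annotation import GeneModel, tss_flank
from .occupancy import PromoterSignal, bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "qc_filter_rna",
    "qc_filter_atac",
    "tn5_shift",
    "dedup_umi",
    "tss_enrichment_score",
    "pseudobulk_accessibility",
    "differential_classes",
    "DifferentialResult",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "cell_barcode", "umi"]


def qc_filter_rna(cells: pd.DataFrame, min_genes: int = 500,
                  max_mito_frac: float = 0.05) -> pd.DataFrame:
    """Keep cells with >= ``min_genes`` expressed genes and a mitochondrial
    UMI fraction strictly below ``max_mito_frac``; zero-UMI cells dropped."""
    total = cells["total_umis"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(total > 0, cells["mito_umis"] / total, 1.0)
    keep = (cells["n_genes_detected"] >= min_genes) & (mito_frac < max_mito_frac)
    return cells[keep]


def qc_filter_atac(cells: pd.DataFrame, min_fragments: int = 1000,
                   min_tss_score: float = 4.0) -> pd.DataFrame:
    """Keep cells with >= ``min_fragments`` fragments and TSS score >= 4."""
    keep = (cells["n_fragments"] >= min_fragments) & (cells["tss_score"] >= min_tss_score)
    return cells[keep]


def tn5_shift(fragments: pd.DataFrame) -> pd.DataFrame:
    """Apply the +4/-5 Tn5 insertion-site shift to fragment coordinates.

    Fragments that collapse (start >= end after shifting) are dropped with a
    logged count.  Re-shifting an already shifted table is refused.
    """
    if fragments.attrs.get("tn5_shifted"):
        raise ValueError("fragments already Tn5-shifted; refusing to shift twice")
    out = fragments.copy()
    out["start"] = out["start"] + 4
    out["end"] = out["end"] - 5
    valid = out["start"] < out["end"]
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("tn5_shift: dropped %d degenerate fragments", n_dropped)
    out = out[valid].reset_index(drop=True)
    out.attrs["tn5_shifted"] = True
    return out


def dedup_umi(records: pd.DataFrame,
              keys: tuple = ("cell_barcode", "umi", "chrom", "start", "end")) -> pd.DataFrame:
    """Remove PCR duplicates: one record per (cell, UMI, coordinates) key,
    first occurrence kept."""
    keys = [k for k in keys if k in records.columns]
    return records.drop_duplicates(subset=keys, keep="first").reset_index(drop=True)


def _insertion_sites(fragments: pd.DataFrame) -> np.ndarray:
    """Tn5 cuts at both fragment ends; each end is one insertion event."""
    return np.concatenate([
        fragments["start"].to_numpy(),
        fragments["end"].to_numpy() - 1,
    ])


def tss_enrichment_score(
    fragments: pd.DataFrame,
    tss_list,
    center_half: int = 50,
    flank_center: int = 1950,
    flank_half: int = 50,
) -> float:
    """Per-cell TSS enrichment: insertion density near TSSs over background.

    Counts fragment-end insertions within +/- ``center_half`` bp of each TSS
    and within the two 100-bp background windows centered at +/- 1950 bp,
    aggregated over all TSSs.  Score = center per-bp rate divided by the
    flank per-bp rate, with +1 added to the flank count so sparse cells get
    a finite score.  Uniform random insertions score ~1; a cell with all
    insertions at TSSs scores far above the QC threshold of 4.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    items = tss_list.items() if hasattr(tss_list, "items") else None
    if items is not None:
        tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in items}
    else:
        tmp: dict[str, list[int]] = {}
        for chrom, pos in tss_list:
            tmp.setdefault(chrom, []).append(pos)
        tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tmp.items()}
    if not tss_by_chrom:
        raise ValueError("at least one TSS required")
    if len(fragments) == 0:
        return 0.0

    center_count = 0
    flank_count = 0
    center_bp = flank_bp = 0
    for chrom, group in fragments.groupby("chrom"):
        tss = tss_by_chrom.get(chrom)
        if tss is None or len(tss) == 0:
            continue
        ins = np.sort(_insertion_sites(group))
        for t in tss:
            center_count += int(
                np.searchsorted(ins, t + center_half, "right")
                - np.searchsorted(ins, t - center_half, "left")
            )
            for sign in (-1, 1):
                c = t + sign * flank_center
                flank_count += int(
                    np.searchsorted(ins, c + flank_half, "right")
                    - np.searchsorted(ins, c - flank_half, "left")
                )
    n_tss = sum(len(v) for v in tss_by_chrom.values())
    center_bp = n_tss * (2 * center_half + 1)
    flank_bp = n_tss * 2 * (2 * flank_half + 1)
    center_rate = center_count / center_bp
    flank_rate = (flank_count + 1) / flank_bp
    return float(center_rate / flank_rate)


def pseudobulk_accessibility(
    fragments: pd.DataFrame,
    cell_types: pd.Series,
    gene: GeneModel,
    chrom_sizes: dict[str, int],
    half_width: int = 200,
) -> dict[str, PromoterSignal | None]:
    """Per-cell-type mean fragments-per-million coverage at +/- 200 bp of the TSS.

    Fragments are merged per cell-type label, coverage is normalized per
    million fragments, and the promoter value is the mean over the window of
    the best-supported TSS.  Labels with no cells map to None.
    """
    labels = pd.Series(cell_types)
    out: dict[str, PromoterSignal | None] = {}
    chrom_len = chrom_sizes[gene.chrom]
    for label in labels.unique():
        cells = set(labels.index[labels == label])
        sub = fragments[fragments["cell_barcode"].isin(cells)]
        n_frag = len(sub)
        if n_frag == 0:
            out[label] = None
            continue
        on_chrom = sub[sub["chrom"] == gene.chrom]
        best = 0.0
        for tss in gene.tss_list:
            win = tss_flank(tss, half_width, chrom_len=chrom_len, chrom=gene.chrom)
            if len(win) == 0:
                continue
            lo = np.maximum(on_chrom["start"].to_numpy(), win.start)
            hi = np.minimum(on_chrom["end"].to_numpy(), win.end)
            covered = np.clip(hi - lo, 0, None).sum()
            best = max(best, float(covered) / len(win))
        value = best * 1e6 / n_frag
        out[label] = PromoterSignal(gene.gene_id, value, half_width, condition=str(label))
    return out


@dataclass
class DifferentialResult:
    gene_id: str
    fold_change: float
    p_value: float
    q_value: float
    klass: str  # up / down / unchanged


def _depth_normalize(counts: pd.DataFrame, mode: str, ref_size: float) -> pd.DataFrame:
    libsize = counts.sum(axis=0).astype(float)
    libsize = libsize.replace(0, np.nan)
    if mode == "median":
        scaled = counts.div(libsize, axis=1) * ref_size
    elif mode == "log10k":
        scaled = np.log1p(counts.div(libsize, axis=1) * 1e4)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return scaled.fillna(0.0)


def differential_classes(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    eps: float = 0.01,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    fdr: float = 0.05,
    normalization: str = "median",
) -> list[DifferentialResult]:
    """Threshold-based differential classes between two cell groups.

    ``counts_a``/``counts_b`` are gene x cell count tables for the two
    conditions (same gene index).  Counts are depth-normalized per cell
    (counts x median library size / cell library size by default;
    ``"log10k"`` gives the log-normalize-to-10k alternative), the per-gene
    fold change is (mean_a + eps)/(mean_b + eps), p-values come from a
    two-sided rank-sum test across cells, q-values from BH.  Classes:
    up iff fc >= 2 and q <= 0.05; down iff fc <= 0.5 and q <= 0.05.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 cells per group")
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("gene indices of the two groups differ")
    ref = float(pd.concat([counts_a.sum(axis=0), counts_b.sum(axis=0)]).median())
    norm_a = _depth_normalize(counts_a, normalization, ref)
    norm_b = _depth_normalize(counts_b, normalization, ref)
    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    fc = (mean_a + eps) / (mean_b + eps)

    pvals = np.ones(len(fc))
    a_mat, b_mat = norm_a.to_numpy(), norm_b.to_numpy()
    for i in range(len(fc)):
        xa, xb = a_mat[i], b_mat[i]
        if np.ptp(np.concatenate([xa, xb])) == 0:
            continue
        pvals[i] = mannwhitneyu(xa, xb, alternative="two-sided").pvalue
    qvals = bh_fdr(pvals)

    results = []
    for gene, f, p, q in zip(counts_a.index, fc, pvals, qvals):
        if f >= fc_up and q <= fdr:
            klass = "up"
        elif f <= fc_down and q <= fdr:
            klass = "down"
        else:
            klass = "unchanged"
        results.append(DifferentialResult(str(gene), float(f), float(p), float(q), klass))
    return results
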