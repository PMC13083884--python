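"""Promoter-signal quantification, knockout-vs-control fold changes, quartile
stratification by occupancy, and the nonparametric statistics used throughout
(paired Wilcoxon signed-rank, Spearman/Pearson correlation, Benjamini-Hochberg
FDR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel, tss_flank
from .coverage import RAW, CoverageTrack

__all__ = [
    "PromoterSignal",
    "GroupComparison",
    "promoter_signal",
    "fold_change",
    "quartile_stratify",
    "paired_wilcoxon",
    "rank_correlation",
    "bh_fdr",
]


@dataclass
class PromoterSignal:
    """Mean normalized coverage in a fixed window around the TSS."""

    gene_id: str
    value: float
    half_width: int
    condition: str = ""
    replicate_id: str = ""


def promoter_signal(
    track: CoverageTrack,
    gene: GeneModel,
    half_width: int = 200,
    multi_tss: str = "max",
    condition: str = "",
    replicate_id: str = "",
) -> PromoterSignal:
    """Average normalized coverage at +/- ``half_width`` bp from the TSS.

    Requires a normalized (rpm or spike-scaled) track.  For multi-TSS genes
    the representative promoter is the TSS with maximal signal
    (``multi_tss="max"``); ``"mean"`` averages over all TSSs instead.
    Windows are clipped at chromosome edges and averaged over existing bases.
    """
    if track.normalization == RAW:
        raise ValueError("promoter_signal requires a normalized track")
    chrom_len = track.chrom_sizes.get(gene.chrom)
    if chrom_len is None:
        raise ValueError(f"track lacks chromosome {gene.chrom}")
    means = []
    for tss in gene.tss_list:
        win = tss_flank(tss, half_width, chrom_len=chrom_len, chrom=gene.chrom)
        if len(win) == 0:
            continue
        means.append(track.region_sum(win) / len(win))
    if not means:
        raise ValueError(f"{gene.gene_id}: no TSS window on chromosome")
    if multi_tss == "max":
        value = max(means)
    elif multi_tss == "mean":
        value = float(np.mean(means))
    else:
        raise ValueError(f"unknown multi_tss rule {multi_tss!r}")
    return PromoterSignal(gene.gene_id, value, half_width, condition, replicate_id)


@dataclass
class GroupComparison:
    """Per-gene knockout / control ratios with a paired-test summary."""

    ratios: pd.Series  # gene_id -> (A + eps) / (B + eps)
    summary: float  # median (or mean) ratio
    p_value: float
    q_value: float | None = None


def fold_change(
    group_a: pd.Series,
    group_b: pd.Series,
    eps: float = 0.01,
    summary: str = "median",
) -> GroupComparison:
    """Matched per-gene ratio (A + eps)/(B + eps) with a paired Wilcoxon p.

    ``group_a`` and ``group_b`` map the same gene_ids to promoter signals
    (e.g. knockout and control); unmatched ids are an error.
    """
    a = pd.Series(group_a, dtype=float)
    b = pd.Series(group_b, dtype=float)
    if set(a.index) != set(b.index):
        raise ValueError("gene sets of the two groups do not match")
    b = b.reindex(a.index)
    ratios = (a + eps) / (b + eps)
    if summary == "median":
        s = float(ratios.median())
    elif summary == "mean":
        s = float(ratios.mean())
    else:
        raise ValueError(f"unknown summary {summary!r}")
    p = paired_wilcoxon(a.to_numpy(), b.to_numpy())
    return GroupComparison(ratios=ratios, summary=s, p_value=p)


def quartile_stratify(values: pd.Series) -> pd.Series:
    """Rank genes by occupancy into Q1 (lowest), Q2Q3, Q4 (highest).

    For n genes: |Q1| = ceil(n/4), |Q4| = floor(n/4), the rest Q2Q3.
    Ties are broken by gene_id lexicographic order.
    """
    values = pd.Series(values, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 genes to stratify into quartiles")
    order = sorted(values.index, key=lambda g: (values[g], str(g)))
    n_q1 = -(-n // 4)  # ceil
    n_q4 = n // 4
    strata = pd.Series("Q2Q3", index=values.index, name="stratum", dtype=object)
    strata[order[:n_q1]] = "Q1"
    strata[order[n - n_q4 :]] = "Q4"
    return strata


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic with (possibly tied)
    ranks, by dynamic programming over all 2^n equally likely sign vectors.

    Average ranks are half-integers at worst, so doubling makes them integers
    and the distribution of 2*W+ is a convolution of {0, 2r_i} point masses.
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    # counts[s] = number of sign assignments with doubled statistic s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    lo, hi = min(w2, total - w2), max(w2, total - w2)
    p = counts[: lo + 1].sum() + counts[hi:].sum()
    return float(min(1.0, p))


def paired_wilcoxon(x, y, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon matched-pairs signed-rank test p-value.

    Zero differences are dropped (standard signed-rank convention).  After
    dropping, n <= ``exact_max_n`` uses the exact permutation distribution
    (valid with tied ranks); larger n uses the normal approximation with tie
    correction.  All differences zero -> p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return _exact_signed_rank_p(ranks, w_plus)
    res = sps.wilcoxon(x, y, zero_method="wilcox", correction=False,
                       alternative="two-sided", method="approx")
    return float(res.pvalue)


def rank_correlation(x, y, method: str = "spearman") -> float | None:
    """Spearman's rho (average ranks for ties) or Pearson's r; None when
    either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
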