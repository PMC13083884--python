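"""Spike-in absolute transcript quantification and fold-change gene
categorization across germ-cell stages.

Genes are classified from molecules-per-cell abundances over four
FACS-purified stages: spermatogonia (SpG), pachytene/diplotene spermatocytes
(P/D), secondary spermatocytes (SpII) and round spermatids (RS).

* mitosis: SpG >= fold x each of P/D, SpII, RS
* meiosis_I: P/D >= fold x each of SpG, SpII, RS
* spermiogenesis: P/D >= fold x SpG and P/D within `flat`-fold of SpII and RS
* control: max pairwise stage ratio <= max_fc (constant expression)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STAGES = ("SpG", "P/D", "SpII", "RS")
ERCC_TOTAL_MOLECULES = 623_291_645  # molecules of ERCC spike-in mix per sample

CATEGORIES = ("mitosis", "meiosis_I", "spermiogenesis", "control", "unclassified")

__all__ = [
    "STAGES",
    "ERCC_TOTAL_MOLECULES",
    "CATEGORIES",
    "absolute_abundance",
    "categorize_genes",
    "control_gene_set",
    "validate_abundance_table",
]


def absolute_abundance(gene_reads, ercc_reads, n_cells,
                       total_spike_molecules: float = ERCC_TOTAL_MOLECULES):
    """Molecules of transcript per cell.

    abundance = gene_reads * total_spike_molecules / (n_cells * ercc_reads).
    Vectorized over ``gene_reads``.
    """
    if np.any(np.asarray(ercc_reads) <= 0):
        raise ValueError("ercc_reads must be > 0")
    if np.any(np.asarray(n_cells) <= 0):
        raise ValueError("n_cells must be > 0")
    reads = np.asarray(gene_reads, dtype=float)
    if np.any(reads < 0):
        raise ValueError("gene_reads must be >= 0")
    out = reads * total_spike_molecules / (np.asarray(n_cells, dtype=float)
                                           * np.asarray(ercc_reads, dtype=float))
    return float(out) if np.isscalar(gene_reads) else out


def validate_abundance_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [s for s in STAGES if s not in table.columns]
    if missing:
        raise ValueError(f"abundance table missing stages: {missing}")
    sub = table[list(STAGES)].astype(float)
    if (sub < 0).any().any():
        raise ValueError("abundances must be >= 0")
    return sub


def categorize_genes(table: pd.DataFrame, fold: float = 4.0, flat: float = 2.0,
                     eps: float = 0.01) -> pd.Series:
    """Assign one category per gene from its four-stage abundance profile.

    ``table`` has gene_ids as index and the four stages as columns.  The
    pseudocount ``eps`` keeps zero-abundance ratios defined.  Returns a
    Series gene_id -> category; genes matching no rule are 'unclassified'
    (the control set is a separate, overlapping definition).
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if not fold > flat >= 1:
        raise ValueError("require fold > flat >= 1")
    sub = validate_abundance_table(table) + eps
    spg, pd_, spii, rs = (sub[s].to_numpy() for s in STAGES)

    def ge(a, b):
        # ">= fourfold" includes the boundary; guard against the pseudocount
        # and float rounding nudging an exact fold just below the threshold
        return a >= b * (1 - 1e-9)

    mitosis = ge(spg, fold * pd_) & ge(spg, fold * spii) & ge(spg, fold * rs)
    meiosis = ge(pd_, fold * spg) & ge(pd_, fold * spii) & ge(pd_, fold * rs)

    def flat_ratio(a, b):
        return np.maximum(a, b) / np.minimum(a, b)

    spermio = (
        ge(pd_, fold * spg)
        & (flat_ratio(pd_, spii) <= flat * (1 + 1e-9))
        & (flat_ratio(pd_, rs) <= flat * (1 + 1e-9))
    )

    cats = np.full(len(sub), "unclassified", dtype=object)
    cats[spermio] = "spermiogenesis"
    cats[meiosis] = "meiosis_I"  # provably disjoint from spermiogenesis when fold > flat
    cats[mitosis] = "mitosis"
    return pd.Series(cats, index=sub.index, name="category")


def control_gene_set(table: pd.DataFrame, max_fc: float = 2.0,
                     eps: float = 0.01) -> list[str]:
    """Genes whose abundance stays within ``max_fc``-fold across all stages."""
    if max_fc < 1:
        raise ValueError("max_fc must be >= 1")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    sub = validate_abundance_table(table) + eps
    ratio = sub.max(axis=1) / sub.min(axis=1)
    return list(sub.index[ratio <= max_fc])
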