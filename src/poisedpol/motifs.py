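"""IUPAC motif scanning and Fisher-exact enrichment of a known motif in peak
regions versus background promoters.

Only known-motif enrichment is implemented (the NFY CCAAT-box motif
RRCCAATSRS and any user-supplied IUPAC string); de-novo motif discovery is
out of scope.  A region "has the motif" if it contains at least one hit on
either strand; enrichment is a one-sided (greater) Fisher exact test of
peak regions against background regions, with Haldane 0.5 correction of the
odds ratio when a cell is zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import fisher_exact

from .annotation import GenomeSequence, Interval
from .occupancy import bh_fdr

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",  # motif N matches anything; sequence N matches only motif N
}

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

NFYA_MOTIF = "RRCCAATSRS"

__all__ = ["MotifModel", "MotifHit", "EnrichmentResult", "NFYA_MOTIF",
           "iupac_scan", "enrich", "reverse_complement"]


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    iupac: str
    name: str = ""

    def __post_init__(self):
        motif = self.iupac.upper()
        if len(motif) < 4:
            raise ValueError("motif must be at least 4 characters")
        bad = set(motif) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters: {sorted(bad)}")
        object.__setattr__(self, "iupac", motif)

    def _regex(self, motif: str) -> re.Pattern:
        # lookahead so overlapping hits are all reported
        return re.compile("(?=(" + "".join(f"[{IUPAC[c]}]" for c in motif) + "))")


@dataclass(frozen=True)
class MotifHit:
    start: int  # 0-based plus-strand coordinate of the match
    strand: str
    matched: str
    chrom: str = ""


def iupac_scan(seq: str, motif: MotifModel | str, both_strands: bool = True,
               chrom: str = "", offset: int = 0) -> list[MotifHit]:
    """All (possibly overlapping) motif matches in ``seq``.

    Minus-strand hits are matches of the motif's reverse complement, reported
    at their plus-strand coordinates.  ``offset`` shifts reported coordinates
    (for scanning an excised region of a chromosome).
    """
    if isinstance(motif, str):
        motif = MotifModel(motif)
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    hits = [
        MotifHit(offset + m.start(), "+", m.group(1), chrom)
        for m in motif._regex(motif.iupac).finditer(seq)
    ]
    if both_strands:
        rc = reverse_complement(motif.iupac)
        hits += [
            MotifHit(offset + m.start(), "-", m.group(1), chrom)
            for m in motif._regex(rc).finditer(seq)
        ]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass
class EnrichmentResult:
    motif: str
    peaks_with_motif: int
    peaks_total: int
    background_with_motif: int
    background_total: int
    odds_ratio: float
    p_value: float
    q_value: float | None = None


def _region_center(region) -> tuple[str, int]:
    if hasattr(region, "summit"):  # Peak
        return region.interval.chrom, region.summit
    return region.chrom, (region.start + region.end) // 2


def _has_motif(genome: GenomeSequence, region, motif: MotifModel, flank: int) -> bool:
    chrom, center = _region_center(region)
    size = genome.chrom_sizes[chrom]
    lo, hi = max(0, center - flank), min(size, center + flank + 1)
    seq = genome.fetch(Interval(chrom, lo, hi))
    return bool(iupac_scan(seq, motif))


def enrich(
    peaks: Sequence,
    background_regions: Sequence,
    genome: GenomeSequence,
    motif: MotifModel | str,
    flank: int = 75,
) -> EnrichmentResult:
    """Fisher-exact enrichment of the motif under peaks versus background.

    Each region is reduced to +/- ``flank`` bp around its center (the summit
    for peaks); regions crossing a chromosome edge are clipped.  The q-value
    equals p for a single motif; use :func:`enrich_multiple` to BH-correct a
    panel of motifs.
    """
    if isinstance(motif, str):
        motif = MotifModel(motif)
    k_peak = sum(_has_motif(genome, r, motif, flank) for r in peaks)
    k_bg = sum(_has_motif(genome, r, motif, flank) for r in background_regions)
    n_peak, n_bg = len(peaks), len(background_regions)
    table = [[k_peak, n_peak - k_peak], [k_bg, n_bg - k_bg]]
    _, p = fisher_exact(table, alternative="greater")
    a, b, c, d = k_peak, n_peak - k_peak, k_bg, n_bg - k_bg
    if min(a, b, c, d) == 0:  # Haldane correction
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oddsr = (a * d) / (b * c)
    return EnrichmentResult(motif.iupac, k_peak, n_peak, k_bg, n_bg,
                            float(oddsr), float(p), q_value=float(p))


def enrich_multiple(
    peaks: Sequence,
    background_regions: Sequence,
    genome: GenomeSequence,
    motifs: Sequence[MotifModel | str],
    flank: int = 75,
) -> list[EnrichmentResult]:
    """Enrichment for a panel of motifs with BH-corrected q-values."""
    results = [enrich(peaks, background_regions, genome, m, flank) for m in motifs]
    qvals = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    return results
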