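"""Enhancer derivation by histone-mark peak exclusion and genomic
localization of binding-peak summits.

Distal enhancers are derived by exclusion: H3K4me1 (or H3K27Ac) peaks that
overlap a promoter-associated H3K4me3 peak by >= 1 bp are removed whole, and
the remainder are treated as enhancer intervals.  Peak summits are then
classified as promoter-proximal (within +/- half_width of any TSS; takes
precedence), enhancer (inside an enhancer interval), or other.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

from .annotation import Interval

__all__ = ["LocalizationSummary", "subtract_overlapping", "localize_peaks"]


@dataclass
class LocalizationSummary:
    n_peaks: int
    fraction_promoter: float
    fraction_enhancer: float
    fraction_other: float


def subtract_overlapping(marks_a: Sequence[Interval],
                         marks_b: Sequence[Interval]) -> list[Interval]:
    """Intervals of ``marks_a`` having zero-bp overlap with every ``marks_b``.

    Whole-interval removal (no trimming); half-open adjacency is not overlap.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in marks_b:
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    starts_ends: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        starts_ends[chrom] = ([p[0] for p in pairs], sorted(p[1] for p in pairs))
    kept = []
    for a in marks_a:
        entry = starts_ends.get(a.chrom)
        if entry is None:
            kept.append(a)
            continue
        starts, ends = entry
        # overlap exists iff some b has start < a.end and end > a.start
        n_start_before = bisect_left(starts, a.end)
        n_end_notafter = bisect_right(ends, a.start)
        if n_start_before - n_end_notafter <= 0:
            kept.append(a)
    return kept


def localize_peaks(
    peaks: Sequence,
    tss_list: Sequence[tuple[str, int]],
    enhancers: Sequence[Interval],
    half_width: int = 2000,
) -> LocalizationSummary:
    """Classify each peak summit as promoter / enhancer / other.

    ``tss_list`` is (chrom, position) pairs.  Promoter takes precedence when
    a summit is both near a TSS and inside an enhancer, so the three
    fractions partition the peaks exactly.
    """
    tss_by_chrom: dict[str, list[int]] = {}
    for chrom, pos in tss_list:
        tss_by_chrom.setdefault(chrom, []).append(pos)
    for positions in tss_by_chrom.values():
        positions.sort()
    enh_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for e in enhancers:
        enh_by_chrom.setdefault(e.chrom, []).append((e.start, e.end))
    for pairs in enh_by_chrom.values():
        pairs.sort()

    n_prom = n_enh = 0
    peaks = list(peaks)
    for peak in peaks:
        chrom = peak.interval.chrom if hasattr(peak, "interval") else peak.chrom
        summit = peak.summit if hasattr(peak, "summit") else (peak.start + peak.end) // 2
        positions = tss_by_chrom.get(chrom, [])
        idx = bisect_left(positions, summit)
        near = any(
            abs(positions[i] - summit) <= half_width
            for i in (idx - 1, idx)
            if 0 <= i < len(positions)
        )
        if near:
            n_prom += 1
            continue
        inside = any(s <= summit < e for s, e in enh_by_chrom.get(chrom, []))
        if inside:
            n_enh += 1
    n = len(peaks)
    if n == 0:
        return LocalizationSummary(0, 0.0, 0.0, 0.0)
    return LocalizationSummary(
        n_peaks=n,
        fraction_promoter=n_prom / n,
        fraction_enhancer=n_enh / n,
        fraction_other=(n - n_prom - n_enh) / n,
    )
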