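"""Promoter/gene-body signal densities, the Pol II pausing index, the Ser5P
pause ratio, and metagene profiles.

The pausing index is the ratio of signal density (signal per bp) over the
promoter-proximal window (TSS to the first 5% of the gene) to the density
over the gene body (30% of gene length to the TES).  Density, not raw sums,
is the default because the two windows differ in length; ``mode="reads"``
ratios the raw sums instead.  The index is a normalization-free statistic:
any multiplicative rescaling of the track cancels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotation import GeneModel, Interval, body_window, promoter_window
from .coverage import CoverageTrack

logger = logging.getLogger(__name__)

__all__ = [
    "PausingRecord",
    "MetageneMatrix",
    "window_density",
    "pausing_index",
    "ser5p_pause_ratio",
    "replicate_average",
    "metagene",
]


@dataclass
class PausingRecord:
    gene_id: str
    promoter_density: float
    body_density: float
    pausing_index: float | None
    replicate_id: str = ""


def window_density(track: CoverageTrack, interval: Interval) -> float:
    """Mean signal per bp over the interval."""
    if len(interval) < 1:
        raise ValueError("zero-length interval has no density")
    return track.region_sum(interval) / len(interval)


def pausing_index(
    track: CoverageTrack,
    gene: GeneModel,
    promoter_fraction: float = 0.05,
    body_fraction: float = 0.30,
    mode: str = "density",
) -> float | None:
    """Promoter density / body density; None (missing) when the body is silent.

    ``mode="reads"`` divides raw window sums instead of per-bp densities.
    """
    if gene.length < 4:
        raise ValueError(f"{gene.gene_id}: gene too short for pausing index")
    prom = promoter_window(gene, promoter_fraction)
    body = body_window(gene, body_fraction)
    if mode == "density":
        num, den = window_density(track, prom), window_density(track, body)
    elif mode == "reads":
        num, den = track.region_sum(prom), track.region_sum(body)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if den == 0:
        return None
    return num / den


def _pause_window(gene: GeneModel, start_nt: int, end_nt: int) -> Interval | None:
    """Strand-aware [TSS+start_nt, TSS+end_nt] window (1-based inclusive
    offsets in the direction of transcription); None if it leaves the gene."""
    tss = gene.canonical_tss
    if gene.strand == "+":
        lo, hi = tss + start_nt, tss + end_nt + 1
        if hi > gene.end:
            return None
    else:
        lo, hi = tss - end_nt, tss - start_nt + 1
        if lo < gene.start:
            return None
    return Interval(gene.chrom, lo, hi)


def ser5p_pause_ratio(
    track: CoverageTrack,
    gene: GeneModel,
    pause_start: int = 31,
    pause_end: int = 60,
    body_fraction: float = 0.30,
) -> float | None:
    """Pol II Ser5P density over [TSS+31, TSS+60] nt relative to body density.

    Returns None when the pause window falls outside the gene or the body
    carries no signal.
    """
    win = _pause_window(gene, pause_start, pause_end)
    if win is None:
        return None
    den = window_density(track, body_window(gene, body_fraction))
    if den == 0:
        return None
    return window_density(track, win) / den


def replicate_average(values: Sequence[float | None]) -> float | None:
    """Arithmetic mean over replicates where defined; None if all missing."""
    if not values:
        raise ValueError("at least one replicate required")
    defined = [v for v in values if v is not None]
    if not defined:
        return None
    return float(np.mean(defined))


@dataclass
class MetageneMatrix:
    """Per-gene binned profiles, transcription oriented left-to-right.

    Columns: ``n_flank_bins`` fixed-width upstream bins, ``body_bins``
    length-normalized gene-body bins, ``n_flank_bins`` downstream bins.
    Bases beyond the chromosome are NaN and excluded from the profile mean.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    flank: int
    flank_bin: int
    body_bins: int

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.flank_bin

    def profile(self) -> np.ndarray:
        return np.nanmean(self.matrix, axis=0)


def _binned(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of ``values`` over ``n_bins`` near-equal contiguous chunks;
    bins that are empty or entirely off-chromosome are NaN."""
    edges = np.linspace(0, len(values), n_bins + 1).round().astype(int)
    out = np.full(n_bins, np.nan)
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        chunk = values[a:b]
        if b > a and not np.isnan(chunk).all():
            out[i] = np.nanmean(chunk)
    return out


def metagene(
    tracks: CoverageTrack | Sequence[CoverageTrack],
    genes: Sequence[GeneModel],
    flank: int = 5000,
    body_bins: int = 100,
    flank_bin: int = 50,
) -> MetageneMatrix:
    """Resample each gene's signal into flank + body + flank bins.

    Multiple tracks (replicates) are averaged per gene.  Genes shorter than
    two body bins are skipped with a log entry.
    """
    if not genes:
        raise ValueError("gene set is empty")
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    n_flank_bins = flank // flank_bin
    rows, ids = [], []
    skipped = 0
    for gene in genes:
        if gene.length < 2:  # cannot span two body bins
            skipped += 1
            continue
        per_track = []
        for track in tracks:
            arr = track.values.get(gene.chrom)
            if arr is None:
                continue
            lo, hi = gene.start - flank, gene.end + flank
            padded = np.full(hi - lo, np.nan)
            src_lo, src_hi = max(0, lo), min(len(arr), hi)
            padded[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
            if gene.strand == "-":
                padded = padded[::-1]
            up = _binned(padded[:flank], n_flank_bins)
            body = _binned(padded[flank : flank + gene.length], body_bins)
            down = _binned(padded[flank + gene.length :], n_flank_bins)
            per_track.append(np.concatenate([up, body, down]))
        if not per_track:
            skipped += 1
            continue
        stacked = np.vstack(per_track)
        row = np.full(stacked.shape[1], np.nan)
        has_data = ~np.isnan(stacked).all(axis=0)
        row[has_data] = np.nanmean(stacked[:, has_data], axis=0)
        rows.append(row)
        ids.append(gene.gene_id)
    if skipped:
        logger.info("metagene: skipped %d genes (too short or off-genome)", skipped)
    if not rows:
        raise ValueError("no usable genes for metagene")
    return MetageneMatrix(np.vstack(rows), ids, flank, flank_bin, body_bins)
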