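"""Coverage tracks, normalization scale factors, peak calling and
replicate-consensus TSS-proximal classification.

The peak caller is a deliberately simplified MACS-like procedure: fixed
sliding windows are tested against a Poisson null whose rate is the maximum
of the genome-wide mean, local means over +/-5 kb and +/-10 kb flanks, and
(when a matched IgG/control track is supplied) the control's local mean.
Window p-values are Benjamini-Hochberg corrected, significant windows merged,
and short merged intervals discarded.  It is not a reimplementation of MACS3;
the downstream consensus classification is the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel, Interval

__all__ = [
    "CoverageTrack",
    "LibraryStats",
    "Peak",
    "ConsensusCall",
    "rpm_normalize",
    "spike_scale_proseq",
    "spike_scale_cuttag",
    "call_peaks",
    "nearest_peak_distance",
    "consensus_call",
    "load_bedgraph",
    "write_bedgraph",
    "write_narrowpeak",
    "write_consensus_tsv",
]

RAW, RPM, SPIKE = "raw", "rpm", "spike_scaled"


@dataclass
class LibraryStats:
    """Per-library sequencing statistics.

    ``spikein_reads`` are reads mapping to the exogenous reference (ERCC mix,
    fly genome or E. coli depending on the assay).  ``ploidy_factor`` is 0.5
    for haploid round-spermatid libraries, 1 otherwise.
    """

    mapped_reads: int
    spikein_reads: int = 0
    n_cells: int = 0
    ploidy_factor: float = 1.0
    assay: str = "atac"

    def __post_init__(self):
        if min(self.mapped_reads, self.spikein_reads, self.n_cells) < 0:
            raise ValueError("library counts must be >= 0")
        if self.ploidy_factor not in (1, 1.0, 0.5):
            raise ValueError(f"ploidy_factor must be 1 or 0.5, got {self.ploidy_factor}")


@dataclass
class CoverageTrack:
    """Nonnegative per-base signal per chromosome with a normalization state."""

    values: dict[str, np.ndarray]
    normalization: str = RAW
    library_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for chrom, arr in self.values.items():
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: coverage must be 1-D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{chrom}: non-finite coverage values")
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: negative coverage values")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def scaled(self, factor: float, normalization: str, **meta) -> "CoverageTrack":
        return CoverageTrack(
            values={c: v * factor for c, v in self.values.items()},
            normalization=normalization,
            library_label=self.library_label,
            metadata={**self.metadata, **meta},
        )

    def region_sum(self, interval: Interval) -> float:
        arr = self.values.get(interval.chrom)
        if arr is None:
            return 0.0
        lo = max(0, interval.start)
        hi = min(len(arr), interval.end)
        if hi <= lo:
            return 0.0
        return float(arr[lo:hi].sum())


@dataclass(frozen=True)
class Peak:
    """Enriched interval with a summit, a -log10 q-value score and a fold enrichment."""

    interval: Interval
    summit: int
    score: float
    fold_enrichment: float

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie within the peak interval")


@dataclass
class ConsensusCall:
    """Replicate-consensus status of one gene (poised / accessible / bound)."""

    gene_id: str
    status: bool
    per_replicate_distance: list[int | None]
    n_supporting: int


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _require_state(track: CoverageTrack, state: str) -> None:
    if track.normalization != state:
        raise ValueError(
            f"track is {track.normalization!r}; this operation requires {state!r} "
            "(double normalization refused)"
        )


def rpm_normalize(track: CoverageTrack, stats: LibraryStats) -> CoverageTrack:
    """Scale to reads per million mapped reads (RPM)."""
    _require_state(track, RAW)
    if stats.mapped_reads <= 0:
        raise ValueError("mapped_reads must be > 0 for RPM normalization")
    return track.scaled(1e6 / stats.mapped_reads, RPM)


def spike_scale_proseq(track: CoverageTrack, stats: LibraryStats,
                       mode: str = "as-stated") -> CoverageTrack:
    """Spike-in scale a nascent-transcription track.

    ``as-stated`` applies factor ploidy * spikein / mapped (the published
    formula, which scales signal up with more spike-in reads); ``reciprocal``
    applies ploidy * 1e6 / spikein (the conventional direction).  The mode is
    recorded in the track metadata.
    """
    _require_state(track, RAW)
    if stats.spikein_reads <= 0:
        raise ValueError("spikein_reads must be > 0")
    if stats.mapped_reads <= 0:
        raise ValueError("mapped_reads must be > 0")
    if mode == "as-stated":
        factor = stats.ploidy_factor * stats.spikein_reads / stats.mapped_reads
    elif mode == "reciprocal":
        factor = stats.ploidy_factor * 1e6 / stats.spikein_reads
    else:
        raise ValueError(f"unknown spike scaling mode {mode!r}")
    return track.scaled(factor, SPIKE, spike_mode=mode)


def spike_scale_cuttag(track: CoverageTrack, stats: LibraryStats) -> CoverageTrack:
    """Scale by 10000 / (E. coli spike-in reads)."""
    _require_state(track, RAW)
    if stats.spikein_reads <= 0:
        raise ValueError("spikein_reads (E. coli) must be > 0")
    return track.scaled(10_000 / stats.spikein_reads, SPIKE, spike_mode="ecoli10k")


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------

def _window_means(csum: np.ndarray, centers: np.ndarray, half: int) -> np.ndarray:
    """Mean signal over [center-half, center+half) clipped to the chromosome."""
    n = len(csum) - 1
    lo = np.clip(centers - half, 0, n)
    hi = np.clip(centers + half, 0, n)
    width = np.maximum(hi - lo, 1)
    return (csum[hi] - csum[lo]) / width


def _track_quantum(track: CoverageTrack) -> float:
    """Smallest positive value in the track; the unit one read contributes.

    Dividing window sums and the Poisson rate by this quantum makes the caller
    invariant under multiplying a count track by a positive constant.
    """
    q = np.inf
    for arr in track.values.values():
        pos = arr[arr > 0]
        if pos.size:
            q = min(q, float(pos.min()))
    return q if np.isfinite(q) else 1.0


def _refine_bounds(arr: np.ndarray, s: int, e: int, lam: float,
                   margin: int) -> tuple[int, int]:
    """Trim a merged candidate to its enriched core: the maximum-sum run of
    per-base excess (signal - lambda), searched over the candidate plus one
    window margin on each side.  Window union otherwise overstates the width
    of an enrichment by up to a window on each side."""
    lo = max(0, s - margin)
    hi = min(len(arr), e + margin)
    excess = arr[lo:hi] - lam
    csum = np.concatenate([[0.0], np.cumsum(excess)])
    run_min = np.minimum.accumulate(csum[:-1])
    gains = csum[1:] - run_min
    j = int(np.argmax(gains))
    i = int(np.argmin(csum[: j + 1]))
    if gains[j] <= 0:
        return s, s  # nothing above background
    return lo + i, lo + j + 1


def call_peaks(
    track: CoverageTrack,
    background: CoverageTrack | None = None,
    fdr: float = 0.01,
    min_length: int = 150,
    window: int = 200,
    merge_gap: int = 100,
) -> list[Peak]:
    """Call enriched intervals against a Poisson local-background null.

    Sliding windows (half-window step) are tested with rate
    lambda = max(genome mean, local means over +/-5 kb and +/-10 kb,
    background local mean when an IgG/control track is given), BH-corrected
    at ``fdr``, merged across gaps <= ``merge_gap`` and filtered to
    ``min_length``.  Summit is the leftmost maximum of the merged interval.
    """
    if track.normalization not in (RAW, RPM):
        raise ValueError("peak calling expects a raw or rpm track")
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    if background is not None:
        missing = set(track.values) - set(background.values)
        if missing:
            raise ValueError(f"background lacks chromosomes: {sorted(missing)}")

    quantum = _track_quantum(track)
    total = track.total()
    total_len = sum(track.chrom_sizes.values())
    if total == 0 or total_len == 0:
        return []
    genome_mean = total / total_len

    bg_scale = 1.0
    if background is not None and background.total() > 0:
        # match the control's depth to the treatment before comparing rates
        bg_scale = total / background.total()

    step = max(1, window // 2)
    records = []  # (chrom, win_start, pvalue, lam_per_bp)
    for chrom, arr in track.values.items():
        n = len(arr)
        if n == 0:
            continue
        csum = np.concatenate([[0.0], np.cumsum(arr)])
        starts = np.arange(0, max(1, n - window + 1), step)
        ends = np.minimum(starts + window, n)
        sums = csum[ends] - csum[starts]
        centers = (starts + ends) // 2
        lam_bp = np.maximum(
            genome_mean,
            np.maximum(
                _window_means(csum, centers, 5000),
                _window_means(csum, centers, 10_000),
            ),
        )
        if background is not None:
            barr = background.values[chrom]
            bcsum = np.concatenate([[0.0], np.cumsum(barr)])
            bcenters = np.clip(centers, 0, max(0, len(barr)))
            # control raises lambda at the test-window scale too, so
            # enrichment shared with the IgG/control is suppressed
            blam = np.maximum(
                _window_means(bcsum, bcenters, window // 2),
                np.maximum(
                    _window_means(bcsum, bcenters, 5000),
                    _window_means(bcsum, bcenters, 10_000),
                ),
            ) * bg_scale
            lam_bp = np.maximum(lam_bp, blam)
        widths = ends - starts
        k = np.round(sums / quantum).astype(np.int64)
        lam = lam_bp * widths / quantum
        pvals = stats.poisson.sf(k - 1, lam)
        for s, e, p, lb in zip(starts, ends, pvals, lam_bp):
            records.append((chrom, int(s), int(e), float(p), float(lb)))

    if not records:
        return []
    pvals = np.array([r[3] for r in records])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    sig = qvals <= fdr
    if not sig.any():
        return []

    peaks: list[Peak] = []
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for keep, rec, q in zip(sig, records, qvals):
        if keep:
            by_chrom.setdefault(rec[0], []).append((rec[1], rec[2], float(q)))
    for chrom, wins in by_chrom.items():
        wins.sort()
        arr = track.values[chrom]
        merged: list[list] = []
        for s, e, q in wins:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] = min(merged[-1][2], q)
            else:
                merged.append([s, e, q])
        csum = np.concatenate([[0.0], np.cumsum(arr)])
        for s, e, q in merged:
            center = (s + e) // 2
            lam_trim = max(
                genome_mean,
                _window_means(csum, np.array([center]), 5000)[0],
                _window_means(csum, np.array([center]), 10_000)[0],
            )
            s, e = _refine_bounds(arr, s, e, lam_trim, margin=window)
            if e - s < max(min_length, 1):
                continue
            summit = s + int(np.argmax(arr[s:e]))  # leftmost maximum
            lam_local = max(
                genome_mean,
                _window_means(csum, np.array([summit]), 5000)[0],
                _window_means(csum, np.array([summit]), 10_000)[0],
            )
            fold = float(arr[summit] / lam_local) if lam_local > 0 else np.inf
            score = float(-np.log10(max(q, 1e-300)))
            peaks.append(Peak(Interval(chrom, s, e), summit, score, fold))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


# ---------------------------------------------------------------------------
# TSS-proximal classification
# ---------------------------------------------------------------------------

def nearest_peak_distance(gene: GeneModel, peaks: Sequence[Peak]) -> int | None:
    """Min over TSSs and same-chromosome peak summits of |summit - tss|.

    Returns None when the gene's chromosome carries no peak.
    """
    summits = [p.summit for p in peaks if p.interval.chrom == gene.chrom]
    if not summits:
        return None
    return min(abs(s - t) for s in summits for t in gene.tss_list)


def consensus_call(
    gene: GeneModel,
    per_replicate_peaks: Sequence[Sequence[Peak]],
    half_width: int = 2000,
    min_reps: int = 2,
) -> ConsensusCall:
    """Gene is positive iff >= ``min_reps`` replicates have a peak summit
    within ``half_width`` of at least one of its TSSs."""
    if not per_replicate_peaks:
        raise ValueError("at least one replicate required")
    distances = [nearest_peak_distance(gene, peaks) for peaks in per_replicate_peaks]
    n_supporting = sum(1 for d in distances if d is not None and d <= half_width)
    return ConsensusCall(
        gene_id=gene.gene_id,
        status=n_supporting >= min_reps,
        per_replicate_distance=distances,
        n_supporting=n_supporting,
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def load_bedgraph(path, chrom_sizes: dict[str, int],
                  library_label: str = "") -> CoverageTrack:
    values = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if chrom not in values:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not 0 <= s < e <= len(values[chrom]):
                raise ValueError(f"{path}:{lineno}: interval outside chromosome")
            values[chrom][s:e] = v
    return CoverageTrack(values=values, library_label=library_label)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length-encoded bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_narrowpeak(peaks: Iterable[Peak], path, name_prefix: str = "peak") -> None:
    """BED6+4 narrowPeak-style writer; summit stored as a relative offset."""
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))
    with open(path, "w") as fh:
        for i, p in enumerate(rows, start=1):
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        f"{name_prefix}_{i}",
                        str(int(min(1000, 10 * p.score))),
                        ".",
                        f"{p.fold_enrichment:.4g}",
                        "-1",
                        f"{p.score:.4g}",
                        str(p.summit - p.interval.start),
                    ]
                )
                + "\n"
            )


def summarize_consensus(calls: Sequence[ConsensusCall]) -> dict:
    """Count and percentage of positive consensus calls."""
    n = len(calls)
    k = sum(1 for c in calls if c.status)
    return {"n": n, "n_positive": k,
            "percent": (100.0 * k / n) if n else 0.0}


def write_consensus_tsv(calls: Iterable[ConsensusCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstatus\tn_supporting\tdistances\n")
        for c in calls:
            dist = ",".join("NA" if d is None else str(d) for d in c.per_replicate_distance)
            fh.write(f"{c.gene_id}\t{int(c.status)}\t{c.n_supporting}\t{dist}\n")
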