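"""Gene models, genomic windows and annotation file formats.

All internal coordinates are 0-based half-open (BED/bedGraph convention);
1-based formats (GTF) are converted at the file boundary.  Every window is
strand-aware relative to the transcription start site (TSS): for a plus-strand
gene the TSS is ``start``; for a minus-strand gene it is ``end - 1`` and
"downstream" means decreasing genomic coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "Interval",
    "GenomeSequence",
    "ParseError",
    "promoter_window",
    "body_window",
    "tss_flank",
    "load_gene_models",
    "write_bed12",
    "load_genome_fasta",
    "write_genome_fasta",
]


class ParseError(ValueError):
    """Malformed annotation input; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


def _round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4, not banker's 4 -> 4)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval [start, end); empty (start == end) allowed."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene with one or more annotated TSSs.

    The canonical TSS is ``start`` on plus-strand genes and ``end - 1`` on
    minus-strand genes; additional TSSs (alternative isoform starts) may be
    listed in ``tss_list``.  All distance-based classifications take the
    minimum over ``tss_list``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss_list: tuple[int, ...] = ()
    category_hint: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.tss_list:
            object.__setattr__(self, "tss_list", (self.canonical_tss,))

    @property
    def canonical_tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeSequence:
    """Uppercase DNA per chromosome, over the alphabet {A, C, G, T, N}."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}
        for chrom, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"{chrom}: invalid characters {sorted(bad)}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, interval: Interval) -> str:
        seq = self.sequences[interval.chrom]
        return seq[interval.start : interval.end]

    def contains(self, gene: GeneModel) -> bool:
        size = self.chrom_sizes.get(gene.chrom)
        return size is not None and gene.end <= size


def promoter_window(gene: GeneModel, fraction: float = 0.05) -> Interval:
    """Promoter-proximal window: the first ``fraction`` of the gene from its TSS.

    The window extends in the direction of transcription; length is
    round(fraction * gene length), clamped to >= 1 bp.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    length = max(1, _round_half_away(fraction * gene.length))
    if gene.strand == "+":
        return Interval(gene.chrom, gene.start, gene.start + length)
    return Interval(gene.chrom, gene.end - length, gene.end)


def body_window(gene: GeneModel, fraction: float = 0.30) -> Interval:
    """Gene-body window: from ``fraction`` into the gene through the TES."""
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    offset = _round_half_away(fraction * gene.length)
    if gene.strand == "+":
        return Interval(gene.chrom, gene.start + offset, gene.end)
    return Interval(gene.chrom, gene.start, gene.end - offset)


def tss_flank(tss: int, half_width: int = 2000, chrom_len: int | None = None,
              chrom: str = "") -> Interval:
    """Symmetric window of ``half_width`` bp on each side of the TSS base.

    Returns [tss - half_width, tss + half_width + 1), clipped to the
    chromosome when ``chrom_len`` is given.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    start = max(0, tss - half_width)
    end = tss + half_width + 1
    if chrom_len is not None:
        end = min(end, chrom_len)
        start = min(start, end)
    return Interval(chrom, start, end)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _check_unique(models: list[GeneModel], path) -> list[GeneModel]:
    seen: dict[str, int] = {}
    for i, m in enumerate(models):
        if m.gene_id in seen:
            raise ParseError(f"duplicate gene_id {m.gene_id!r}", path=path)
        seen[m.gene_id] = i
    return models


def _parse_bed_line(fields: Sequence[str], path, lineno: int) -> GeneModel:
    if len(fields) < 6:
        raise ParseError(f"expected >= 6 BED fields, got {len(fields)}", path, lineno)
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"non-integer coordinate: {exc}", path, lineno) from exc
    if end <= start:
        raise ParseError(f"end {end} <= start {start}", path, lineno)
    strand = fields[5]
    if strand not in ("+", "-"):
        raise ParseError(f"bad strand {strand!r}", path, lineno)
    return GeneModel(gene_id=fields[3], chrom=fields[0], start=start, end=end,
                     strand=strand)


def _parse_gtf_lite(lines: Iterable[str], path) -> list[GeneModel]:
    models = []
    skipped = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ParseError(f"expected 9 GTF fields, got {len(fields)}", path, lineno)
        if fields[2] != "gene":
            skipped += 1
            continue
        try:
            start1, end1 = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise ParseError(f"non-integer coordinate: {exc}", path, lineno) from exc
        start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        if end <= start:
            raise ParseError(f"end {end1} <= start {start1}", path, lineno)
        strand = fields[6]
        if strand not in ("+", "-"):
            raise ParseError(f"bad strand {strand!r}", path, lineno)
        gene_id = None
        for attr in fields[8].split(";"):
            attr = attr.strip()
            if attr.startswith("gene_id"):
                gene_id = attr.split(None, 1)[1].strip().strip('"')
                break
        if gene_id is None:
            raise ParseError("missing gene_id attribute", path, lineno)
        models.append(GeneModel(gene_id=gene_id, chrom=fields[0], start=start,
                                end=end, strand=strand))
    if skipped:
        logger.info("ignored %d non-gene GTF records in %s", skipped, path)
    return models


def _parse_gene_tsv(lines: Iterable[str], path) -> list[GeneModel]:
    """Tab-separated gene table: gene_id chrom start end strand [tss_list] [category]."""
    models = []
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None and fields[0] == "gene_id":
            header = fields
            continue
        if len(fields) < 5:
            raise ParseError(f"expected >= 5 TSV fields, got {len(fields)}", path, lineno)
        try:
            start, end = int(fields[2]), int(fields[3])
        except ValueError as exc:
            raise ParseError(f"non-integer coordinate: {exc}", path, lineno) from exc
        if end <= start:
            raise ParseError(f"end {end} <= start {start}", path, lineno)
        tss_list: tuple[int, ...] = ()
        if len(fields) > 5 and fields[5]:
            tss_list = tuple(int(t) for t in fields[5].split(","))
        category = fields[6] if len(fields) > 6 and fields[6] else None
        models.append(GeneModel(gene_id=fields[0], chrom=fields[1], start=start,
                                end=end, strand=fields[4], tss_list=tss_list,
                                category_hint=category))
    return models


def load_gene_models(path, format: str = "bed12") -> list[GeneModel]:
    """Load gene models from BED6/BED12, minimal GTF, or a gene TSV.

    Models are returned in file order; duplicate gene_ids are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        if format in ("bed12", "bed6", "bed"):
            models = []
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                models.append(_parse_bed_line(line.split(), path, lineno))
        elif format == "gtf_lite":
            models = _parse_gtf_lite(fh, path)
        elif format == "tsv":
            models = _parse_gene_tsv(fh, path)
        else:
            raise ValueError(f"unknown format {format!r}")
    return _check_unique(models, path)


def write_bed12(models: Iterable[GeneModel], path) -> None:
    """Write genes as single-block BED12, sorted by (chrom, start)."""
    rows = sorted(models, key=lambda m: (m.chrom, m.start, m.gene_id))
    with open(path, "w") as fh:
        for m in rows:
            block = m.end - m.start
            fh.write(
                "\t".join(
                    [m.chrom, str(m.start), str(m.end), m.gene_id, "0", m.strand,
                     str(m.start), str(m.end), "0", "1", f"{block},", "0,"]
                )
                + "\n"
            )


def write_gene_tsv(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\ttss_list\tcategory\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.gene_id)):
            fh.write(
                f"{m.gene_id}\t{m.chrom}\t{m.start}\t{m.end}\t{m.strand}\t"
                f"{','.join(map(str, m.tss_list))}\t{m.category_hint or ''}\n"
            )


def load_intervals_bed(path) -> list[Interval]:
    """Plain BED3+ intervals (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError("expected >= 3 BED fields", path, lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from exc
            out.append(Interval(fields[0], start, end))
    return out


def write_intervals_bed(intervals: Iterable[Interval], path) -> None:
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def load_genome_fasta(path) -> GenomeSequence:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSequence(sequences=seqs)


def write_genome_fasta(genome: GenomeSequence, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sorted(genome.sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")
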