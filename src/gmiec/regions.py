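"""BED regions to gene set via overlap with a gene annotation table.

Both the BED input and the annotation use 0-based half-open coordinates;
touching intervals (a.end == b.start) do not overlap. 1-based inclusive
exports (e.g. RefSeq tables) must be shifted by one before use. Strand is
ignored and any overlap of >= 1 bp counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .io import ParseError, ValidationError


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start in interval {self}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class GeneAnnotation:
    """(interval, gene symbol) records; one gene may span several records."""

    records: list[tuple[GenomicInterval, str]]

    def __post_init__(self) -> None:
        for _, gene in self.records:
            if not gene:
                raise ValidationError("annotation record with empty gene symbol")


def read_bed(path) -> list[GenomicInterval]:
    """Parse BED3/BED4 into intervals, preserving file order."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else None
            intervals.append(GenomicInterval(fields[0], start, end, name))
    return intervals


def read_annotation(path) -> GeneAnnotation:
    """Read a 4-column annotation TSV: chrom, start, end, gene (0-based half-open)."""
    records = []
    with open(path) as fh:
        header = fh.readline()
        if header and not _looks_like_header(header):
            fh.seek(0)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: annotation line has <4 columns")
            records.append(
                (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), fields[3])
            )
    return GeneAnnotation(records=records)


def _looks_like_header(line: str) -> bool:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        return True
    try:
        int(fields[1])
        int(fields[2])
    except ValueError:
        return True
    return False


def map_regions_to_genes(
    regions: list[GenomicInterval], annotation: GeneAnnotation
) -> list[str]:
    """Genes whose annotation interval overlaps any region by >= 1 bp.

    Half-open overlap test (a.start < b.end and b.start < a.end), so touching
    intervals never match. Returns unique symbols in lexicographic order;
    raises when nothing overlaps, since downstream analysis needs a non-empty
    gene set.
    """
    if not regions:
        raise ValidationError("no regions provided")
    if not annotation.records:
        raise ValidationError("empty gene annotation")
    trees: dict[str, IntervalTree] = {}
    for region in regions:
        trees.setdefault(region.chrom, IntervalTree()).addi(region.start, region.end)
    hits: set[str] = set()
    for interval, gene in annotation.records:
        tree = trees.get(interval.chrom)
        if tree is not None and tree.overlap(interval.start, interval.end):
            hits.add(gene)
    if not hits:
        raise ValidationError("no annotated gene overlaps any supplied region")
    return sorted(hits)
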