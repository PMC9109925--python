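"""Gene annotation handling: GTF exon extraction and exon flattening.

Read types are only well defined over a *non-overlapping* exon partition:
if two annotated exons overlap, a read falling in the shared region has no
unique exon ID. This module converts each gene's (possibly overlapping)
exon records into an ordered set of disjoint "flat" exons, numbered 1..E
left to right along the genome, so that every exonic base belongs to
exactly one exon ID.

Coordinates are 1-based inclusive internally (GTF convention). The
flattened annotation is serialized as a BED-like 6-column TSV with
0-based half-open coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Raised for empty or structurally invalid annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class FlatExon:
    """One non-overlapping exon of a gene, with its integer exon ID."""

    gene_id: str
    exon_id: int
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.exon_id < 1:
            raise ValueError("exon_id must be a positive integer")


@dataclass
class GeneModel:
    """A gene as an ordered list of disjoint flat exons on one chromosome."""

    gene_id: str
    exons: list[FlatExon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")
        chroms = {e.interval.chrom for e in self.exons}
        if len(chroms) != 1:
            raise AnnotationError(f"gene {self.gene_id}: exons span chromosomes {chroms}")
        ids = [e.exon_id for e in self.exons]
        if ids != list(range(1, len(ids) + 1)):
            raise AnnotationError(f"gene {self.gene_id}: exon IDs {ids} not consecutive from 1")
        starts = [e.interval.start for e in self.exons]
        if starts != sorted(starts):
            raise AnnotationError(f"gene {self.gene_id}: exons not sorted by start")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.interval.end >= b.interval.start:
                raise AnnotationError(f"gene {self.gene_id}: overlapping flat exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_lengths(self) -> dict[int, int]:
        return {e.exon_id: e.interval.length for e in self.exons}


def parse_annotation(stream: IO[str] | Iterable[str]) -> dict[str, list[GenomicInterval]]:
    """Extract exon intervals per gene from a GTF/GFF2 stream.

    Only ``exon`` feature records are used; anything else (CDS, UTR, ...)
    is ignored. Records that fail to parse, or exon records without a
    ``gene_id`` attribute, are skipped with a logged warning. Duplicate
    identical intervals within a gene are deduplicated.

    Raises
    ------
    AnnotationError
        If the stream contains no usable exon record at all.
    """
    out: dict[str, list[GenomicInterval]] = {}
    seen: dict[str, set[GenomicInterval]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # malformed record
            logger.warning("skipping malformed annotation line %d: %s", lineno, exc)
            continue
        if feat.featuretype != "exon":
            continue
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            logger.warning("skipping exon without gene_id at line %d", lineno)
            continue
        gene_id = gene_ids[0]
        strand = feat.strand if feat.strand in ("+", "-") else "."
        try:
            iv = GenomicInterval(feat.seqid, feat.start, feat.end, strand)
        except ValueError as exc:
            logger.warning("skipping invalid exon at line %d: %s", lineno, exc)
            continue
        if iv not in seen.setdefault(gene_id, set()):
            seen[gene_id].add(iv)
            out.setdefault(gene_id, []).append(iv)
    if not out:
        raise AnnotationError("annotation stream contains no exon records")
    return out


def flatten_exons(gene_id: str, intervals: list[GenomicInterval]) -> GeneModel:
    """Partition the union of a gene's exons into disjoint flat exons.

    Breakpoints are placed wherever the set of covering input exons
    changes, so the output is the coarsest disjoint partition in which
    every input exon is a union of consecutive flat exons. IDs are
    assigned 1..E in genomic (left-to-right) order; strand is recorded
    but plays no role in the numbering.
    """
    if not intervals:
        raise AnnotationError(f"gene {gene_id}: empty interval list")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise AnnotationError(f"gene {gene_id}: intervals on multiple chromosomes {chroms}")
    strands = {iv.strand for iv in intervals}
    strand = strands.pop() if len(strands) == 1 else "."

    # candidate breakpoints: interval starts, and positions just past ends
    chrom = intervals[0].chrom
    points = sorted({iv.start for iv in intervals} | {iv.end + 1 for iv in intervals})
    spans = sorted({(iv.start, iv.end) for iv in intervals})
    flat: list[FlatExon] = []
    for lo, hi in zip(points, points[1:]):
        seg_end = hi - 1
        # a segment between adjacent breakpoints is covered iff any input spans it whole
        if any(s <= lo and seg_end <= e for s, e in spans):
            flat.append(
                FlatExon(gene_id, len(flat) + 1, GenomicInterval(chrom, lo, seg_end, strand))
            )
    return GeneModel(gene_id, flat)


def flatten_annotation(exons_by_gene: dict[str, list[GenomicInterval]]) -> dict[str, GeneModel]:
    """Flatten every gene of a parsed annotation; genes are independent."""
    return {g: flatten_exons(g, ivs) for g, ivs in sorted(exons_by_gene.items())}


FLAT_COLUMNS = ("chrom", "start", "end", "gene_id", "exon_id", "strand")


def write_flat_annotation(models: dict[str, GeneModel], stream: IO[str]) -> None:
    """Write flat exons as BED-like TSV (0-based half-open coordinates)."""
    stream.write("#" + "\t".join(FLAT_COLUMNS) + "\n")
    for gene_id in sorted(models):
        for e in models[gene_id].exons:
            iv = e.interval
            stream.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{gene_id}\t{e.exon_id}\t{iv.strand}\n"
            )


def read_flat_annotation(stream: IO[str] | Iterable[str]) -> dict[str, GeneModel]:
    """Read a flat-annotation TSV back into gene models.

    Validation (consecutive exon IDs, disjointness, sortedness) happens in
    the ``GeneModel`` constructor; a file violating the invariants raises
    :class:`AnnotationError`.
    """
    rows: dict[str, list[FlatExon]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise AnnotationError(f"line {lineno}: expected 6 columns, got {len(parts)}")
        chrom, start, end, gene_id, exon_id, strand = parts
        iv = GenomicInterval(chrom, int(start) + 1, int(end), strand)
        rows.setdefault(gene_id, []).append(FlatExon(gene_id, int(exon_id), iv))
    if not rows:
        raise AnnotationError("flat annotation stream is empty")
    models = {}
    for gene_id, exons in rows.items():
        exons.sort(key=lambda e: e.exon_id)
        models[gene_id] = GeneModel(gene_id, exons)
    return models
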