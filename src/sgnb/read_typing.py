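"""Summarize aligned single-end reads into read types and count them.

A read type is a string of ordered exon IDs ("1", "2-4", ...): the chain
of flat exons that a read's aligned segments touch. Because the flat
exons of a gene are disjoint, the chain is unambiguous. Reads that fall
partly outside any flat exon, or touch exons of more than one gene, are
discarded — the model assumes each read originates from a single gene.

Counting yields a (gene, read type) x sample table of counts X_ghj plus
per-sample library sizes N_j (total mapped primary alignments).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Mapping

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import GeneModel, GenomicInterval

# discard reasons
UNMAPPED = "unmapped"
SECONDARY = "secondary"
SUPPLEMENTARY = "supplementary"
NO_GENE = "no-gene"
MULTI_GENE = "multi-gene"
OUTSIDE_EXONS = "outside-exons"


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to its reference match blocks."""

    query_id: str
    chrom: str
    blocks: tuple[GenomicInterval, ...]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("AlignedRead needs at least one block")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.end >= b.start:
                raise ValueError("blocks must be sorted and non-overlapping")


@dataclass(frozen=True)
class ReadType:
    """An ordered chain of exon IDs within one gene."""

    gene_id: str
    chain: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.chain:
            raise ValueError("empty chain")
        if list(self.chain) != sorted(set(self.chain)):
            raise ValueError(f"chain {self.chain} not strictly increasing")

    @property
    def label(self) -> str:
        return chain_label(self.chain)


def chain_label(chain: Iterable[int]) -> str:
    return "-".join(str(i) for i in chain)


def parse_chain(label: str) -> tuple[int, ...]:
    return tuple(int(tok) for tok in label.split("-"))


@dataclass
class DesignInfo:
    """Two-condition design: sample_id -> condition label 0 or 1."""

    conditions: dict[str, int]

    def __post_init__(self) -> None:
        bad = {s: c for s, c in self.conditions.items() if c not in (0, 1)}
        if bad:
            raise ValueError(f"conditions must be 0 or 1, got {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.conditions)

    def samples_in(self, condition: int) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    @property
    def j0(self) -> int:
        return len(self.samples_in(0))

    @property
    def j1(self) -> int:
        return len(self.samples_in(1))

    def require_replicates(self, minimum: int = 2) -> None:
        if self.j0 < minimum or self.j1 < minimum:
            raise ValueError(
                f"each condition needs >= {minimum} samples (got {self.j0} and {self.j1})"
            )


@dataclass
class CountTable:
    """Read-type counts: rows (gene_id, read_type label), columns samples.

    ``lib_sizes`` holds N_j, the total mapped primary alignments per
    sample (not just exonic ones).
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series
    discards: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.counts.index.names) != ["gene_id", "read_type"]:
            self.counts.index = self.counts.index.set_names(["gene_id", "read_type"])
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = [s for s in self.counts.columns if s not in self.lib_sizes.index]
        if missing:
            raise ValueError(f"lib_sizes missing samples {missing}")
        if (self.lib_sizes.loc[list(self.counts.columns)] <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def genes(self) -> list[str]:
        return list(self.counts.index.get_level_values("gene_id").unique())

    def gene(self, gene_id: str) -> pd.DataFrame:
        return self.counts.xs(gene_id, level="gene_id", drop_level=True)

    def to_tsv(self, stream: IO[str]) -> None:
        self.counts.to_csv(stream, sep="\t")

    @classmethod
    def from_tsv(cls, stream: IO[str], lib_sizes: Mapping[str, int] | pd.Series | None = None) -> "CountTable":
        df = pd.read_csv(stream, sep="\t", index_col=[0, 1], dtype={0: str, 1: str})
        df.index = df.index.set_names(["gene_id", "read_type"])
        if lib_sizes is None:
            sizes = df.sum(axis=0)
        else:
            sizes = pd.Series(lib_sizes, dtype=float)
        return cls(df, sizes)


def blocks_from_alignment(record: pysam.AlignedSegment, sample_id: str = "") -> AlignedRead | str:
    """Turn one SAM/BAM alignment into match blocks, or a discard reason.

    Junction gaps (N) split blocks; deletions (D) are absorbed into the
    enclosing block; insertions and clips consume no reference and are
    dropped. Only mapped, primary, non-supplementary records are kept.
    """
    if record.is_unmapped:
        return UNMAPPED
    if record.is_secondary:
        return SECONDARY
    if record.is_supplementary:
        return SUPPLEMENTARY
    pos = record.reference_start + 1  # to 1-based
    chrom = record.reference_name
    blocks: list[GenomicInterval] = []
    cur_start: int | None = None
    cur_end: int | None = None
    for op, length in record.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X: consume reference, part of the read
            if cur_start is None:
                cur_start = pos
            pos += length
            cur_end = pos - 1
        elif op == 2:  # D: absorbed into the enclosing block
            pos += length
            if cur_start is not None:
                cur_end = pos - 1
        elif op == 3:  # N: junction gap closes the block
            if cur_start is not None:
                blocks.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start = cur_end = None
            pos += length
        # I (1), S (4), H (5), P (6): no reference consumption
    if cur_start is not None:
        blocks.append(GenomicInterval(chrom, cur_start, cur_end))
    if not blocks:
        return UNMAPPED
    return AlignedRead(record.query_name, chrom, tuple(blocks), sample_id)


class GeneIndex:
    """Interval index over all genes' flat exons, per chromosome."""

    def __init__(self, models: Mapping[str, GeneModel]):
        self.models = dict(models)
        self._trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
        for gene_id, model in models.items():
            for exon in model.exons:
                iv = exon.interval
                # IntervalTree is half-open; store [start, end+1)
                self._trees[iv.chrom][iv.start : iv.end + 1] = (gene_id, exon.exon_id)

    def hits(self, chrom: str, start: int, end: int) -> list[tuple[int, int, str, int]]:
        """(overlap_start, overlap_end, gene_id, exon_id) for exons touching [start, end]."""
        out = []
        for node in self._trees.get(chrom, IntervalTree()).overlap(start, end + 1):
            gene_id, exon_id = node.data
            out.append((max(node.begin, start), min(node.end - 1, end), gene_id, exon_id))
        return out


def assign_read_type(read: AlignedRead, index: GeneIndex) -> ReadType | str:
    """Assign a read to a gene's read type, or return a discard reason.

    The read is kept iff every base of every block lies inside flat exons
    of exactly one gene. The chain is the genomically ordered set of
    distinct exon IDs its blocks overlap.
    """
    genes: set[str] = set()
    per_block_hits = []
    for block in read.blocks:
        hits = index.hits(read.chrom, block.start, block.end)
        genes.update(g for _, _, g, _ in hits)
        per_block_hits.append(hits)
    if not genes:
        return NO_GENE
    if len(genes) > 1:
        return MULTI_GENE
    (gene_id,) = genes
    exon_ids: set[int] = set()
    for block, hits in zip(read.blocks, per_block_hits):
        # coverage check: exon hits must tile the block without gaps
        spans = sorted((s, e) for s, e, g, _ in hits if g == gene_id)
        covered_to = block.start - 1
        for s, e in spans:
            if s > covered_to + 1:
                return OUTSIDE_EXONS
            covered_to = max(covered_to, e)
        if covered_to < block.end:
            return OUTSIDE_EXONS
        exon_ids.update(x for _, _, g, x in hits if g == gene_id)
    return ReadType(gene_id, tuple(sorted(exon_ids)))


def iter_sam(path: str, sample_id: str) -> Iterator[pysam.AlignedSegment]:
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        yield from fh


def count_read_types(
    alignments_by_sample: Mapping[str, Iterable[pysam.AlignedSegment]],
    models: Mapping[str, GeneModel],
    design: DesignInfo | None = None,
) -> CountTable:
    """Count read types per sample from alignment streams.

    N_j is the number of mapped primary alignments in sample j. A sample
    with zero mapped reads raises ``ValueError``. The returned table's
    ``discards`` frame tallies why reads were dropped, per sample; for
    every sample, assigned + discarded == mapped primary alignments.
    """
    if not alignments_by_sample:
        raise ValueError("no samples provided")
    index = GeneIndex(models)
    counts: dict[tuple[str, str], dict[str, int]] = collections.defaultdict(dict)
    lib_sizes: dict[str, int] = {}
    discards: dict[str, collections.Counter] = {}
    for sample_id, stream in alignments_by_sample.items():
        n_mapped = 0
        tally: collections.Counter = collections.Counter()
        for record in stream:
            got = blocks_from_alignment(record, sample_id)
            if isinstance(got, str):
                # unmapped / secondary / supplementary: excluded from N_j
                tally[got] += 1
                continue
            n_mapped += 1
            typed = assign_read_type(got, index)
            if isinstance(typed, str):
                tally[typed] += 1
                continue
            key = (typed.gene_id, typed.label)
            counts[key][sample_id] = counts[key].get(sample_id, 0) + 1
        if n_mapped == 0:
            raise ValueError(f"sample {sample_id!r} has zero mapped reads")
        lib_sizes[sample_id] = n_mapped
        discards[sample_id] = tally
    samples = list(alignments_by_sample)
    order = sorted(counts, key=lambda k: (k[0], parse_chain(k[1])))
    df = pd.DataFrame.from_dict(counts, orient="index", columns=None).reindex(columns=samples)
    df = df.fillna(0).astype(int).loc[order]
    df.index = pd.MultiIndex.from_tuples(order, names=["gene_id", "read_type"])
    disc = pd.DataFrame(discards).fillna(0).astype(int)
    if design is not None:
        missing = [s for s in design.samples if s not in samples]
        if missing:
            raise ValueError(f"design refers to absent samples {missing}")
    return CountTable(df, pd.Series(lib_sizes, dtype=float), disc)
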