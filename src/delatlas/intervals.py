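"""Genomic interval and gene-model primitives.

Coordinates are 0-based, half-open everywhere inside the package;
format conversions (GFF3 is 1-based inclusive) happen at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .errors import InvalidArgumentError


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval, sortable by (chrom, start, end)."""

    chrom: str
    start: int
    end: int
    strand: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidArgumentError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        """Half-open overlap of at least ``min_bp`` base pairs."""
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance_to(self, pos: int) -> int:
        """bp distance from this interval to a position (0 if inside)."""
        return max(0, self.start - pos, pos - (self.end - 1))


@dataclass(frozen=True)
class GeneModel:
    """Gene span with strand-aware TSS and optional exon structure."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple = ()   # (start, end) pairs, half-open; empty = span fallback

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidArgumentError(
                f"gene {self.gene_id}: invalid span {self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise InvalidArgumentError(
                f"gene {self.gene_id}: strand must be '+' or '-'"
            )
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise InvalidArgumentError(
                    f"gene {self.gene_id}: exon {s}-{e} outside span"
                )

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (last base of the span on the minus strand)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, strand=self.strand)


def build_tree(intervals) -> dict:
    """chrom -> IntervalTree of the given GenomicIntervals."""
    trees: dict = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def any_overlap(tree_by_chrom: dict, iv: GenomicInterval, min_bp: int = 1) -> bool:
    """Does ``iv`` overlap any tree interval by at least ``min_bp`` bp?"""
    tree = tree_by_chrom.get(iv.chrom)
    if tree is None:
        return False
    for hit in tree.overlap(iv.start, iv.end):
        if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_bp:
            return True
    return False
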