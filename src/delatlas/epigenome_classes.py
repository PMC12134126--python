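"""Classification of H3K27ac-increased regions by H3K4me3 co-occurrence.

Regions with increased H3K27ac (called upstream by differential-binding
tools) are split into promoter-like H3K27ac^up/H3K4me3^pos and
enhancer-like H3K27ac^up/H3K4me3^neg elements by overlap with H3K4me3
peaks, then annotated genomically (promoter / exon / intron / intergenic)
by their midpoint with fixed precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .errors import InvalidArgumentError
from .intervals import GeneModel, GenomicInterval, any_overlap, build_tree
from .multiomic_screen import assign_nearest_gene

K4_POS = "H3K27ac_up_K4pos"
K4_NEG = "H3K27ac_up_K4neg"
ANNOTATIONS = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class RegionClassification:
    region: GenomicInterval
    class_label: str                  # K4_POS or K4_NEG
    annotation: str | None = None     # one of ANNOTATIONS
    nearest_gene: str | None = None


def split_by_h3k4me3(
    up_regions: list,
    k4_peaks: list,
    min_overlap_bp: int = 1,
) -> list:
    """Label each H3K27ac-up region pos/neg by H3K4me3 peak overlap.

    A region is positive iff it overlaps at least one peak by
    ``min_overlap_bp`` bp (half-open coordinates).
    """
    if min_overlap_bp < 1:
        raise InvalidArgumentError("min_overlap_bp must be >= 1")
    trees = build_tree(k4_peaks)
    return [
        RegionClassification(
            region=region,
            class_label=K4_POS if any_overlap(trees, region, min_overlap_bp) else K4_NEG,
        )
        for region in up_regions
    ]


def _promoter_offset(pos: int, gene: GeneModel) -> int:
    """Signed strand-aware offset of a position from the gene TSS."""
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def annotate_midpoint(
    pos: int,
    chrom: str,
    genes_on_chrom: list,
    promoter_window: tuple = (-2000, 500),
) -> str:
    """Genomic annotation of a single position with fixed precedence.

    Precedence promoter > exon > intron > intergenic.  The promoter window
    is strand-aware around the TSS; genes without exon structure treat the
    whole span as exonic.
    """
    lo, hi = promoter_window
    for g in genes_on_chrom:
        if lo <= _promoter_offset(pos, g) <= hi:
            return "promoter"
    for g in genes_on_chrom:
        if g.start <= pos < g.end:
            if not g.exons:
                return "exon"
            if any(s <= pos < e for s, e in g.exons):
                return "exon"
            return "intron"
    return "intergenic"


def annotate_regions(
    classified: list,
    genes: list,
    promoter_window: tuple = (-2000, 500),
) -> list:
    """Attach a midpoint genomic annotation and nearest gene to each region."""
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.gene_id))
    # assign_nearest_gene skips gene-free chromosomes; map back by coordinates
    nearest_by_coord = {
        (t.interval.chrom, t.interval.start, t.interval.end): t.nearest_gene
        for t in assign_nearest_gene([c.region for c in classified], genes)
    }
    out = []
    for c in classified:
        anno = annotate_midpoint(
            c.region.midpoint, c.region.chrom,
            by_chrom.get(c.region.chrom, []), promoter_window,
        )
        out.append(
            replace(
                c,
                annotation=anno,
                nearest_gene=nearest_by_coord.get(
                    (c.region.chrom, c.region.start, c.region.end)
                ),
            )
        )
    return out


def class_summary(classified: list) -> pd.DataFrame:
    """Counts and within-class fractions per (class, annotation)."""
    if not classified:
        return pd.DataFrame(columns=["class_label", "annotation", "count", "fraction"])
    rows = pd.DataFrame(
        {
            "class_label": [c.class_label for c in classified],
            "annotation": [c.annotation for c in classified],
        }
    )
    counts = (
        rows.value_counts(["class_label", "annotation"])
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("class_label")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts.sort_values(
        ["class_label", "annotation"], kind="mergesort"
    ).reset_index(drop=True)
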