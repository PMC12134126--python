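"""4C-seq interaction screen: consensus, nearest gene, DEG intersection.

Given per-replicate interaction intervals measured from a fixed viewpoint
locus, the screen (i) keeps intervals reproduced across replicates,
(ii) annotates each with its nearest gene by TSS distance on the same
chromosome, (iii) classifies contacts as intra- or inter-chromosomal
relative to the viewpoint, and (iv) intersects the target genes with a
differential-expression table to rank candidate genes by fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .intervals import GeneModel, GenomicInterval, any_overlap, build_tree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionTarget:
    """A consensus interaction interval annotated with its nearest gene."""

    interval: GenomicInterval
    nearest_gene: str
    distance: int                       # bp to the gene TSS, 0 if inside
    chromosomal_class: str | None = None  # "intra" / "inter"
    replicate_support: int | None = None

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise InvalidArgumentError("distance must be >= 0")


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2FC: float
    padj: float

    def __post_init__(self) -> None:
        if not 0 <= self.padj <= 1:
            raise InvalidArgumentError(
                f"{self.gene_id}: padj must lie in [0, 1]"
            )

    @property
    def direction(self) -> str:
        return "up" if self.log2FC > 0 else "down"


def replicate_consensus(
    replicates: list,
    min_support: int | None = None,
) -> list:
    """Intervals of replicate 1 supported by enough other replicates.

    An interval is retained when it is overlapped (>= 1 bp, half-open) by
    intervals in at least ``min_support - 1`` of the other replicates;
    ``min_support`` defaults to the number of replicates (support required
    in all of them).  Output is sorted by (chrom, start).
    """
    if not replicates:
        raise InvalidArgumentError("need at least one replicate")
    n_reps = len(replicates)
    if min_support is None:
        min_support = n_reps
    if not 1 <= min_support <= n_reps:
        raise InvalidArgumentError(
            f"min_support={min_support} out of range for {n_reps} replicates"
        )
    trees = [build_tree(rep) for rep in replicates[1:]]
    kept = []
    for iv in replicates[0]:
        support = 1 + sum(any_overlap(t, iv) for t in trees)
        if support >= min_support:
            kept.append(iv)
    return sorted(kept)


def assign_nearest_gene(intervals: list, genes: list) -> list:
    """Nearest gene per interval by TSS distance on the same chromosome.

    Distance is 0 when the TSS lies inside the (half-open) interval; ties
    resolve to the lexicographically smallest gene_id.  Intervals on
    chromosomes without genes yield no target (counted in a log message —
    the reason interval counts can exceed assigned-gene counts).
    """
    if not genes:
        raise InvalidArgumentError("gene list is empty")
    by_chrom: dict = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.tss, g.gene_id))
    tss_arrays = {
        c: np.array([g.tss for g in lst]) for c, lst in by_chrom.items()
    }
    targets, unassigned = [], 0
    for iv in intervals:
        lst = by_chrom.get(iv.chrom)
        if not lst:
            unassigned += 1
            continue
        tss = tss_arrays[iv.chrom]
        dist = np.maximum.reduce(
            [np.zeros_like(tss), iv.start - tss, tss - (iv.end - 1)]
        )
        best = np.flatnonzero(dist == dist.min())
        gene = min((lst[i] for i in best), key=lambda g: g.gene_id)
        targets.append(
            InteractionTarget(
                interval=iv, nearest_gene=gene.gene_id,
                distance=int(dist.min()),
            )
        )
    if unassigned:
        logger.info(
            "%d of %d intervals lie on chromosomes without genes and stay "
            "unassigned", unassigned, len(intervals),
        )
    return targets


def classify_chromosomal(targets: list, viewpoint: GenomicInterval) -> list:
    """Tag targets intra (same chromosome as the viewpoint) or inter."""
    out = [
        replace(
            t,
            chromosomal_class=(
                "intra" if t.interval.chrom == viewpoint.chrom else "inter"
            ),
        )
        for t in targets
    ]
    counts = pd.Series([t.chromosomal_class for t in out]).value_counts()
    logger.info(
        "chromosomal classes: intra=%d inter=%d",
        int(counts.get("intra", 0)), int(counts.get("inter", 0)),
    )
    return out


def screen_candidates(
    targets: list,
    degs: list,
    padj_thresh: float = 0.05,
    lfc_thresh: float = 0.585,
) -> pd.DataFrame:
    """Interaction targets with significant expression changes, FC-ranked.

    Candidates are genes that are the nearest gene of at least one
    consensus target and pass ``padj < padj_thresh`` and
    ``|log2FC| >= lfc_thresh``.  Rows are ranked by descending |log2FC|
    (dense rank, ties broken by gene_id) and carry the minimal interaction
    distance over the gene's supporting targets.
    """
    dist_by_gene: dict = {}
    for t in targets:
        d = dist_by_gene.get(t.nearest_gene)
        dist_by_gene[t.nearest_gene] = t.distance if d is None else min(d, t.distance)
    rows = []
    for rec in degs:
        if rec.gene_id not in dist_by_gene:
            continue
        if rec.padj < padj_thresh and abs(rec.log2FC) >= lfc_thresh:
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "direction": rec.direction,
                    "log2FC": rec.log2FC,
                    "padj": rec.padj,
                    "distance": dist_by_gene[rec.gene_id],
                }
            )
    cols = ["gene_id", "direction", "log2FC", "padj", "distance", "rank"]
    if not rows:
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(rows)
    table["abs_lfc"] = table["log2FC"].abs()
    table = table.sort_values(
        ["abs_lfc", "gene_id"], ascending=[False, True], kind="mergesort"
    ).drop(columns="abs_lfc")
    table["rank"] = range(1, len(table) + 1)
    return table.reset_index(drop=True)[cols]


def degs_from_frame(frame: pd.DataFrame) -> list:
    """DEGRecord list from a (gene_id, log2FC, padj) DataFrame."""
    required = {"gene_id", "log2FC", "padj"}
    missing = required - set(frame.columns)
    if missing:
        raise InvalidArgumentError(f"DEG table lacks columns {sorted(missing)}")
    return [
        DEGRecord(str(r.gene_id), float(r.log2FC), float(r.padj))
        for r in frame.itertuples(index=False)
    ]


def run_screen(
    replicates: list,
    genes: list,
    degs: list,
    viewpoint: GenomicInterval,
    min_support: int | None = None,
    padj_thresh: float = 0.05,
    lfc_thresh: float = 0.585,
):
    """Consensus -> nearest gene -> class -> candidate table in one call.

    Returns ``(targets, candidates, summary)`` where summary counts
    intervals, assigned targets, unique genes, and intra/inter classes.
    """
    consensus = replicate_consensus(replicates, min_support=min_support)
    targets = assign_nearest_gene(consensus, genes)
    targets = classify_chromosomal(targets, viewpoint)
    candidates = screen_candidates(
        targets, degs, padj_thresh=padj_thresh, lfc_thresh=lfc_thresh
    )
    summary = {
        "n_consensus_intervals": len(consensus),
        "n_assigned_targets": len(targets),
        "n_unassigned_intervals": len(consensus) - len(targets),
        "n_unique_genes": len({t.nearest_gene for t in targets}),
        "n_intra": sum(t.chromosomal_class == "intra" for t in targets),
        "n_inter": sum(t.chromosomal_class == "inter" for t in targets),
        "n_candidates": len(candidates),
        "n_up": int((candidates["direction"] == "up").sum()) if len(candidates) else 0,
        "n_down": int((candidates["direction"] == "down").sum()) if len(candidates) else 0,
    }
    return targets, candidates, summary
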