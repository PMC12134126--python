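"""Readers and writers for the package's on-disk formats.

Tabular files are TSV (UTF-8, ``.`` for missing); intervals are BED
(0-based half-open, native) and gene models a GFF3 subset (1-based
inclusive on disk, converted to half-open on read).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .expression import ExpressionMatrix, META_COLUMNS
from .intervals import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

MISSING = "."


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    expr_path,
    meta_path=None,
    scale_tag: str = "linear",
) -> ExpressionMatrix:
    """Load a genes x samples TSV plus optional sample-metadata TSV.

    The expression header row holds sample ids; the metadata file is keyed
    by a ``sample_id`` column.  Samples without metadata raise; metadata
    rows without a matching sample only warn.
    """
    try:
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{expr_path}: {exc}") from exc
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ParseError(f"{expr_path}: duplicated gene_id {dup!r}")
    for col in values.columns:
        bad = pd.to_numeric(values[col], errors="coerce")
        if bad.isna().any():
            row = values.index[bad.isna()][0]
            raise ParseError(
                f"{expr_path}: non-numeric cell at gene {row!r}, sample {col!r}"
            )
        values[col] = bad
    meta = pd.DataFrame()
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", na_values=[MISSING])
        if "sample_id" not in meta.columns:
            raise ParseError(f"{meta_path}: missing sample_id column")
        meta = meta.set_index("sample_id")
        extra = meta.index.difference(values.columns)
        if len(extra):
            logger.warning(
                "%s: %d metadata row(s) without expression samples",
                meta_path, len(extra),
            )
    return ExpressionMatrix(values, scale_tag=scale_tag, sample_meta=meta)


def write_expression(matrix: ExpressionMatrix, expr_path, meta_path=None) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(expr_path, sep="\t", float_format="%.10g")
    if meta_path is not None and not matrix.sample_meta.empty:
        meta = matrix.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t", na_rep=MISSING)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed(path) -> list:
    """BED3/BED6 intervals, returned in canonical (chrom, start) order."""
    intervals = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{ln}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{ln}: start >= end ({start} >= {end})")
            score = None
            strand = None
            if len(fields) >= 5 and fields[4] not in (MISSING, ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{ln}: non-numeric score") from exc
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            intervals.append(
                GenomicInterval(chrom, start, end, strand=strand, score=score)
            )
    return sorted(intervals)


def _fmt_score(score) -> str:
    if score is None:
        return "0"
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(intervals, path, name_prefix: str | None = None) -> None:
    """Write BED3, or BED6 when any interval carries strand or score."""
    six = any(iv.strand is not None or iv.score is not None for iv in intervals)
    with open(path, "w", encoding="utf-8") as fh:
        for i, iv in enumerate(intervals):
            if six:
                name = f"{name_prefix}{i}" if name_prefix else MISSING
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t"
                    f"{_fmt_score(iv.score)}\t{iv.strand or MISSING}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _gff_attributes(field: str) -> dict:
    out = {}
    for part in field.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff_genes(path) -> list:
    """Gene models (gene + exon features) from a GFF3 subset.

    GFF3 coordinates are 1-based inclusive; they are converted to 0-based
    half-open on read.  Exons are attached to their gene via ``Parent``.
    """
    spans: dict = {}
    exons: dict = {}
    order: list = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{ln}: expected 9 GFF3 columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            if start1 > end1 or start1 < 1:
                raise ParseError(f"{path}:{ln}: invalid 1-based span")
            start, end = start1 - 1, end1
            attrs = _gff_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id")
                if gid is None:
                    raise ParseError(f"{path}:{ln}: gene without ID attribute")
                if gid in spans:
                    raise ParseError(f"{path}:{ln}: duplicated gene {gid!r}")
                if strand not in ("+", "-"):
                    raise ParseError(f"{path}:{ln}: gene {gid!r} without strand")
                spans[gid] = (chrom, start, end, strand)
                order.append(gid)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}:{ln}: exon without Parent")
                exons.setdefault(parent, []).append((start, end))
    genes = [
        GeneModel(
            gene_id=gid,
            chrom=spans[gid][0],
            start=spans[gid][1],
            end=spans[gid][2],
            strand=spans[gid][3],
            exons=tuple(sorted(exons.get(gid, ()))),
        )
        for gid in order
    ]
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def write_gff_genes(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tdelatlas\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tdelatlas\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# small tables
# ---------------------------------------------------------------------------

def read_deg_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2FC", "padj"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: DEG table lacks columns {sorted(missing)}")
    return frame


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, na_rep=MISSING, float_format="%.10g")


def parse_viewpoint(spec: str) -> GenomicInterval:
    """Parse a ``chrom:start-end`` viewpoint string (0-based half-open)."""
    try:
        chrom, span = spec.split(":")
        start_s, end_s = span.replace(",", "").split("-")
        return GenomicInterval(chrom, int(start_s), int(end_s))
    except ValueError as exc:
        raise ParseError(f"cannot parse viewpoint {spec!r}") from exc
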