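"""Corn-plot rendering of spatial expression patterns.

A corn plot draws one glyph ("kernel") per laser-microdissected sample,
arranged by section along the anterior-posterior axis (rows) and zipcode
(columns), colored by expression — the stylized view used for gastrula
Geo-seq data.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .expression import ExpressionMatrix
from .io import write_table

#: canonical left-to-right zipcode order on the corn-plot grid
ZIPCODE_ORDER = (
    "EA", "End", "MA", "Mes", "L2", "L1", "A", "Ect", "P", "R1", "R2",
    "MP", "EP", "PS",
)


@dataclass
class CornPlotLayout:
    """Deterministic per-sample plot coordinates from (section, zipcode)."""

    coords: pd.DataFrame  # index sample_id, columns x, y, section_index, zipcode

    @classmethod
    def from_metadata(cls, meta: pd.DataFrame) -> "CornPlotLayout":
        for col in ("section_index", "zipcode"):
            if col not in meta.columns:
                raise InvalidArgumentError(f"metadata lacks {col!r}")
        zips = [z for z in ZIPCODE_ORDER if z in set(meta["zipcode"])]
        extra = sorted(set(meta["zipcode"]) - set(zips))
        order = {z: i for i, z in enumerate(list(zips) + extra)}
        coords = pd.DataFrame(
            {
                "x": [order[z] for z in meta["zipcode"]],
                "y": [-int(s) for s in meta["section_index"]],
                "section_index": meta["section_index"].astype(int),
                "zipcode": meta["zipcode"],
            },
            index=meta.index,
        )
        return cls(coords)


def render_cornplot(
    matrix: ExpressionMatrix,
    gene_or_group,
    out_path,
    layout: CornPlotLayout | None = None,
    log_scale: bool = True,
    cmap: str = "viridis",
) -> pd.DataFrame:
    """Render one corn plot and write the plotted values as TSV.

    ``gene_or_group`` is a gene id or an iterable of gene ids (averaged).
    The glyph color is monotone in (log2) expression.  A TSV of the
    plotted per-sample values is written next to the image at
    ``<out_path>.tsv``; the frame is also returned.
    """
    if isinstance(gene_or_group, str):
        genes = [gene_or_group]
        title = gene_or_group
    else:
        genes = list(gene_or_group)
        title = f"group of {len(genes)} genes"
    unknown = [g for g in genes if g not in matrix.gene_ids]
    if unknown:
        raise InvalidArgumentError(f"unknown gene(s): {unknown[:5]}")
    if layout is None:
        layout = CornPlotLayout.from_metadata(matrix.sample_meta)

    vals = matrix.values.loc[genes].mean(axis=0)
    if log_scale and matrix.scale_tag == "linear":
        vals = np.log2(vals + 1.0)
    plotted = layout.coords.copy()
    plotted["value"] = vals.reindex(plotted.index).to_numpy()

    fig, ax = plt.subplots(figsize=(6, 4))
    sc = ax.scatter(
        plotted["x"], plotted["y"], c=plotted["value"],
        s=220, cmap=cmap, edgecolors="black", linewidths=0.4,
    )
    ax.set_xticks(sorted(plotted["x"].unique()))
    ax.set_xticklabels(
        [
            plotted.loc[plotted["x"] == x, "zipcode"].iloc[0]
            for x in sorted(plotted["x"].unique())
        ],
        rotation=90,
    )
    ax.set_yticks(sorted(plotted["y"].unique()))
    ax.set_yticklabels([str(-y) for y in sorted(plotted["y"].unique())])
    ax.set_xlabel("zipcode")
    ax.set_ylabel("section (posterior → anterior)")
    ax.set_title(title)
    fig.colorbar(sc, ax=ax, label="log2 expression" if log_scale else "expression")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120, metadata={"Software": "delatlas"})
    plt.close(fig)

    tsv = plotted.reset_index(names="sample_id")
    write_table(tsv, f"{out_path}.tsv")
    return plotted
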