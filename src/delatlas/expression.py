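"""Gene x sample expression container shared by every pipeline stage.

The matrix tracks the scale its values live on (``linear`` FPKM-like,
``log2``, or per-gene ``zscore``) so that downstream operations can demand
the scale they were designed for instead of guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: sample-metadata columns recognised across the package
META_COLUMNS = ("stage", "section_index", "zipcode", "day", "genotype")

SCALE_TAGS = ("linear", "log2", "zscore")


class ScaleError(ValueError):
    """Raised when an operation receives values on the wrong scale."""


@dataclass
class ExpressionMatrix:
    """Non-negative (on linear scale) genes x samples expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    scale_tag
        One of ``linear``, ``log2`` or ``zscore``.
    sample_meta
        DataFrame indexed by sample id; any of :data:`META_COLUMNS` may be
        present (``stage``, ``section_index``, ``zipcode``, ``day``,
        ``genotype``).
    """

    values: pd.DataFrame
    scale_tag: str = "linear"
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ScaleError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated gene_id {dup!r}")
        if self.scale_tag == "linear" and (self.values.to_numpy() < 0).any():
            raise ValueError("linear-scale expression must be non-negative")
        if not self.sample_meta.empty:
            missing = self.values.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(
                    f"samples without metadata: {sorted(map(str, missing))}"
                )
            # align metadata to column order; extra metadata rows are tolerated
            self.sample_meta = self.sample_meta.loc[self.values.columns]

    # -- basic views -----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(genes)])

    def require_scale(self, *tags: str) -> None:
        if self.scale_tag not in tags:
            raise ScaleError(
                f"operation requires scale in {tags}, got {self.scale_tag!r}"
            )

    # -- scale conversions ----------------------------------------------
    def to_log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Return a log2-scale copy, ``log2(x + pseudocount)``.

        The default pseudocount of 1 is the conventional choice for
        FPKM-like data that may contain zeros; strictly positive matrices
        can pass ``pseudocount=0`` for an exact transform.
        """
        if self.scale_tag == "log2":
            return self
        self.require_scale("linear")
        vals = self.values.to_numpy(dtype=float)
        if pseudocount == 0 and (vals <= 0).any():
            raise ValueError("pseudocount=0 requires strictly positive values")
        out = np.log2(vals + pseudocount)
        return replace(
            self,
            values=pd.DataFrame(out, index=self.gene_ids, columns=self.sample_ids),
            scale_tag="log2",
        )

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale_tag == "linear":
            return self
        self.require_scale("log2")
        return replace(
            self,
            values=pd.DataFrame(
                np.exp2(self.values.to_numpy(dtype=float)),
                index=self.gene_ids,
                columns=self.sample_ids,
            ),
            scale_tag="linear",
        )
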