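"""Gene-by-sample expression container with stage/replicate annotations.

The container is a thin, validated wrapper around two pandas DataFrames:
``values`` (genes in rows, samples in columns) and ``samples`` (one row per
sample column with ``stage`` and ``replicate`` fields).  A ``units`` tag
distinguishes raw counts from TPM, and an optional per-gene transcript
``lengths`` Series (base pairs) supports TPM computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """A gene x sample abundance matrix.

    Parameters
    ----------
    values:
        Nonnegative abundances, index = gene ids, columns = sample ids.
    samples:
        Per-sample annotation indexed by sample id with at least a ``stage``
        column (condition or developmental stage) and a ``replicate`` column.
    units:
        ``"counts"`` or ``"TPM"`` (free-form tags are allowed but these two
        drive pipeline behaviour).
    lengths:
        Optional per-gene transcript length in base pairs, index-aligned with
        ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    units: str = "counts"
    lengths: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples lacking annotation: {missing}")
        if "stage" not in self.samples.columns:
            raise ValueError("sample annotation must have a 'stage' column")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.values.index)
            if self.lengths.isna().any():
                missing = self.lengths.index[self.lengths.isna()].tolist()
                raise ValueError(f"genes lacking length: {missing}")
            if (self.lengths <= 0).any():
                raise ValueError("gene lengths must be strictly positive")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def stages(self) -> list[str]:
        """Distinct stage labels in annotation order of first appearance."""
        seen: list[str] = []
        for s in self.samples.loc[list(self.values.columns), "stage"]:
            if s not in seen:
                seen.append(s)
        return seen

    def stage_columns(self, stage: str) -> list[str]:
        ann = self.samples.loc[list(self.values.columns)]
        cols = list(ann.index[ann["stage"] == stage])
        if not cols:
            raise KeyError(f"unknown stage label: {stage!r}")
        return cols

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to the given genes, preserving current row order."""
        keep = [g for g in self.values.index if g in set(genes)]
        lengths = self.lengths.loc[keep] if self.lengths is not None else None
        return ExpressionMatrix(self.values.loc[keep], self.samples, self.units, lengths)

    # -- I/O -------------------------------------------------------------------

    def to_tsv(self, values_path, annotation_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        ann = self.samples.copy()
        ann.index.name = "sample"
        ann.to_csv(annotation_path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path, annotation_path, units: str = "counts",
                 lengths_path=None) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        samples = pd.read_csv(annotation_path, sep="\t", index_col=0)
        lengths = None
        if lengths_path is not None and Path(lengths_path).exists():
            lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(values, samples, units=units, lengths=lengths)
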