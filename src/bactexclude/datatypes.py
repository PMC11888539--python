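"""Core in-memory containers shared across the pipeline stages.

Matrices are oriented genes-as-rows throughout (rows = gene ids, columns =
sample ids); orientation is validated at construction because transposed
expression matrices are a classic silent-corruption source.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CLASSES = ("V", "B", "VB", "NI")
#: classes counted as "any bacterial" for the binary outcome
BACTERIAL_CLASSES = ("B", "VB")


class PipelineError(ValueError):
    """Raised on invalid inputs or configurations anywhere in the pipeline."""


@dataclass
class CountMatrix:
    """Integer gene-by-sample count matrix.

    Parameters
    ----------
    counts
        DataFrame with gene ids as the index and sample ids as columns;
        entries must be non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.counts.index, self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise PipelineError(f"duplicate gene ids: {dup[:5]}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise PipelineError(f"duplicate sample ids: {dup[:5]}")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise PipelineError("counts must be non-negative")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                bad = np.argwhere(vals != np.round(vals))[0]
                raise PipelineError(
                    f"non-integer count at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def libsize(self) -> pd.Series:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset(self, genes=None, samples=None) -> "CountMatrix":
        df = self.counts
        if genes is not None:
            df = df.loc[genes]
        if samples is not None:
            df = df[samples]
        return CountMatrix(df)


@dataclass
class ExpressionMatrix:
    """Normalized expression, either CPM or log2(CPM+1), tagged with its scale."""

    values: pd.DataFrame
    scale: str  # "cpm" | "log2cpm"

    def __post_init__(self) -> None:
        if self.scale not in ("cpm", "log2cpm"):
            raise PipelineError(f"unknown scale tag {self.scale!r}")
        if self.scale == "cpm" and (self.values.to_numpy() < 0).any():
            raise PipelineError("negative values on cpm scale")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def require_scale(self, scale: str) -> None:
        if self.scale != scale:
            raise PipelineError(
                f"expected expression on {scale!r} scale, got {self.scale!r}"
            )


@dataclass
class SampleAnnotation:
    """Per-sample batch label and outcome class (V, B, VB or NI).

    The binary outcome used throughout is any-bacterial (B or VB) versus
    nonbacterial (V); non-infected controls (NI) are held aside from
    modeling and scored separately.
    """

    table: pd.DataFrame  # index = sample id, columns: batch, class

    def __post_init__(self) -> None:
        missing = {"batch", "class"} - set(self.table.columns)
        if missing:
            raise PipelineError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise PipelineError("duplicate sample ids in annotation")
        bad = set(self.table["class"]) - set(CLASSES)
        if bad:
            raise PipelineError(f"unknown outcome classes: {sorted(bad)}")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    @property
    def batch(self) -> pd.Series:
        return self.table["batch"]

    @property
    def outcome_class(self) -> pd.Series:
        return self.table["class"]

    def ari_samples(self) -> pd.Index:
        """Samples with an acute respiratory infection (everything but NI)."""
        return self.table.index[self.table["class"] != "NI"]

    def binary_labels(self, samples: Sequence | None = None) -> pd.Series:
        """1 = any bacterial (B or VB), 0 = nonbacterial (V); NI excluded."""
        sub = self.table if samples is None else self.table.loc[samples]
        sub = sub[sub["class"] != "NI"]
        return sub["class"].isin(BACTERIAL_CLASSES).astype(int)

    def subset(self, samples) -> "SampleAnnotation":
        return SampleAnnotation(self.table.loc[samples])


@dataclass
class FilterReport:
    """Bookkeeping for the QC cascade; removals reconcile with retentions."""

    genes_removed_mean_cpm: list[str] = field(default_factory=list)
    samples_removed_pca: list[str] = field(default_factory=list)
    genes_removed_batch_variance: list[str] = field(default_factory=list)
    genes_retained: list[str] = field(default_factory=list)
    samples_retained: list[str] = field(default_factory=list)
    n_genes_in: int = 0
    n_samples_in: int = 0

    def validate(self) -> None:
        removed_g = set(self.genes_removed_mean_cpm) | set(
            self.genes_removed_batch_variance
        )
        if removed_g & set(self.genes_retained):
            raise PipelineError("filter report: gene removed and retained")
        if len(removed_g) + len(self.genes_retained) != self.n_genes_in:
            raise PipelineError("filter report: gene counts do not reconcile")
        if set(self.samples_removed_pca) & set(self.samples_retained):
            raise PipelineError("filter report: sample removed and retained")
        if len(self.samples_removed_pca) + len(self.samples_retained) != self.n_samples_in:
            raise PipelineError("filter report: sample counts do not reconcile")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
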