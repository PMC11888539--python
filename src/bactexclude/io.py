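"""Reading and writing the pipeline's on-disk formats.

Count matrices travel as gene-by-sample TSV (gene ids in the first column,
sample ids in the header) or MatrixMarket triplets with plain-text row and
column name sidecars; annotations as CSV; models and reports as JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import CountMatrix, PipelineError, SampleAnnotation


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix from TSV or MatrixMarket (by extension).

    ``.mtx`` files need ``<stem>.rownames.txt`` and ``<stem>.colnames.txt``
    sidecars (one id per line). Validation (duplicates, non-integer or
    negative entries) happens in :class:`CountMatrix`.
    """
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"counts file not found: {path}")
    if path.suffix == ".mtx":
        rows = _read_names(path.with_suffix(".rownames.txt"))
        cols = _read_names(path.with_suffix(".colnames.txt"))
        mat = spio.mmread(path)
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        if dense.shape != (len(rows), len(cols)):
            raise PipelineError(
                f"{path}: matrix shape {dense.shape} does not match sidecars "
                f"({len(rows)} genes, {len(cols)} samples)"
            )
        df = pd.DataFrame(dense, index=rows, columns=cols)
    else:
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - passthrough context
            raise PipelineError(f"malformed counts file {path}: {exc}") from exc
        bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
        if len(bad):
            for col in bad:
                vals = pd.to_numeric(df[col], errors="coerce")
                line = int(np.argmax(vals.isna().to_numpy())) + 2  # header + 1-based
                raise PipelineError(
                    f"{path}: non-numeric count in column {col!r} near line {line}"
                )
    return CountMatrix(df)


def _read_names(path: Path) -> list[str]:
    if not path.exists():
        raise PipelineError(f"MatrixMarket sidecar not found: {path}")
    return path.read_text().splitlines()


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def write_counts_mtx(cm: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix != ".mtx":
        raise PipelineError("MatrixMarket path must end in .mtx")
    spio.mmwrite(str(path), sparse.coo_matrix(cm.counts.to_numpy()))
    path.with_suffix(".rownames.txt").write_text("\n".join(cm.genes) + "\n")
    path.with_suffix(".colnames.txt").write_text("\n".join(cm.samples) + "\n")


def read_annotation(path: str | Path) -> SampleAnnotation:
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"annotation file not found: {path}")
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise PipelineError(f"{path}: annotation needs a sample_id column")
    return SampleAnnotation(df.set_index("sample_id"))


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, index_label="sample_id")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
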