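"""Reading and writing matrices as dense TSV or sparse Matrix Market files.

TSV dialect: tab-separated, UTF-8, "." decimal; the first row holds column
identifiers and the first column holds row identifiers.  Matrix Market files
carry the values only, with row/column identifiers in plain-text sidecar
files ``<stem>.rows.txt`` / ``<stem>.cols.txt`` (one id per line).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    AssociationData,
    FeatureMatrix,
    SimilarityMatrix,
    ValidationError,
)

__all__ = [
    "MatrixFormatError",
    "read_table",
    "write_table",
    "read_feature_matrix",
    "read_association_data",
    "read_similarity_matrix",
    "write_matrix",
]


class MatrixFormatError(ValueError):
    """A matrix file could not be parsed."""


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.rows.txt"), Path(f"{stem}.cols.txt")


def _read_ids(path: Path) -> list[str]:
    if not path.exists():
        raise MatrixFormatError(f"missing identifier sidecar: {path}")
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.rstrip("\n")]


def _write_ids(path: Path, ids: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_table(path, fmt: str | None = None) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labelled matrix; returns (values, row_ids, col_ids).

    ``fmt`` is ``"tsv"`` or ``"mtx"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        try:
            df = pd.read_csv(
                path, sep="\t", index_col=0, header=0, float_precision="round_trip"
            )
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
        return values, [str(i) for i in df.index], [str(c) for c in df.columns]
    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
        values = np.asarray(sp.coo_matrix(mat).todense(), dtype=float)
        rows_p, cols_p = _sidecar_paths(path)
        row_ids, col_ids = _read_ids(rows_p), _read_ids(cols_p)
        if values.shape != (len(row_ids), len(col_ids)):
            raise MatrixFormatError(
                f"{path}: shape {values.shape} does not match sidecar ids "
                f"({len(row_ids)} x {len(col_ids)})"
            )
        return values, row_ids, col_ids
    raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'mtx'")


def write_table(values, row_ids, col_ids, path, fmt: str | None = None) -> None:
    """Write a labelled matrix losslessly (full decimal precision)."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.shape != (len(row_ids), len(col_ids)):
        raise ValidationError("values shape inconsistent with ids")
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        df = pd.DataFrame(values, index=list(row_ids), columns=list(col_ids))
        df.to_csv(path, sep="\t")  # default float repr round-trips exactly
    elif fmt == "mtx":
        scipy.io.mmwrite(path, sp.coo_matrix(values), precision=17)
        rows_p, cols_p = _sidecar_paths(path)
        _write_ids(rows_p, list(row_ids))
        _write_ids(cols_p, list(col_ids))
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'mtx'")


def read_feature_matrix(path, view_id: int, fmt: str | None = None) -> FeatureMatrix:
    """Load a (features x drugs) feature view and validate its invariants."""
    values, row_ids, col_ids = read_table(path, fmt)
    return FeatureMatrix(
        values=values, view_id=view_id, feature_ids=row_ids, drug_ids=col_ids
    )


def read_association_data(path, fmt: str | None = None) -> AssociationData:
    """Load a (drugs x diseases) binary association matrix."""
    values, row_ids, col_ids = read_table(path, fmt)
    return AssociationData(Y=values, drug_ids=row_ids, disease_ids=col_ids)


def read_similarity_matrix(path, kind: str = "drug", fmt: str | None = None) -> SimilarityMatrix:
    """Load a square symmetric similarity matrix."""
    values, row_ids, col_ids = read_table(path, fmt)
    if row_ids != col_ids:
        raise ValidationError("similarity matrix row and column ids must match")
    return SimilarityMatrix(values=values, entity_ids=row_ids, kind=kind)


def write_matrix(m, path, fmt: str | None = None) -> None:
    """Write any typed matrix; readable back by the matching reader."""
    if isinstance(m, FeatureMatrix):
        write_table(m.values, m.feature_ids, m.drug_ids, path, fmt)
    elif isinstance(m, AssociationData):
        write_table(m.Y, m.drug_ids, m.disease_ids, path, fmt)
    elif isinstance(m, SimilarityMatrix):
        write_table(m.values, m.entity_ids, m.entity_ids, path, fmt)
    else:
        raise TypeError(f"cannot write object of type {type(m).__name__}")
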