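"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV (first column literally named ``gene``,
remaining columns sample ids, '.' decimal, UTF-8).  Every expression writer
emits a JSON sidecar (``<path>.meta.json``) recording the scale and
standardization flags so a matrix read back knows what it is.  Sample
metadata is CSV; gene panels are one-symbol-per-line text with ``#``
comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import ExpressionMatrix, validate_metadata


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_expression_tsv(matrix: ExpressionMatrix, path, float_format: str | None = None) -> None:
    """Write an expression matrix as TSV plus a JSON sidecar with its flags.

    With the default ``float_format=None`` values are written at full repr
    precision so a write -> read round-trip is bit-identical.
    """
    path = Path(path)
    df = matrix.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=float_format or "%.17g")
    _sidecar_path(path).write_text(json.dumps(
        {"scale": matrix.scale, "standardized": matrix.standardized}, indent=0))


def read_expression_tsv(path, scale: str | None = None,
                        standardized: bool | None = None,
                        impute_missing: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    Scale flags default to the JSON sidecar written by
    :func:`write_expression_tsv` when present, else ``linear``/False;
    explicit arguments override.  Missing values are rejected unless
    ``impute_missing`` enables per-gene median imputation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.name != "gene":
        raise ValidationError(
            f"{path}: first column must be named 'gene', got {df.index.name!r}")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate gene ids: {dup}")
    for j, col in enumerate(df.columns):
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if not bad.any():
                df[col] = coerced
                continue
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"{path}: non-numeric cell at gene {row!r}, column {col!r} (column {j + 2})")
    if df.isna().any().any():
        if not impute_missing:
            n_missing = int(df.isna().to_numpy().sum())
            raise ValidationError(
                f"{path}: {n_missing} missing values (pass impute_missing=True "
                "for per-gene median imputation)")
        med = df.median(axis=1)
        df = df.apply(lambda row: row.fillna(med[row.name]), axis=1)
    side = _sidecar_path(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    if scale is None:
        scale = meta.get("scale", "linear")
    if standardized is None:
        standardized = bool(meta.get("standardized", False))
    return ExpressionMatrix.from_frame(df, scale=scale, standardized=standardized)


def read_metadata_csv(path) -> pd.DataFrame:
    """Read and validate a sample metadata CSV (see :func:`validate_metadata`)."""
    df = pd.read_csv(path)
    return validate_metadata(df)


def write_metadata_csv(metadata: pd.DataFrame, path) -> None:
    validate_metadata(metadata).to_csv(path, index=False)


def read_gene_list(path) -> list[str]:
    """Read an ordered gene panel: one symbol per line, '#' comments allowed."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            genes.append(token)
    return genes


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")
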