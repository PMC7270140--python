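"""Core containers: expression matrices and sample metadata.

Expression data travels through the pipeline as an :class:`ExpressionMatrix`
(genes x samples) carrying two provenance flags -- ``scale`` (``"linear"`` or
``"log2"``) and ``standardized`` -- because downstream stages care about both:
co-expression analysis expects log2/standardized values while reference-based
deconvolution expects linear-scale values.

Sample metadata is a plain :class:`pandas.DataFrame` with the columns
``sample_id, study, location, grade, age, sex``, validated by
:func:`validate_metadata`.  ``location`` is the binary phenotype under test
(skull-base vs convexity meningioma) and is never allowed to be missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Allowed anatomical locations (the phenotype under test).
LOCATIONS = ("convexity", "skull_base")

#: Allowed WHO grades.
GRADES = (1, 2, 3)

#: Allowed sex codes.
SEXES = ("M", "F")

METADATA_COLUMNS = ("sample_id", "study", "location", "grade", "age", "sex")


def _check_unique(ids, what: str) -> None:
    seen: dict = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValidationError(f"duplicate {what} identifiers: {dups}")


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric expression matrix with scale flags.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))`` with no
        missing entries.
    scale
        ``"linear"`` or ``"log2"``.
    standardized
        Whether the matrix has been globally z-scored.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "linear"
    standardized: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale flag: {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains missing/non-finite entries")
        if self.scale == "linear" and not self.standardized and self.values.size:
            if self.values.min() < 0:
                raise ValidationError("linear-scale unstandardized values must be >= 0")

    # -- convenience ------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str = "linear",
                   standardized: bool = False) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float),
                   scale=scale, standardized=standardized)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return replace(self, gene_ids=list(genes), values=self.values[rows, :])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return replace(self, sample_ids=list(samples), values=self.values[:, cols])

    def copy(self) -> "ExpressionMatrix":
        return replace(self, values=self.values.copy())


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and coerce column dtypes.

    Required columns: ``sample_id, study, location, grade, age, sex``.
    ``location`` must be one of ``convexity``/``skull_base``; ``grade`` one of
    1/2/3.  Raises :class:`ValidationError` naming the offending row.
    """
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    df = df.loc[:, list(METADATA_COLUMNS)].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    _check_unique(df["sample_id"], "sample")
    for i, row in df.iterrows():
        if pd.isna(row["location"]) or row["location"] not in LOCATIONS:
            raise ValidationError(
                f"row {i} (sample {row['sample_id']}): unknown location "
                f"{row['location']!r}; expected one of {LOCATIONS}"
            )
        if int(row["grade"]) not in GRADES:
            raise ValidationError(
                f"row {i} (sample {row['sample_id']}): WHO grade must be in {GRADES}, "
                f"got {row['grade']!r}"
            )
        if row["sex"] not in SEXES:
            raise ValidationError(
                f"row {i} (sample {row['sample_id']}): sex must be in {SEXES}, "
                f"got {row['sex']!r}"
            )
    df["grade"] = df["grade"].astype(int)
    df["age"] = df["age"].astype(float)
    return df.reset_index(drop=True)


def check_metadata_covers(matrix: ExpressionMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Return metadata rows aligned to the matrix sample order; error if any missing."""
    meta = metadata.set_index("sample_id")
    absent = [s for s in matrix.sample_ids if s not in meta.index]
    if absent:
        raise ValidationError(f"samples without metadata: {absent}")
    return meta.loc[matrix.sample_ids].reset_index()
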