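"""Reference-based immune cell deconvolution of bulk expression.

Bulk tumour expression is modelled per sample as a non-negative mixture of
cell-type reference profiles (an LM22-format signature matrix, genes x 22
immune cell types).  Two engines solve the per-sample regression over the
genes shared between mixture and signature:

* ``nnls`` (default): non-negative least squares -- deterministic and exact
  for noiseless mixtures;
* ``nusvr``: linear nu-support-vector regression over nu in {0.25, 0.5,
  0.75}, keeping the fit with the lowest residual RMSE and clamping
  negative coefficients to zero (the CIBERSORT recipe).

Both engines normalize coefficients to the simplex (relative fractions).
Following the CIBERSORT convention, each mixture column is z-scored over
the shared genes and the signature is z-scored as a whole matrix, and the
regression includes an intercept, so affine offsets between the two scales
do not bias the fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .errors import DegenerateInputError, ValidationError
from .preprocess import global_scale, unlog2_transform
from .types import ExpressionMatrix, _check_unique

MIN_SHARED_GENES = 50


@dataclass
class SignatureMatrix:
    """Non-negative reference profiles: genes x cell types, full column rank."""

    gene_ids: list[str]
    cell_type_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_type_names = [str(c) for c in self.cell_type_names]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_type_names, "cell type")
        if self.values.shape != (len(self.gene_ids), len(self.cell_type_names)):
            raise ValidationError("signature shape does not match ids")
        if self.values.min() < 0:
            raise ValidationError("signature matrix must be non-negative")
        if np.linalg.matrix_rank(self.values) < len(self.cell_type_names):
            raise ValidationError("signature matrix is rank deficient")

    @property
    def K(self) -> int:
        return len(self.cell_type_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.cell_type_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class CellFractions:
    """Simplex-constrained deconvolution output with per-sample diagnostics."""

    sample_ids: list[str]
    cell_type_names: list[str]
    values: np.ndarray                       # samples x K, rows sum to 1
    diagnostics: pd.DataFrame                # per-sample rmse (+ nu for SVR)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < -1e-12:
            raise ValidationError("cell fractions must be non-negative")
        sums = self.values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError("cell fraction rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.cell_type_names)


def load_signature_tsv(path) -> SignatureMatrix:
    """Read an LM22-format signature TSV (first column = gene symbol)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({c for c in header if header.count(c) > 1})
        raise ValidationError(f"{path}: duplicate cell type columns: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"{path}: signature contains missing values")
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: signature contains negative entries")
    return SignatureMatrix.from_frame(df)


def prepare_mixture(matrix: ExpressionMatrix, log2_offset: float = 1.0,
                    scale: bool = True) -> ExpressionMatrix:
    """Put a bulk matrix on the scale the deconvolution expects: linear
    (un-logged if flagged log2) and, by default, globally z-scored."""
    if matrix.scale == "log2":
        matrix = unlog2_transform(matrix, offset=log2_offset)
    elif matrix.scale != "linear":
        raise ValidationError(f"unknown scale flag {matrix.scale!r}")
    if scale:
        matrix = global_scale(matrix)
    return matrix


def _fit_nnls(S: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    # free intercept (via +/- columns) absorbs the affine offset between the
    # two z-scored scales -- unless the signature has (near-)constant row
    # sums, in which case the intercept makes fractions unidentifiable up to
    # an additive constant and is dropped
    ones = np.ones((S.shape[0], 1))
    aug = np.hstack([S, ones, -ones])
    sv = np.linalg.svd(np.hstack([S, ones]), compute_uv=False)
    if sv[-1] < 1e-8 * sv[0]:
        aug = S
    coef, _ = _scipy_nnls(aug, y)
    f = coef[: S.shape[1]]
    resid = aug @ coef - y
    return f, float(np.sqrt(np.mean(resid ** 2)))


def _fit_nusvr(S: np.ndarray, y: np.ndarray, nus=(0.25, 0.5, 0.75)
               ) -> tuple[np.ndarray, float, float]:
    from sklearn.svm import NuSVR

    best = None
    for nu in nus:
        svr = NuSVR(kernel="linear", nu=nu, C=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svr.fit(S, y)
        coef = svr.coef_.ravel()
        resid = S @ coef + svr.intercept_ - y
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        if best is None or rmse < best[1]:
            best = (np.clip(coef, 0.0, None), rmse, nu)
    return best


def estimate_fractions(mixture: ExpressionMatrix, signature: SignatureMatrix,
                       engine: str = "nnls") -> CellFractions:
    """Estimate relative cell-type fractions for every mixture sample.

    Raises
    ------
    ValidationError
        Fewer than 50 genes shared between mixture and signature, or an
        unknown engine.
    """
    if engine not in ("nnls", "nusvr"):
        raise ValidationError(f"unknown engine {engine!r}")
    shared = sorted(set(mixture.gene_ids) & set(signature.gene_ids))
    if len(shared) < MIN_SHARED_GENES:
        raise ValidationError(
            f"only {len(shared)} genes shared between mixture and signature "
            f"(need >= {MIN_SHARED_GENES})")
    mix = mixture.subset_genes(shared).values
    sig = signature.to_frame().loc[shared].to_numpy()
    # CIBERSORT-style standardization over the shared genes
    sig_z = (sig - sig.mean()) / sig.std()
    rows = []
    fracs = np.empty((mixture.n_samples, signature.K))
    for j in range(mixture.n_samples):
        y = mix[:, j]
        sd = y.std()
        if sd == 0:
            raise DegenerateInputError(
                f"mixture sample {mixture.sample_ids[j]!r} is constant")
        y_z = (y - y.mean()) / sd
        if engine == "nnls":
            f, rmse = _fit_nnls(sig_z, y_z)
            rows.append({"sample_id": mixture.sample_ids[j], "rmse": rmse})
        else:
            f, rmse, nu = _fit_nusvr(sig_z, y_z)
            rows.append({"sample_id": mixture.sample_ids[j], "rmse": rmse, "nu": nu})
        total = f.sum()
        if total <= 0:
            warnings.warn(
                f"all-zero coefficient vector for sample {mixture.sample_ids[j]!r}; "
                "returning uniform fractions")
            f = np.full(signature.K, 1.0 / signature.K)
        else:
            f = f / total
        fracs[j] = f
    return CellFractions(list(mixture.sample_ids), list(signature.cell_type_names),
                         fracs, pd.DataFrame(rows).set_index("sample_id"))
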