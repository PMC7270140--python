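"""Cross-study preprocessing: quantile normalization, log2 transform,
gene-intersection merge, global scaling, and parametric empirical-Bayes
batch correction.

The full per-study chain mirrors standard multi-study microarray practice:
each study is quantile-normalized and log2-transformed, studies are merged
over their common genes, each study is scaled to pooled mean 0 / SD 1, and
the merged matrix is batch-corrected with the parametric empirical-Bayes
location/scale model of Johnson, Li & Rabinovic (ComBat).  Scaling is done
per study (not pooled) by default: pooled scaling would leave in place the
between-study location/scale structure the batch correction is meant to
shrink, whereas per-study scaling removes the gross component and lets the
empirical-Bayes step handle the per-gene residual.  Pooled scaling remains
available via ``global_scale`` on the merged matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError
from .types import ExpressionMatrix


@dataclass
class MergeReport:
    """Bookkeeping from a cross-study merge."""

    per_study_gene_counts: dict[str, int]
    intersected_gene_count: int
    dropped_genes: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "per_study_gene_counts": self.per_study_gene_counts,
            "intersected_gene_count": self.intersected_gene_count,
            "dropped_genes": self.dropped_genes,
        }


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common reference distribution.

    The reference is the across-sample mean of per-column sorted values.
    Ties within a column receive the mean of their reference quantiles
    (midrank rule).  After normalization all columns have identical sorted
    value vectors.
    """
    if matrix.n_samples < 2:
        raise DegenerateInputError("quantile normalization needs >= 2 samples")
    X = matrix.values
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        ranks = sps.rankdata(col, method="average")  # midranks, 1-based
        # interpolate reference at fractional midranks so tied entries get
        # the mean of the reference values their rank range spans
        out[:, j] = np.interp(ranks, np.arange(1, len(col) + 1), reference)
    return replace(matrix, values=out)


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """``value <- log2(value + offset)``; flips the scale flag to log2."""
    if matrix.scale != "linear":
        raise ValidationError("log2_transform expects a linear-scale matrix")
    if matrix.values.min() < 0:
        raise ValidationError("negative values cannot be log-transformed")
    return replace(matrix, values=np.log2(matrix.values + offset), scale="log2")


def unlog2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Inverse of :func:`log2_transform`."""
    if matrix.scale != "log2":
        raise ValidationError("unlog2_transform expects a log2-scale matrix")
    return replace(matrix, values=np.exp2(matrix.values) - offset, scale="linear")


def intersect_and_merge(matrices: list[ExpressionMatrix],
                        study_names: list[str] | None = None
                        ) -> tuple[ExpressionMatrix, MergeReport]:
    """Merge studies over the intersection of their gene sets.

    Genes are ordered canonically (sorted); sample columns are concatenated
    in study order.  Studies must have disjoint sample ids.
    """
    if len(matrices) < 2:
        raise ValidationError("need >= 2 studies to merge")
    if study_names is None:
        study_names = [f"study{i + 1}" for i in range(len(matrices))]
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.sample_ids)
    if len(set(all_samples)) != len(all_samples):
        dup = sorted({s for s in all_samples if all_samples.count(s) > 1})
        raise ValidationError(f"sample ids duplicated across studies: {dup}")
    gene_sets = [set(m.gene_ids) for m in matrices]
    common = set.intersection(*gene_sets)
    if not common:
        raise ValidationError("empty gene intersection across studies")
    genes = sorted(common)
    merged = np.concatenate(
        [m.subset_genes(genes).values for m in matrices], axis=1)
    scales = {m.scale for m in matrices}
    if len(scales) != 1:
        raise ValidationError(f"cannot merge matrices with mixed scales: {scales}")
    report = MergeReport(
        per_study_gene_counts={n: m.n_genes for n, m in zip(study_names, matrices)},
        intersected_gene_count=len(genes),
        dropped_genes={n: sorted(set(m.gene_ids) - common)
                       for n, m in zip(study_names, matrices)},
    )
    out = ExpressionMatrix(genes, all_samples, merged, scale=scales.pop(),
                           standardized=all(m.standardized for m in matrices))
    return out, report


def global_scale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale the full matrix (all entries pooled) to mean 0 and population SD 1."""
    X = matrix.values
    sd = X.std()  # population sd (ddof=0)
    if sd == 0:
        raise DegenerateInputError("constant matrix cannot be scaled")
    return replace(matrix, values=(X - X.mean()) / sd, standardized=True)


def per_study_scale(matrix: ExpressionMatrix, study_labels) -> ExpressionMatrix:
    """Apply :func:`global_scale` separately to each study's sample block."""
    study_labels = np.asarray(study_labels)
    if study_labels.size != matrix.n_samples:
        raise ValidationError("one study label per sample required")
    X = matrix.values.copy()
    for b in np.unique(study_labels):
        cols = study_labels == b
        block = X[:, cols]
        sd = block.std()
        if sd == 0:
            raise DegenerateInputError(f"study {b!r} block is constant")
        X[:, cols] = (block - block.mean()) / sd
    return replace(matrix, values=X, standardized=True)


# ---------------------------------------------------------------------------
# parametric empirical-Bayes batch correction (ComBat)
# ---------------------------------------------------------------------------

def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _it_sol(Z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-4, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Iterative joint EB solution for batch location (gamma*) and scale
    (delta2*) per gene, as in the parametric ComBat algorithm."""
    n = Z.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((Z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(np.abs(g_new - g_old).max() / np.abs(g_old).max()
                     if np.abs(g_old).max() > 0 else 0.0,
                     np.abs(d_new - d_old).max() / d_old.max())
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat(matrix: ExpressionMatrix, batch_labels, parametric: bool = True
           ) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per gene, the data are standardized by the grand mean and pooled
    variance; per-batch location (gamma) and scale (delta^2) estimates are
    shrunk toward batch-wide priors (normal on gamma, inverse-gamma on
    delta^2, hyperparameters by method of moments) via the iterative joint
    solution; the adjusted values are back-transformed.  No covariate design
    is modelled.

    Raises
    ------
    ValidationError
        Fewer than 2 batches, a batch with a single sample, or a gene with
        zero variance (which would break standardization).
    NotImplementedError
        ``parametric=False`` (non-parametric priors are not provided).
    """
    if not parametric:
        raise NotImplementedError("non-parametric empirical Bayes mode is not supported")
    batch_labels = np.asarray(batch_labels)
    if batch_labels.size != matrix.n_samples:
        raise ValidationError("one batch label per sample required")
    batches = list(pd.unique(batch_labels))
    if len(batches) < 2:
        # nothing to correct
        return matrix.copy()
    sizes = {b: int((batch_labels == b).sum()) for b in batches}
    small = [b for b, n in sizes.items() if n < 2]
    if small:
        raise ValidationError(f"batches with a single sample cannot be corrected: {small}")
    X = matrix.values
    n_genes, n_samples = X.shape
    gene_var = X.var(axis=1)
    if np.any(gene_var == 0):
        bad = [matrix.gene_ids[i] for i in np.nonzero(gene_var == 0)[0][:5]]
        raise ValidationError(f"zero-variance genes (first few): {bad}")

    masks = {b: batch_labels == b for b in batches}
    n_b = np.array([sizes[b] for b in batches], dtype=float)
    batch_means = np.stack([X[:, masks[b]].mean(axis=1) for b in batches])  # B x G
    # grand mean = sample-size-weighted batch means; pooled variance of the
    # residual after removing batch means
    grand_mean = (n_b[:, None] * batch_means).sum(axis=0) / n_samples
    resid = X.copy()
    for i, b in enumerate(batches):
        resid[:, masks[b]] -= batch_means[i][:, None]
    var_pooled = (resid ** 2).sum(axis=1) / n_samples
    if np.any(var_pooled == 0):
        raise ValidationError("pooled residual variance is zero for some gene")
    Z = (X - grand_mean[:, None]) / np.sqrt(var_pooled)[:, None]

    adjusted = Z.copy()
    for i, b in enumerate(batches):
        Zb = Z[:, masks[b]]
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)
        g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        a, bp = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(Zb, g_hat, d_hat, g_bar, t2, a, bp)
        adjusted[:, masks[b]] = (Zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = adjusted * np.sqrt(var_pooled)[:, None] + grand_mean[:, None]
    return replace(matrix, values=out)


def preprocess_studies(matrices: list[ExpressionMatrix],
                       study_names: list[str] | None = None,
                       log2_offset: float = 1.0,
                       scale_per_study: bool = True,
                       run_combat: bool = True
                       ) -> tuple[ExpressionMatrix, MergeReport]:
    """Full chain: per-study (quantile normalize -> log2) -> merge over common
    genes -> scaling -> optional batch correction.  Returns the analysis-ready
    matrix and the merge report."""
    if study_names is None:
        study_names = [f"study{i + 1}" for i in range(len(matrices))]
    normed = [log2_transform(quantile_normalize(m), offset=log2_offset)
              for m in matrices]
    merged, report = intersect_and_merge(normed, study_names)
    labels = np.concatenate([[n] * m.n_samples
                             for n, m in zip(study_names, matrices)])
    if scale_per_study:
        merged = per_study_scale(merged, labels)
    else:
        merged = global_scale(merged)
    if run_combat:
        merged = combat(merged, labels)
    return merged, report
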