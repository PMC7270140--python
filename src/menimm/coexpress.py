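"""Weighted gene co-expression network analysis.

The standard WGCNA recipe: pairwise gene correlations are soft-thresholded
(``|cor|^beta``, default beta = 20) into a weighted adjacency, transformed
into the topological overlap matrix (TOM) that scores gene pairs by shared
network neighbourhood, clustered by average linkage on ``1 - TOM``, and cut
into modules with a minimum size of 30 genes.  Each module is summarized by
its meta-gene (module eigengene, the first principal component across
samples), which is then tested against tumour location with a Mann-Whitney
test and a covariate-adjusted logistic model, labelled with correlated
cytokines, and used to build a top-gene logistic location classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DegenerateInputError, ValidationError
from .stats import mann_whitney_u, pearson_with_p
from .types import ExpressionMatrix, check_metadata_covers


@dataclass
class NetworkConfig:
    """Co-expression network parameters."""

    power: float = 20.0
    network_type: str = "unsigned"  # or "signed"
    min_module_size: int = 30
    #: dendrogram cut height as a fraction of the maximum merge height;
    #: ``None`` uses the adaptive default of 0.99
    cut_height_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValidationError("soft-threshold power must be >= 1")
        if self.network_type not in ("unsigned", "signed"):
            raise ValidationError(f"unknown network type {self.network_type!r}")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")


def _gene_correlations(matrix: ExpressionMatrix, block_size: int = 2000) -> np.ndarray:
    """Gene x gene Pearson correlation, computed in row blocks to bound the
    intermediate memory; block size never changes the result."""
    X = matrix.values
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = [matrix.gene_ids[i] for i in np.nonzero(sd == 0)[0][:5]]
        raise DegenerateInputError(f"constant gene rows (first few): {bad}")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    n = X.shape[1]
    G = X.shape[0]
    C = np.empty((G, G))
    for start in range(0, G, block_size):
        stop = min(start + block_size, G)
        C[start:stop] = Z[start:stop] @ Z.T / n
    np.clip(C, -1.0, 1.0, out=C)
    return C


def soft_adjacency(matrix: ExpressionMatrix, config: NetworkConfig) -> np.ndarray:
    """Soft-thresholded adjacency with zero diagonal.

    Unsigned: ``|cor|^beta``; signed: ``((1 + cor) / 2)^beta``.
    """
    C = _gene_correlations(matrix)
    if config.network_type == "unsigned":
        A = np.abs(C) ** config.power
    else:
        A = ((1.0 + C) / 2.0) ** config.power
    np.fill_diagonal(A, 0.0)
    return A


def pick_soft_threshold(matrix: ExpressionMatrix, candidate_powers,
                        network_type: str = "unsigned",
                        n_bins: int = 10) -> pd.DataFrame:
    """Scale-free topology fit for each candidate power.

    For each power the node connectivities ``k_i`` are binned, the empirical
    log10 p(k) is regressed on log10 k, and the fit R^2 is reported (signed
    negative when the slope is positive, i.e. the topology is anti
    scale-free).  Also reports mean connectivity.
    """
    if matrix.n_genes < 50:
        raise ValidationError("need >= 50 genes for a meaningful scale-free fit")
    C = _gene_correlations(matrix)
    rows = []
    for beta in candidate_powers:
        if network_type == "unsigned":
            A = np.abs(C) ** beta
        else:
            A = ((1.0 + C) / 2.0) ** beta
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=0)
        pos = k[k > 0]
        if pos.size < n_bins:
            rows.append({"power": beta, "sft_r2": 0.0, "mean_k": float(k.mean())})
            continue
        edges = np.linspace(pos.min(), pos.max() + 1e-12, n_bins + 1)
        which = np.clip(np.digitize(pos, edges) - 1, 0, n_bins - 1)
        freq = np.bincount(which, minlength=n_bins).astype(float) / pos.size
        kmean = np.array([pos[which == b].mean() if (which == b).any() else np.nan
                          for b in range(n_bins)])
        ok = (freq > 0) & np.isfinite(kmean) & (kmean > 0)
        if ok.sum() < 3:
            rows.append({"power": beta, "sft_r2": 0.0, "mean_k": float(k.mean())})
            continue
        x, y = np.log10(kmean[ok]), np.log10(freq[ok])
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = ((y - yhat) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        rows.append({"power": beta, "sft_r2": float(-r2 if slope > 0 else r2),
                     "mean_k": float(k.mean())})
    return pd.DataFrame(rows)


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    ``TOM_ij = (sum_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij)`` with
    ``k_i = sum_u A_iu``; ``TOM_ii = 1``.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    if A.min() < 0 or A.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=0)
    numer = A @ A + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(tom: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Average-linkage clustering on ``1 - TOM`` with an adaptive height cut.

    The dendrogram is cut at ``cut_height_fraction`` (default 0.99) of the
    maximum merge height; clusters smaller than ``min_module_size`` are
    relabelled 0 (the grey/background module), the rest renumbered 1..M by
    descending size (ties broken by smallest member index).
    """
    tom = np.asarray(tom, dtype=float)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    frac = 0.99 if config.cut_height_fraction is None else config.cut_height_fraction
    height = frac * link[:, 2].max()
    raw = hierarchy.fcluster(link, t=height, criterion="distance")
    return _relabel_by_size(raw, config.min_module_size)


def _relabel_by_size(raw: np.ndarray, min_size: int) -> np.ndarray:
    labels = np.zeros(raw.shape[0], dtype=int)
    clusters = []
    for c in np.unique(raw):
        members = np.nonzero(raw == c)[0]
        if members.size >= min_size:
            clusters.append((members.size, members[0], members))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for new_id, (_, _, members) in enumerate(clusters, start=1):
        labels[members] = new_id
    return labels


def module_eigengene(matrix: ExpressionMatrix, labels: np.ndarray
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module across samples.

    Module genes are row-standardized before the SVD; the meta-gene is the
    first right singular vector (unit Euclidean norm over samples), with its
    sign aligned so it correlates non-negatively with the module's mean
    standardized profile.  Returns (samples x modules meta-gene matrix,
    per-module variance explained).
    """
    labels = np.asarray(labels)
    if labels.size != matrix.n_genes:
        raise ValidationError("one module label per gene required")
    module_ids = sorted(set(labels) - {0})
    metagenes = {}
    varexp = {}
    for m in module_ids:
        rows = matrix.values[labels == m, :]
        sd = rows.std(axis=1)
        if np.any(sd == 0):
            raise DegenerateInputError(f"module {m} contains constant genes")
        Z = (rows - rows.mean(axis=1, keepdims=True)) / sd[:, None]
        if Z.shape[0] == 1:
            warnings.warn(f"module {m} has a single gene; meta-gene is its profile")
            v = Z[0] / np.linalg.norm(Z[0])
            metagenes[m], varexp[m] = v, 1.0
            continue
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        v = Vt[0]
        mean_profile = Z.mean(axis=0)
        if float(v @ mean_profile) < 0:
            v = -v
        metagenes[m] = v
        varexp[m] = float(s[0] ** 2 / (s ** 2).sum())
    mg = pd.DataFrame(metagenes, index=matrix.sample_ids)
    mg.columns = [f"ME{m}" for m in module_ids]
    return mg, pd.Series(varexp, name="variance_explained")


def test_module_location(metagenes: pd.DataFrame, metadata: pd.DataFrame
                         ) -> pd.DataFrame:
    """Per-module location tests.

    ``mann_whitney_p`` compares meta-gene scores between skull-base and
    convexity samples.  ``adjusted_p`` is the Wald p-value of the meta-gene
    coefficient in a logistic regression
    ``location ~ metagene + grade + age + sex`` (grade ordinal numeric, sex
    binary), which absorbs confounding by the clinical covariates.
    """
    import statsmodels.api as sm

    meta = metadata.set_index("sample_id").loc[metagenes.index]
    is_sb = (meta["location"] == "skull_base").to_numpy()
    if is_sb.all() or (~is_sb).all():
        raise DegenerateInputError("both locations must be represented")
    covars = np.column_stack([
        meta["grade"].to_numpy(dtype=float),
        (meta["age"].to_numpy(dtype=float) - meta["age"].mean()) / max(meta["age"].std(), 1e-9),
        (meta["sex"] == "F").to_numpy(dtype=float),
    ])
    rows = []
    for col in metagenes.columns:
        score = metagenes[col].to_numpy()
        _, p_mw = mann_whitney_u(score[is_sb], score[~is_sb])
        X = sm.add_constant(np.column_stack([score, covars]))
        adj_p = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("newton", "bfgs"):
                try:
                    fit = sm.Logit(is_sb.astype(float), X).fit(
                        disp=0, maxiter=500, method=method)
                    adj_p = float(fit.pvalues[1])
                    break
                except Exception:
                    continue  # separation/singular Hessian: try next, else undefined
        rows.append({"module": col, "mann_whitney_p": p_mw, "adjusted_p": adj_p})
    return pd.DataFrame(rows).set_index("module")


def label_cytokines(metagenes: pd.DataFrame, matrix: ExpressionMatrix,
                    panel, rho_min: float = 0.6, alpha: float = 0.05
                    ) -> tuple[dict[str, list[str]], list[str]]:
    """Cytokines positively associated with each meta-gene.

    A panel gene labels a module iff its Pearson correlation with the
    meta-gene exceeds ``rho_min`` with ``p < alpha`` (positive correlations
    only).  Returns (module -> cytokines, panel genes missing from the
    matrix)."""
    gidx = matrix.gene_index()
    missing = [g for g in panel if g not in gidx]
    present = [g for g in panel if g in gidx]
    out: dict[str, list[str]] = {}
    for col in metagenes.columns:
        mg = metagenes[col].to_numpy()
        hits = []
        for g in present:
            expr = matrix.values[gidx[g], :]
            if np.ptp(expr) == 0:
                continue
            res = pearson_with_p(expr, mg)
            if res.rho > rho_min and res.p < alpha:
                hits.append(g)
        out[col] = hits
    return out, missing


def top_module_genes(matrix: ExpressionMatrix, metagene: np.ndarray,
                     module_genes, n: int = 10) -> list[str]:
    """The ``n`` module genes most correlated with the meta-gene (kME),
    descending; ties broken lexicographically by gene id."""
    module_genes = list(module_genes)
    if n > len(module_genes):
        raise ValidationError(f"n={n} exceeds module size {len(module_genes)}")
    gidx = matrix.gene_index()
    kme = []
    for g in module_genes:
        res = pearson_with_p(matrix.values[gidx[g], :], metagene)
        kme.append((-res.rho, g))
    kme.sort()
    return [g for _, g in kme[:n]]


def location_classifier(matrix: ExpressionMatrix, gene_panel, metadata: pd.DataFrame,
                        scheme: str = "in_sample", k: int = 5,
                        seed: int = 0) -> tuple[float, pd.DataFrame]:
    """Logistic regression of location on a gene panel, scored by ROC AUC.

    ``scheme`` is ``in_sample`` (fit and score on all samples) or ``kfold``
    (stratified k-fold out-of-fold predictions).  The fit uses unpenalized
    maximum likelihood; under perfect separation it falls back to an L2
    (ridge) logistic fit rather than failing.  AUC is computed with the
    rank (Mann-Whitney) formula over predicted probabilities.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    meta = check_metadata_covers(matrix, metadata)
    y = (meta["location"] == "skull_base").to_numpy(dtype=int)
    if y.min() == y.max():
        raise DegenerateInputError("both locations must be represented")
    gidx = matrix.gene_index()
    absent = [g for g in gene_panel if g not in gidx]
    if absent:
        raise ValidationError(f"panel genes absent from matrix: {absent}")
    X = matrix.values[[gidx[g] for g in gene_panel], :].T

    def fit_predict(X_tr, y_tr, X_te):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                clf = LogisticRegression(penalty=None, max_iter=500)
                clf.fit(X_tr, y_tr)
                if not np.all(np.isfinite(clf.coef_)) or np.abs(clf.coef_).max() > 1e6:
                    raise FloatingPointError("separation")
            except Exception:
                clf = LogisticRegression(penalty="l2", C=1.0, max_iter=500)
                clf.fit(X_tr, y_tr)
        return clf.predict_proba(X_te)[:, 1]

    if scheme == "in_sample":
        scores = fit_predict(X, y, X)
    elif scheme == "kfold":
        scores = np.empty(y.size)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for tr, te in skf.split(X, y):
            scores[te] = fit_predict(X[tr], y[tr], X[te])
    else:
        raise ValidationError(f"unknown scheme {scheme!r}")
    return roc_auc(y, scores), _roc_points(y, scores)


def roc_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formula with midrank tie handling."""
    from scipy.stats import rankdata

    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _roc_points(y: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
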