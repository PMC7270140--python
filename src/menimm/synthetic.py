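"""Synthetic multi-study meningioma cohorts with planted ground truth.

Real cohorts for this analysis are bulk microarray studies of skull-base and
convexity meningiomas.  The generator emulates their statistical structure so
every pipeline stage can be verified against a known answer:

* **cell fractions** drawn from location-specific Dirichlet distributions
  over 22 LM22-style immune cell types (skull-base tumours enriched for
  gamma-delta T cells, monocytes and plasma cells; convexity tumours for
  activated mast cells and neutrophils);
* a **signature matrix** with disjoint marker blocks per cell type, so
  reference-based deconvolution has a well-posed inverse problem;
* **co-expression modules** driven by per-sample latent factors, one of
  which is shifted between locations (the phenotype-linked module the
  network analysis must find);
* **cell-cytokine couplings**: chosen cytokine genes are linear functions of
  a cell fraction plus noise within one location group, with coefficients
  solved so the population Pearson correlation hits a requested target;
* per-study **batch effects** (affine location/scale distortions) and
  multiplicative log-normal noise, with each study missing a small disjoint
  slice of genes so cross-study intersection is exercised.

Identical configuration + seed reproduces every output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .types import ExpressionMatrix, validate_metadata

#: LM22-style immune cell labels (activated/resting, naive/memory variants).
LM22_CELL_TYPES = (
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory (Tregs)", "T cells gamma delta",
    "NK cells resting", "NK cells activated",
    "Monocytes", "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
)

#: Default 35-gene cytokine/immune-mediator panel.  Configurable; real-data
#: runs should supply the panel actually assayed.
DEFAULT_CYTOKINE_PANEL = (
    "IL6", "IL1R2", "BTK", "CCL3",
    "IL1A", "IL1B", "IL2", "IL4", "IL5", "IL7", "IL10", "IL12A", "IL12B",
    "IL13", "IL15", "IL17A", "IL18", "TNF", "IFNG", "TGFB1",
    "CCL2", "CCL4", "CCL5", "CXCL8", "CXCL9", "CXCL10", "CXCL12",
    "CSF1", "CSF2", "CSF3", "VEGFA", "PDGFB", "FGF2", "HGF", "IL23A",
)

#: Cell types whose Dirichlet concentration is boosted per location,
#: mirroring the enrichment pattern the analysis is meant to recover.
SKULL_BASE_BOOSTED = ("T cells gamma delta", "Monocytes", "Plasma cells")
CONVEXITY_BOOSTED = ("Mast cells activated", "Neutrophils")

#: Default planted cell-cytokine couplings: (cell type, cytokine, location,
#: target Pearson rho).  Convexity couples activated mast cells and
#: neutrophils; skull base couples gamma-delta T cells, plasma cells and
#: monocytes.  The dominant cell of each location carries several partner
#: cytokines: an immunologically active cell type engages a repertoire of
#: mediators, not a single one, and a one-edge cell would be statistically
#: indistinguishable from the spurious significant correlations that a
#: 22 x 35 pair scan produces at alpha = 0.05.
DEFAULT_COUPLINGS = (
    ("Mast cells activated", "IL6", "convexity", 0.70),
    ("Mast cells activated", "IL1A", "convexity", 0.60),
    ("Mast cells activated", "TNF", "convexity", 0.60),
    ("Mast cells activated", "IL1B", "convexity", 0.55),
    ("Mast cells activated", "CCL2", "convexity", 0.55),
    ("Mast cells activated", "CSF1", "convexity", 0.50),
    ("Neutrophils", "IL1R2", "convexity", 0.74),
    ("Neutrophils", "CXCL8", "convexity", 0.55),
    ("T cells gamma delta", "CCL3", "skull_base", 0.70),
    ("T cells gamma delta", "CCL4", "skull_base", 0.60),
    ("T cells gamma delta", "IFNG", "skull_base", 0.60),
    ("T cells gamma delta", "IL2", "skull_base", 0.55),
    ("T cells gamma delta", "IL15", "skull_base", 0.55),
    ("Plasma cells", "BTK", "skull_base", 0.57),
    ("Monocytes", "BTK", "skull_base", 0.54),
)


@dataclass
class SimulationConfig:
    """Everything the cohort generator needs; defaults emulate a 3-study,
    107-sample meningioma meta-cohort (71 skull base)."""

    n_studies: int = 3
    samples_per_study: tuple[int, ...] = (12, 84, 11)
    skull_base_fraction: tuple[float, ...] = (7 / 12, 53 / 84, 1.0)
    n_genes: int = 2000
    n_cell_types: int = 22
    cell_type_names: tuple[str, ...] = LM22_CELL_TYPES
    markers_per_cell_type: int = 10
    module_sizes: tuple[int, ...] = (300, 200, 150, 100)
    #: index into module_sizes of the module whose latent factor is shifted
    location_module_index: int = 0
    #: shift (in latent-factor SD units) added to skull-base samples
    module_location_effect: float = 1.5
    module_loading_range: tuple[float, float] = (0.3, 0.8)
    #: Dirichlet concentration: base for every cell type, boost replaces it
    #: for the location-enriched cell types listed above.
    dirichlet_base_alpha: float = 1.0
    dirichlet_boost_alpha: float = 3.0
    cytokine_panel: tuple[str, ...] = DEFAULT_CYTOKINE_PANEL
    couplings: tuple[tuple[str, str, str, float], ...] = DEFAULT_COUPLINGS
    cytokine_base_level: float = 5.0
    cytokine_noise_sd: float = 0.5
    signature_base_level: float = 1.0
    signature_marker_fold: float = 10.0
    #: multiplicative log-normal jitter on signature entries; real reference
    #: profiles have heterogeneous marker fold changes, and exactly
    #: block-constant signatures are a degenerate special case (constant row
    #: sums) that no real signature exhibits
    signature_jitter_sd: float = 0.3
    module_gene_base_level: float = 5.0
    background_base_level: float = 5.0
    batch_shift_range: tuple[float, float] = (0.0, 0.5)
    batch_scale_range: tuple[float, float] = (0.7, 1.4)
    gene_shift_sd: float = 0.05
    #: fraction of genes each study drops (disjoint across studies)
    gene_drop_rate: float = 0.05
    #: SD of multiplicative log-normal noise (natural-log scale)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies != len(self.samples_per_study):
            raise ValidationError("samples_per_study must have n_studies entries")
        if self.n_studies != len(self.skull_base_fraction):
            raise ValidationError("skull_base_fraction must have n_studies entries")
        if any(n <= 0 for n in self.samples_per_study):
            raise ValidationError("samples_per_study entries must be positive")
        if self.n_cell_types < 2:
            raise ValidationError("need at least 2 cell types")
        if len(self.cell_type_names) < self.n_cell_types:
            raise ValidationError("not enough cell type names for n_cell_types")
        self.cell_type_names = tuple(self.cell_type_names[: self.n_cell_types])
        for _, _, loc, rho in self.couplings:
            if loc not in ("convexity", "skull_base"):
                raise ValidationError(f"coupling location {loc!r} invalid")
            if not (-1.0 < rho < 1.0):
                raise ValidationError(f"coupling target rho {rho} not in (-1, 1)")
        n_structured = (self.n_cell_types * self.markers_per_cell_type
                        + sum(self.module_sizes) + len(self.cytokine_panel))
        if self.n_genes < n_structured:
            raise ValidationError(
                f"n_genes={self.n_genes} too small for {n_structured} structured genes")


@dataclass
class GroundTruth:
    """Planted quantities the analysis should recover."""

    true_fractions: pd.DataFrame          # samples x cell types, rows sum to 1
    signature: pd.DataFrame               # marker genes x cell types
    module_labels: pd.Series              # gene -> module id (0 = background)
    location_module_id: int
    couplings: list[dict]                 # realized coupling parameters
    batch_params: pd.DataFrame            # per-study shift/scale
    cytokine_panel: list[str]


def generate_signature(K: int, markers_per_type: int, base_level: float = 1.0,
                       marker_fold: float = 10.0, seed: int | None = None,
                       cell_type_names: Sequence[str] | None = None,
                       jitter_sd: float = 0.0) -> pd.DataFrame:
    """Block-structured reference signature: genes x K cell types.

    Each cell type owns a disjoint block of ``markers_per_type`` genes
    expressed ``marker_fold`` times above ``base_level`` in that type only.
    Optional multiplicative log-normal jitter roughens the blocks; with
    ``jitter_sd=0`` the matrix is exactly block-constant and full rank.
    """
    if K < 2:
        raise ValidationError("K must be >= 2")
    if markers_per_type < 1:
        raise ValidationError("markers_per_type must be >= 1")
    if marker_fold <= 1.0:
        raise ValidationError("marker_fold must exceed 1 (markers must distinguish types)")
    names = list(cell_type_names) if cell_type_names is not None else \
        [f"CellType{k + 1}" for k in range(K)]
    if len(names) != K:
        raise ValidationError("cell_type_names length must equal K")
    n_genes = K * markers_per_type
    values = np.full((n_genes, K), float(base_level))
    genes = []
    for k in range(K):
        block = slice(k * markers_per_type, (k + 1) * markers_per_type)
        values[block, k] = base_level * marker_fold
        genes.extend(f"MRK{k + 1:02d}_{j + 1:03d}" for j in range(markers_per_type))
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        values = values * np.exp(rng.normal(0.0, jitter_sd, size=values.shape))
    return pd.DataFrame(values, index=genes, columns=names)


def apply_batch_effects(values: np.ndarray, study_labels: Sequence[str],
                        shifts: dict[str, float], scales: dict[str, float],
                        gene_shift_sd: float = 0.0,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Affine per-study distortion: ``value <- scale_b * value + shift_gb``.

    ``shift_gb`` is gene-specific, drawn Normal(shift_b, gene_shift_sd) per
    gene within study b (sd 0 makes the shift exactly the study mean).
    This is the distortion empirical-Bayes batch correction must remove.
    """
    values = np.asarray(values, dtype=float)
    study_labels = np.asarray(study_labels)
    if values.shape[1] != study_labels.size:
        raise ValidationError("one study label per sample column required")
    for b in np.unique(study_labels):
        if b not in shifts or b not in scales:
            raise ValidationError(f"missing shift/scale for study {b!r}")
        if scales[b] <= 0:
            raise ValidationError(f"batch scale must be positive, got {scales[b]} for {b!r}")
    if gene_shift_sd > 0 and rng is None:
        rng = np.random.default_rng(0)
    out = values.copy()
    n_genes = values.shape[0]
    for b in np.unique(study_labels):
        cols = study_labels == b
        gene_shift = np.full(n_genes, float(shifts[b]))
        if gene_shift_sd > 0:
            gene_shift = rng.normal(shifts[b], gene_shift_sd, size=n_genes)
        out[:, cols] = scales[b] * out[:, cols] + gene_shift[:, None]
    return out


def _dirichlet_alphas(config: SimulationConfig) -> dict[str, np.ndarray]:
    alphas = {}
    for loc, boosted in (("convexity", CONVEXITY_BOOSTED),
                         ("skull_base", SKULL_BASE_BOOSTED)):
        a = np.full(config.n_cell_types, config.dirichlet_base_alpha)
        for name in boosted:
            if name in config.cell_type_names:
                a[config.cell_type_names.index(name)] = config.dirichlet_boost_alpha
        alphas[loc] = a
    return alphas


def _dirichlet_cov(alpha: np.ndarray) -> np.ndarray:
    a0 = alpha.sum()
    denom = a0 * a0 * (a0 + 1.0)
    cov = -np.outer(alpha, alpha) / denom
    cov[np.diag_indices_from(cov)] = alpha * (a0 - alpha) / denom
    return cov


def _solve_coupling_coefficients(rhos: np.ndarray, cov: np.ndarray,
                                 noise_sd: float) -> tuple[np.ndarray, float]:
    """Coefficients ``a`` and total SD for a cytokine coupled to one or more
    cell fractions with covariance ``cov``, hitting population correlations
    ``rhos``: cytokine = a . fractions + Normal(0, noise_sd).

    From cov(c, f) = cov @ a and sd(c)^2 = a' cov a + noise_sd^2:
    a = cov^-1 u * sd_c with u_i = rho_i * sd(f_i), and
    sd_c^2 = noise_sd^2 / (1 - u' cov^-1 u); feasible iff u' cov^-1 u < 1.
    """
    s = np.sqrt(np.diag(cov))
    if np.any(s <= 0):
        raise DegenerateInputError("coupling target with zero fraction variance")
    u = rhos * s
    w = np.linalg.solve(cov, u)
    q = float(u @ w)
    if q >= 1.0:
        raise DegenerateInputError(
            f"requested coupling correlations jointly infeasible (u'C^-1 u = {q:.3f} >= 1)")
    sd_c = noise_sd / np.sqrt(1.0 - q)
    return w * sd_c, sd_c


def generate_cohort(config: SimulationConfig) -> tuple[list[ExpressionMatrix],
                                                       pd.DataFrame, GroundTruth]:
    """Simulate the multi-study cohort.

    Returns one linear-scale :class:`ExpressionMatrix` per study (each
    missing its own disjoint slice of genes), a validated metadata table,
    and the :class:`GroundTruth` of everything planted.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_cell_types
    cell_names = list(config.cell_type_names)

    # ---- samples and metadata ------------------------------------------
    sample_ids, studies, locations = [], [], []
    for s, (n, sb_frac) in enumerate(zip(config.samples_per_study,
                                         config.skull_base_fraction)):
        study = f"STUDY{s + 1}"
        n_sb = int(round(sb_frac * n))
        loc = ["skull_base"] * n_sb + ["convexity"] * (n - n_sb)
        for j in range(n):
            sample_ids.append(f"{study}_S{j + 1:03d}")
        studies.extend([study] * n)
        locations.extend(loc)
    n_samples = len(sample_ids)
    locations = np.array(locations)
    studies = np.array(studies)

    # grade II tumours are rarer on the skull base; grade III absent by default
    p_g2 = np.where(locations == "convexity", 0.10, 0.02)
    grades = np.where(rng.random(n_samples) < p_g2, 2, 1)
    ages = np.clip(rng.normal(56.4, 12.6, n_samples), 18, 90).round(1)
    sexes = np.where(rng.random(n_samples) < 0.7, "F", "M")
    metadata = validate_metadata(pd.DataFrame({
        "sample_id": sample_ids, "study": studies, "location": locations,
        "grade": grades, "age": ages, "sex": sexes,
    }))

    # ---- cell fractions -------------------------------------------------
    alphas = _dirichlet_alphas(config)
    fractions = np.empty((n_samples, K))
    for loc in ("convexity", "skull_base"):
        mask = locations == loc
        if mask.any():
            fractions[mask] = rng.dirichlet(alphas[loc], size=int(mask.sum()))
    true_fractions = pd.DataFrame(fractions, index=sample_ids, columns=cell_names)

    # ---- gene universe --------------------------------------------------
    signature = generate_signature(
        K, config.markers_per_cell_type, config.signature_base_level,
        config.signature_marker_fold, cell_type_names=cell_names,
        seed=int(rng.integers(2 ** 31)), jitter_sd=config.signature_jitter_sd)
    marker_genes = list(signature.index)
    module_genes: list[str] = []
    module_label_list: list[int] = []
    for m, size in enumerate(config.module_sizes, start=1):
        module_genes.extend(f"MOD{m}_{j + 1:04d}" for j in range(size))
        module_label_list.extend([m] * size)
    cytokine_genes = list(config.cytokine_panel)
    n_background = config.n_genes - len(marker_genes) - len(module_genes) - len(cytokine_genes)
    background_genes = [f"BG_{j + 1:05d}" for j in range(n_background)]
    gene_ids = marker_genes + module_genes + cytokine_genes + background_genes
    g_index = {g: i for i, g in enumerate(gene_ids)}

    # ---- bulk expression ------------------------------------------------
    bulk = np.empty((config.n_genes, n_samples))
    # markers: signature . fractions (linear mixing)
    bulk[: len(marker_genes), :] = signature.to_numpy() @ fractions.T
    # module genes: base level modulated by latent factors on the log2 scale
    factors = rng.normal(0.0, 1.0, size=(len(config.module_sizes), n_samples))
    if config.module_sizes:
        loc_m = config.location_module_index
        factors[loc_m, locations == "skull_base"] += config.module_location_effect
    row = len(marker_genes)
    lo, hi = config.module_loading_range
    for m, size in enumerate(config.module_sizes):
        loadings = rng.uniform(lo, hi, size=size)
        signs = rng.choice([-1.0, 1.0], size=size)
        block = config.module_gene_base_level * \
            2.0 ** ((signs * loadings)[:, None] * factors[m][None, :])
        bulk[row: row + size, :] = block
        row += size
    # cytokines: baseline noise, then planted couplings per location group
    cyt0 = len(marker_genes) + len(module_genes)
    for j in range(len(cytokine_genes)):
        bulk[cyt0 + j, :] = config.cytokine_base_level + \
            rng.normal(0.0, config.cytokine_noise_sd, n_samples)
    realized_couplings: list[dict] = []
    by_target: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for cell, cytokine, loc, rho in config.couplings:
        if cell not in cell_names:
            raise ValidationError(f"coupling cell type {cell!r} not simulated")
        if cytokine not in cytokine_genes:
            raise ValidationError(f"coupling cytokine {cytokine!r} not in panel")
        by_target.setdefault((loc, cytokine), []).append((cell, rho))
    for (loc, cytokine), targets in by_target.items():
        mask = locations == loc
        if not mask.any():
            raise DegenerateInputError(f"no {loc} samples to plant coupling on")
        cols = [cell_names.index(c) for c, _ in targets]
        rhos = np.array([r for _, r in targets])
        cov = _dirichlet_cov(alphas[loc])[np.ix_(cols, cols)]
        a, sd_c = _solve_coupling_coefficients(rhos, cov, config.cytokine_noise_sd)
        vals = fractions[np.ix_(mask.nonzero()[0], cols)] @ a + \
            config.cytokine_base_level + \
            rng.normal(0.0, config.cytokine_noise_sd, int(mask.sum()))
        bulk[cyt0 + cytokine_genes.index(cytokine), mask] = vals
        for (cell, rho), coef in zip(targets, a):
            realized_couplings.append({
                "cell_type": cell, "cytokine": cytokine, "location": loc,
                "target_rho": float(rho), "coefficient": float(coef),
                "total_sd": float(sd_c)})
    # background genes: flat baseline (noise added below)
    bg0 = cyt0 + len(cytokine_genes)
    bulk[bg0:, :] = config.background_base_level

    # multiplicative log-normal noise keeps the linear scale non-negative
    if config.noise_sd > 0:
        bulk *= np.exp(rng.normal(0.0, config.noise_sd, size=bulk.shape))
    np.clip(bulk, 0.0, None, out=bulk)

    # ---- batch effects --------------------------------------------------
    shift_lo, shift_hi = config.batch_shift_range
    scale_lo, scale_hi = config.batch_scale_range
    study_names = [f"STUDY{s + 1}" for s in range(config.n_studies)]
    shifts = {b: float(rng.uniform(shift_lo, shift_hi)) for b in study_names}
    scales = {b: float(rng.uniform(scale_lo, scale_hi)) for b in study_names}
    bulk = apply_batch_effects(bulk, studies, shifts, scales,
                               gene_shift_sd=config.gene_shift_sd, rng=rng)
    np.clip(bulk, 0.0, None, out=bulk)
    batch_params = pd.DataFrame({
        "study": study_names,
        "shift": [shifts[b] for b in study_names],
        "scale": [scales[b] for b in study_names]})

    # ---- per-study gene drops ------------------------------------------
    n_drop = int(round(config.gene_drop_rate * config.n_genes))
    order = rng.permutation(config.n_genes)
    matrices: list[ExpressionMatrix] = []
    for s, study in enumerate(study_names):
        dropped = set(order[s * n_drop: (s + 1) * n_drop])
        keep = [i for i in range(config.n_genes) if i not in dropped]
        cols = (studies == study).nonzero()[0]
        matrices.append(ExpressionMatrix(
            gene_ids=[gene_ids[i] for i in keep],
            sample_ids=[sample_ids[j] for j in cols],
            values=bulk[np.ix_(keep, cols)],
            scale="linear", standardized=False))

    module_labels = pd.Series(
        [0] * len(marker_genes) + module_label_list
        + [0] * (len(cytokine_genes) + n_background),
        index=gene_ids, name="module")
    truth = GroundTruth(
        true_fractions=true_fractions, signature=signature,
        module_labels=module_labels,
        location_module_id=config.location_module_index + 1,
        couplings=realized_couplings, batch_params=batch_params,
        cytokine_panel=cytokine_genes)
    return matrices, metadata, truth


def write_cohort(matrices: list[ExpressionMatrix], metadata: pd.DataFrame,
                 truth: GroundTruth, outdir) -> dict[str, str]:
    """Write the simulated cohort as plain-text files; returns path map."""
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for m, study in zip(matrices, metadata["study"].unique()):
        p = outdir / f"expression_{study}.tsv"
        mio.write_expression_tsv(m, p)
        paths[f"expression_{study}"] = str(p)
    mio.write_metadata_csv(metadata, outdir / "metadata.csv")
    paths["metadata"] = str(outdir / "metadata.csv")
    sig = truth.signature
    sig.index.name = "gene"
    sig.to_csv(outdir / "signature.tsv", sep="\t")
    paths["signature"] = str(outdir / "signature.tsv")
    mio.write_gene_list(truth.cytokine_panel, outdir / "cytokine_panel.txt")
    paths["cytokines"] = str(outdir / "cytokine_panel.txt")
    truth_json = {
        "true_fractions": {s: truth.true_fractions.loc[s].round(12).to_dict()
                           for s in truth.true_fractions.index},
        "module_labels": {g: int(v) for g, v in truth.module_labels.items() if v != 0},
        "location_module_id": truth.location_module_id,
        "couplings": truth.couplings,
        "batch_params": truth.batch_params.to_dict(orient="records"),
        "cytokine_panel": truth.cytokine_panel,
    }
    import json
    (outdir / "ground_truth.json").write_text(json.dumps(truth_json, indent=1))
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths
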