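# Methods

This note documents the models and procedures `menimm` implements, the
parameters that matter, what the synthetic cohorts do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Study design being modelled

The pipeline targets a meta-analysis setting: several independent bulk
microarray studies of surgically resected meningiomas, each sample labelled
with anatomical location (skull base vs convexity), WHO grade, age and sex.
The scientific question is whether the immune microenvironment differs by
location. Analysis proceeds on two complementary fronts: unsupervised
co-expression modules tested against location, and a targeted
cell-fraction-vs-cytokine correlation analysis per location.

## Preprocessing

Per study, expression columns are quantile-normalized (reference = the mean
of per-column sorted vectors; within-column ties receive the mean of the
reference values their rank range spans, the limma midrank convention) and
log2-transformed with offset +1 (`log2(x + 1)`; the offset keeps zero
expression at zero and is the conventional choice when none is dictated).
Studies are merged over the intersection of their gene sets, in sorted gene
order, with sample columns concatenated in study order.

**Scaling order.** The merged matrix is scaled to pooled mean 0 / SD 1
*per study* before batch correction. Pooled scaling is also available, but
per-study scaling is the default: a single pooled z-score would leave the
between-study location/scale structure in place — exactly the component the
batch correction exists to remove — whereas per-study scaling removes the
gross study offset and lets the empirical-Bayes step handle per-gene
residuals. Runs that need the alternative interpretation can call
`global_scale` on the merged matrix instead.

**Batch correction.** Parametric empirical-Bayes location/scale adjustment
(the Johnson-Li-Rabinovic model, no covariate design): genes are
standardized by the batch-weighted grand mean and pooled residual variance;
per-batch, per-gene location (gamma) and scale (delta^2) estimates are
shrunk toward batch-wide priors — normal for gamma, inverse-gamma for
delta^2, hyperparameters by method of moments — through the standard
iterative joint solution (relative-change tolerance 1e-4); adjusted values
are back-transformed. The implementation is validated against an
independent implementation (scanpy's) to ~1e-3 absolute agreement, the
difference being iteration stopping rules. Non-parametric priors are not
provided. Note that EB shrinkage leaves a small grand-mean drift (~1e-5 on
standardized input); it does not preserve the grand mean exactly.

## Co-expression network

- **Adjacency**: unsigned by default, `a_ij = |cor_ij|^beta` with
  `beta = 20`; the signed variant `((1 + cor)/2)^beta` is available. The
  high power sharpens the contrast between within-module correlations
  (driven by a shared latent factor) and background correlations of order
  `1/sqrt(n)`. `pick_soft_threshold` reports the scale-free-topology fit
  R^2 and mean connectivity per candidate power for data-driven selection.
- **TOM**: `TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)`,
  diagonal 1. Correlations are computed in row blocks so memory stays
  bounded for large gene sets; block size never changes results.
- **Module detection**: average-linkage hierarchical clustering on
  `1 - TOM`, cut at 99% of the maximum merge height (configurable); clusters
  below 30 genes are assigned to the grey/background module (label 0), the
  rest renumbered by descending size with ties broken by smallest member
  index. This is the static-height variant of adaptive tree cutting; the
  hybrid dynamic cut is out of scope for this version. No post-hoc merging
  of modules by eigengene similarity is performed (available as an explicit
  off-by-default option would imply a similarity threshold the analysis
  never states).
- **Module eigengene**: module genes are row-standardized, the first right
  singular vector over samples is taken as the meta-gene (unit Euclidean
  norm), sign-aligned to correlate non-negatively with the module's mean
  standardized profile; variance explained = s1^2 / sum(s^2). A
  single-gene module degenerates to that gene's standardized profile (with
  a warning).
- **Location tests**: per module, a two-sided Mann-Whitney U test of
  meta-gene scores between locations (exact null when the pooled sample is
  at most 20 and tie-free, otherwise the tie- and continuity-corrected
  normal approximation), plus the Wald p-value of the meta-gene coefficient
  in `location ~ metagene + grade + age + sex` (grade as ordinal numeric,
  age standardized, sex binary). The logistic fit tries Newton then BFGS;
  under perfect separation the adjusted p is reported as undefined rather
  than fabricated.
- **Cytokine labels**: a panel gene labels a module iff its correlation
  with the meta-gene exceeds 0.6 with p < 0.05 — positive correlations
  only, matching the directional phrasing of the rule.
- **Classifier**: logistic regression of location on the top-10 kME genes
  of each significant module, scored by the rank-formula AUC (identical to
  trapezoidal ROC integration). In-sample scoring is the default (matching
  the apparent original procedure); stratified k-fold scoring is available
  and is what the permutation-null checks use, since out-of-fold AUC is the
  quantity centred on 0.5 under label permutation — in-sample AUC with ten
  covariates is optimistically biased even on noise. Maximum-likelihood
  fits fall back to an L2 (ridge, C = 1) fit under perfect separation.

## Deconvolution

Bulk samples are modelled as non-negative mixtures of reference cell-type
profiles. Input handling follows the convention of the SVR-based
deconvolution family: the mixture is un-logged if flagged log2, globally
z-scored (a configurable step, since z-scored "linear" values are unusual
but are what the original workflow specifies), then mixture columns and the
signature are standardized over their shared genes (at least 50 required)
and regressed with an intercept.

Engines: **NNLS** (default; deterministic, exact on noiseless mixtures) and
**nu-SVR** (linear kernel, nu in {0.25, 0.5, 0.75}, lowest-RMSE fit kept,
negative coefficients clamped). Both normalize coefficients to the simplex;
an all-zero solution returns uniform fractions with a warning.

One identifiability caveat found during development: with an exactly
block-constant signature every gene row sums to the same value, so a free
intercept makes fractions unidentifiable up to an additive constant. Real
signatures never have constant row sums; the generator therefore jitters
signature entries (log-normal, sd 0.3) by default, and the NNLS engine
drops its intercept when the augmented design is numerically rank-deficient.

## Cell-cytokine networks

Within each location group (at least 3 samples), every (cell type, cytokine)
pair is scored by Pearson correlation between deconvolved fractions and
cytokine expression. Zero-variance fractions yield degenerate-flagged rows
(rho 0, p 1) instead of errors, so one collapsed cell type cannot abort a
run.

- **Thresholded network**: edge kept iff `rho > 0.6` and `p < 0.05` — the
  one-sided reading of the published cutoff; a two-sided option
  (`|rho| > 0.6`) exists. Exported as GraphML for external viewers.
- **Connectivity**: per cell, the sum of correlations with `p < 0.05` (no
  effect-size gate). The signed sum is the default, being the literal
  reading of "sum of all significant correlations"; an absolute-value mode
  is provided because the published histograms do not disambiguate the two.
  The mode used is recorded in the output.
- **Eigenvector centrality**: on the binary graph (adjacency 1 iff
  p < 0.05) over all cell and cytokine nodes jointly, the principal
  eigenvector is computed by power iteration on `A + I` (the shift breaks
  the +/-lambda oscillation of bipartite spectra without changing
  eigenvectors; tolerance 1e-12), restricted to the connected component
  with the largest principal eigenvalue (ties broken by smallest member
  index), normalized to unit Euclidean norm. Isolated nodes and
  non-principal components score 0. Unit-norm scaling is chosen over
  max-normalization because it reproduces the sub-unity score ranges
  reported for such networks.
- **No multiple-testing correction** is applied to edge p-values by
  default, for fidelity to the published procedure; Benjamini-Hochberg is
  available as an option. Raw p < 0.05 over a 22 x 35 scan implies ~38
  spurious edges in expectation — a property the synthetic experiments
  account for explicitly (below).

## Enrichment

Hypergeometric upper-tail over-representation of module genes against GMT
gene sets, Bonferroni-corrected across tested sets. The universe is the set
of analysed genes (the merged matrix), not the genome: a module drawn from
the analysed genes can only ever overlap sets within that background. The
plain hypergeometric tail is used (no EASE-style overlap decrement).

## Synthetic cohorts

Defaults emulate a 3-study meta-cohort of 107 samples (12, 84, 11 per
study; 71 skull base, including one all-skull-base study), WHO grade
distribution of roughly 94% grade 1 / 6% grade 2 with grade 2 enriched in
convexity, ages ~N(56, 13), and a 70% female cohort. Per sample:

- **fractions** ~ Dirichlet, base concentration 1.0 per cell type, raised
  to 3.0 for the location-enriched types (skull base: gamma-delta T cells,
  monocytes, plasma cells; convexity: activated mast cells, neutrophils);
- **marker genes** mix linearly: `bulk = signature x fractions` (10 markers
  per type, 10-fold elevation, jittered);
- **module genes** are driven multiplicatively by per-module latent factors
  (`base * 2^(loading * factor)`, loadings 0.3-0.8 with random sign), so
  co-expression lives on the log2 scale where the network analysis operates;
  one module's factor is shifted by 1.5 SD in skull-base samples — an
  effect size chosen to be clearly detectable (AUC ~0.85) while leaving the
  module overlap between groups realistic;
- **cytokine couplings**: within the target location group, a coupled
  cytokine is `a . fractions + Normal(0, sd)` with coefficients solved in
  closed form from the Dirichlet covariance so the *population* correlation
  hits the target (joint solve when one cytokine couples to several cells;
  infeasible combinations are rejected). The uncoupled location gets
  independent noise. The default coupling set mirrors the qualitative
  pattern the analysis is meant to recover — mast cells and neutrophils
  engaged in convexity, gamma-delta T/plasma/monocytes in skull base — and
  gives each location's dominant cell a repertoire of 5-6 cytokines at
  rho 0.45-0.74. The repertoire size is a statistical necessity, not a
  flourish: a cell with a single significant edge (~0.7) is
  indistinguishable from the extreme order statistics of the ~38 spurious
  significant edges a 22 x 35 pair scan produces at alpha = 0.05 with 36
  samples, so a detectable "active" cell must engage several mediators —
  which is also what the real networks show;
- **noise and batch**: multiplicative log-normal noise (sd 0.05, keeping
  linear values non-negative), then per-study affine batch effects (scale
  0.7-1.4, shift 0-0.5, per-gene shift jitter sd 0.05); each study drops a
  random disjoint 5% of genes so the cross-study intersection is exercised
  (intersection >= 85% of the gene universe).

What the generator does **not** emulate: probe-level microarray physics,
correlated cytokine baselines (uncoupled cytokines are independent noise),
realistic transcriptome-wide covariance beyond the planted modules, missing
metadata, or cohort sizes at the real 19k-gene scale — desk-scale runs use
1.5-2k genes. Consequently, passing tests demonstrate that the pipeline
recovers the structures it assumes, under its own noise model; they do not
certify behaviour under real microarray artefacts.

## Numerical choices and degenerate inputs

- Zero-variance vectors, empty groups, constant matrices, single-sample
  batches and empty gene intersections raise typed errors; they are never
  silently converted to NaN.
- Expression TSVs are written at `%.17g` and parsed with round-trip float
  precision, so write -> read is bit-identical.
- kME ties and module-size ties break lexicographically / by smallest
  index, making every ranking deterministic.
- All simulation randomness flows from one `numpy` Generator seeded from
  the configuration; the pipeline derives per-stage seeds from the global
  seed by a counter scheme so stages can be re-run in isolation.
- Desk-scale problem sizes used by the test-suite experiments: 400-1500
  genes, 40-107 samples, 20-seed repetitions for ranking claims. These were
  chosen so each planted structure is identifiable with margin under the
  generator's noise defaults.

## Known limitations

- The static-height tree cut is cruder than the hybrid dynamic cut; very
  close or nested modules may merge or shed genes to grey.
- The covariate-adjusted module test reports an undefined p under perfect
  separation rather than switching to a penalized test.
- Deconvolution assumes the signature's cell types span the mixture;
  unmodelled malignant/stromal content is absorbed into whichever profiles
  resemble it, as in all reference-based methods. Relative fractions only.
- Connectivity mixes positive and negative correlations under the default
  signed mode; a cell with balanced positive and negative engagement scores
  near zero. This is faithful to the statistic's definition, and the
  absolute mode is the escape hatch.
- End-to-end, the full preprocessing chain (quantile normalization at
  desk-scale gene counts, log2, batch correction) attenuates planted
  cell-cytokine correlations by roughly a third relative to computing edges
  on the raw linear matrix; at 36 samples per location a single pipeline
  run can therefore rank a spurious cell above a planted one, which is why
  recovery guarantees are stated across 20 seeds.
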