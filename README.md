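# menimm

Location-resolved analysis of the meningioma immune microenvironment from
bulk transcriptomics.

Skull-base meningiomas tend to behave more benignly than convexity
(hemispheric) meningiomas, and part of that difference appears to be
immunological. `menimm` implements, as one reproducible pipeline, the
systems-biology workflow used to probe that question in multi-study
microarray cohorts:

1. **Multi-study preprocessing** — per-study quantile normalization and
   log2 transform, merge over the genes common to all studies, per-study
   scaling to pooled mean 0 / SD 1, and parametric empirical-Bayes batch
   correction (ComBat).
2. **Weighted gene co-expression networks (WGCNA)** — pairwise gene
   correlations soft-thresholded as `a_ij = |cor(x_i, x_j)|^beta` (default
   `beta = 20`), transformed to the topological overlap matrix
   `TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`,
   clustered by average linkage on `1 - TOM`, and cut into modules of at
   least 30 genes. Each module is summarized by its eigengene (first
   principal component across samples), tested against tumour location
   (Mann-Whitney, plus a logistic model adjusting for WHO grade, age and
   sex), and labelled with cytokines positively correlated with the
   eigengene (`rho > 0.6`, `p < 0.05`). The 10 genes with the highest
   module membership (kME) per significant module feed a logistic-regression
   location classifier scored by ROC AUC.
3. **Immune deconvolution** — CIBERSORT-style estimation of 22 immune cell
   fractions per sample from an LM22-format signature matrix, with NNLS
   (default) and linear nu-SVR engines; fractions are simplex-constrained.
4. **Cell-cytokine networks** — per tumour location, Pearson correlations
   between every cell fraction and a 35-gene cytokine panel. Per cell type,
   *connectivity* = the sum of all significant (`p < 0.05`) correlations;
   node influence is scored by unweighted eigenvector centrality on the
   binary significance graph. Convexity-minus-skull-base contrasts rank the
   cells whose cytokine engagement differs by location.
5. **Over-representation analysis** — hypergeometric tests of module genes
   against user GMT gene sets with Bonferroni correction (an offline
   replacement for web annotation services).

Because the original GEO cohorts are not bundled, the package ships a fully
seeded **synthetic-cohort generator** that plants every structure the
analysis is supposed to recover — known cell fractions, a block signature
matrix, co-expression modules (one shifted between locations), per-study
batch effects, and location-specific cell-cytokine couplings — so the whole
pipeline is verifiable offline against ground truth.

## Worked example

```python
from menimm.pipeline import RunConfig, run_pipeline, write_report

config = RunConfig(outdir="demo_run", seed=7, n_genes=1500)
report = run_pipeline(config)          # simulates a 3-study, 107-sample cohort
write_report(report, "demo_run/report.json")
print(open("demo_run/report.txt").read())
```

prints

```
menimm v0.1.0 run report (seed 7)

modules detected: 4
significant modules (location): ME1
location classifier AUC: 0.853

[convexity]
  top cells by connectivity: Eosinophils, Mast cells activated, T cells CD4 memory activated
  top cells by centrality:   T cells follicular helper, Eosinophils, Macrophages M2

[skull_base]
  top cells by connectivity: T cells CD4 naive, T cells gamma delta, Neutrophils
  top cells by centrality:   T cells CD4 naive, Dendritic cells resting, Neutrophils

[enrichment] skipped
```

Reading the output: the generator plants four co-expression modules and
shifts the first one between locations — the pipeline detects exactly four
modules and flags only `ME1` as location-associated (Mann-Whitney
`p = 1.5e-07` in `demo_run/module_tests.csv`). Its top-10 kME genes
separate skull-base from convexity tumours with an in-sample AUC of 0.853.
In the cell-cytokine networks, the planted convexity driver (activated mast
cells) and the planted skull-base driver (gamma-delta T cells) both surface
in their location's top connectivity ranks; at this cohort size (36
convexity samples split across two studies) spurious correlations can still
outrank them in a single run, which is why the recovery guarantees are
stated over repeated seeds (see the acceptance script below).

The same stages are available as a CLI:

```sh
menimm simulate --outdir sim --seed 7 --n-genes 1500
menimm preprocess --matrix sim/expression_STUDY1.tsv \
    --matrix sim/expression_STUDY2.tsv --matrix sim/expression_STUDY3.tsv \
    --meta sim/metadata.csv --out merged.tsv
menimm deconvolve --expr merged.tsv --signature sim/signature.tsv --out fracs.tsv
menimm network --fractions fracs.tsv --expr merged.tsv --meta sim/metadata.csv \
    --cytokines sim/cytokine_panel.txt --outdir net
menimm run --config run.json        # the whole pipeline from a JSON config
```

## Layout

- `src/menimm/types.py`, `io.py`, `stats.py`, `errors.py` — containers,
  plain-text formats (expression TSV + JSON sidecar, metadata CSV, gene
  lists), Pearson/Mann-Whitney wrappers.
- `src/menimm/synthetic.py` — the seeded cohort generator and its planted
  ground truth.
- `src/menimm/preprocess.py` — quantile normalization, log2, merge, scaling,
  ComBat.
- `src/menimm/coexpress.py` — adjacency, TOM, module detection, eigengenes,
  location tests, cytokine labels, classifier.
- `src/menimm/deconvolve.py` — signature handling and fraction estimation.
- `src/menimm/immune_network.py` — edges, thresholded networks (GraphML),
  connectivity, eigenvector centrality, location contrasts.
- `src/menimm/enrichment.py` — GMT parsing and hypergeometric tests.
- `src/menimm/pipeline.py`, `cli.py` — orchestration, run reports, CLI.

See `docs/methods.md` for the model details, parameter choices and known
limitations.
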