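"""End-to-end orchestration: simulate -> preprocess -> co-expression ->
deconvolution -> immune network -> enrichment, as one seeded, logged run.

The stages communicate through files under ``outdir`` plus in-memory
objects; a :class:`RunReport` records parameters, per-stage wall clock,
output checksums and the headline results (module count, significant
modules, classifier AUC, per-location top cells).  Two runs with the same
config and seed reproduce every non-timing field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import coexpress, deconvolve, enrichment, immune_network, preprocess, synthetic
from .errors import MenimmError, ValidationError
from .io import read_expression_tsv, read_gene_list, read_metadata_csv
from .types import LOCATIONS

log = logging.getLogger("menimm")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    outdir: str = "menimm_run"
    seed: int = 0
    # --- inputs; empty means "simulate a cohort first" -------------------
    expression_paths: list[str] = field(default_factory=list)
    metadata_path: str = ""
    signature_path: str = ""
    cytokine_panel_path: str = ""
    gmt_path: str = ""
    # --- simulation overrides -------------------------------------------
    n_genes: int = 2000
    samples_per_study: list[int] = field(default_factory=lambda: [12, 84, 11])
    skull_base_fraction: list[float] = field(default_factory=lambda: [7 / 12, 53 / 84, 1.0])
    # --- stage parameters ------------------------------------------------
    power: float = 20.0
    min_module_size: int = 30
    rho_min: float = 0.6
    alpha: float = 0.05
    engine: str = "nnls"
    connectivity_mode: str = "signed"
    classifier_scheme: str = "in_sample"
    top_genes_per_module: int = 10
    log2_offset: float = 1.0
    # --- stage toggles ---------------------------------------------------
    skip_combat: bool = False
    skip_enrichment: bool = False

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError(f"unknown RunConfig keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str
    stages: dict = field(default_factory=dict)       # name -> details
    results: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"version": self.version, "seed": self.seed, "config": self.config,
                "stages": self.stages, "results": self.results,
                "checksums": self.checksums}


class PipelineStageError(MenimmError):
    """A stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, report: RunReport, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.report = report
        self.cause = cause


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_seed(base: int, counter: int) -> int:
    # counter-based fan-out keeps stages independently re-runnable
    return (base * 1000 + counter) % (2 ** 31)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; returns the run report.

    Stage order: (simulate) -> preprocess -> co-expression -> deconvolution
    -> immune network -> enrichment.  Deconvolution consumes the merged
    *linear-scale* matrix (before log transform), as reference-based
    deconvolution requires.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=json.loads(config.to_json()), seed=config.seed,
                       version=__version__)
    stage = "setup"
    try:
        # ---- simulate or load ------------------------------------------
        t0 = time.perf_counter()
        if config.expression_paths:
            stage = "load"
            matrices = [read_expression_tsv(p) for p in config.expression_paths]
            metadata = read_metadata_csv(config.metadata_path)
            signature = deconvolve.load_signature_tsv(config.signature_path)
            panel = read_gene_list(config.cytokine_panel_path)
            study_names = list(pd.unique(metadata["study"]))
            truth = None
        else:
            stage = "simulate"
            sim = synthetic.SimulationConfig(
                n_studies=len(config.samples_per_study),
                samples_per_study=tuple(config.samples_per_study),
                skull_base_fraction=tuple(config.skull_base_fraction),
                n_genes=config.n_genes,
                seed=_stage_seed(config.seed, 1))
            matrices, metadata, truth = synthetic.generate_cohort(sim)
            paths = synthetic.write_cohort(matrices, metadata, truth, outdir / "simulated")
            report.checksums.update({k: _sha256(v) for k, v in paths.items()})
            signature = deconvolve.SignatureMatrix.from_frame(truth.signature)
            panel = list(truth.cytokine_panel)
            study_names = [f"STUDY{i + 1}" for i in range(len(matrices))]
        report.stages[stage] = {"seconds": round(time.perf_counter() - t0, 3),
                                "n_studies": len(matrices),
                                "n_samples": int(len(metadata))}
        log.info("stage %s done: %d studies, %d samples", stage, len(matrices),
                 len(metadata))

        # ---- preprocess -------------------------------------------------
        stage = "preprocess"
        t0 = time.perf_counter()
        merged, merge_report = preprocess.preprocess_studies(
            matrices, study_names, log2_offset=config.log2_offset,
            run_combat=not config.skip_combat)
        (outdir / "merge_report.json").write_text(json.dumps(merge_report.to_dict(), indent=1))
        from .io import write_expression_tsv
        write_expression_tsv(merged, outdir / "expression_processed.tsv")
        report.checksums["expression_processed"] = _sha256(outdir / "expression_processed.tsv")
        report.stages[stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "intersected_genes": merge_report.intersected_gene_count,
            "combat_skipped": config.skip_combat}

        # linear merged matrix for deconvolution (pre-log, pre-scaling)
        linear_merged, _ = preprocess.intersect_and_merge(matrices, study_names)

        # ---- co-expression ----------------------------------------------
        stage = "coexpress"
        t0 = time.perf_counter()
        net_cfg = coexpress.NetworkConfig(power=config.power,
                                          min_module_size=config.min_module_size)
        A = coexpress.soft_adjacency(merged, net_cfg)
        tom = coexpress.topological_overlap(A)
        labels = coexpress.detect_modules(tom, net_cfg)
        metagenes, varexp = coexpress.module_eigengene(merged, labels)
        tests = coexpress.test_module_location(metagenes, metadata)
        cyto_labels, missing_panel = coexpress.label_cytokines(
            metagenes, merged, panel, rho_min=config.rho_min, alpha=config.alpha)
        pd.DataFrame({"gene": merged.gene_ids, "module": labels}).to_csv(
            outdir / "module_labels.tsv", sep="\t", index=False)
        metagenes.to_csv(outdir / "metagenes.tsv", sep="\t")
        tests.to_csv(outdir / "module_tests.csv")
        sig_modules = [m for m in tests.index if tests.loc[m, "mann_whitney_p"] < config.alpha]
        panel_genes: list[str] = []
        top_genes: dict[str, list[str]] = {}
        for m in sig_modules:
            mid = int(m.removeprefix("ME"))
            members = [g for g, l in zip(merged.gene_ids, labels) if l == mid]
            n_top = min(config.top_genes_per_module, len(members))
            top = coexpress.top_module_genes(merged, metagenes[m].to_numpy(),
                                             members, n=n_top)
            top_genes[m] = top
            panel_genes.extend(top)
        auc = None
        if panel_genes:
            auc, roc = coexpress.location_classifier(
                merged, panel_genes, metadata, scheme=config.classifier_scheme,
                seed=_stage_seed(config.seed, 2))
            roc.to_csv(outdir / "roc_points.csv", index=False)
        report.stages[stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "module_count": int(labels.max()),
            "grey_genes": int((labels == 0).sum())}
        report.results.update({
            "module_count": int(labels.max()),
            "significant_modules": sig_modules,
            "module_tests": {m: {"mann_whitney_p": float(tests.loc[m, "mann_whitney_p"]),
                                 "adjusted_p": None if pd.isna(tests.loc[m, "adjusted_p"])
                                 else float(tests.loc[m, "adjusted_p"])}
                             for m in tests.index},
            "module_cytokine_labels": cyto_labels,
            "top_module_genes": top_genes,
            "location_auc": None if auc is None else float(auc),
        })

        # ---- deconvolution ----------------------------------------------
        stage = "deconvolve"
        t0 = time.perf_counter()
        mixture = deconvolve.prepare_mixture(linear_merged)
        fractions = deconvolve.estimate_fractions(mixture, signature,
                                                  engine=config.engine)
        fractions.to_frame().to_csv(outdir / "cell_fractions.tsv", sep="\t")
        report.stages[stage] = {"seconds": round(time.perf_counter() - t0, 3),
                                "engine": config.engine,
                                "n_cell_types": signature.K}

        # ---- immune network ---------------------------------------------
        stage = "immune_network"
        t0 = time.perf_counter()
        summaries = {}
        for loc in LOCATIONS:
            if not (metadata["location"] == loc).any():
                continue
            edges, _ = immune_network.cell_cytokine_edges(
                fractions, merged, panel, metadata, loc)
            edges.to_csv(outdir / f"edges_{loc}.csv", index=False)
            graph = immune_network.build_network(edges, rho_min=config.rho_min,
                                                 alpha=config.alpha)
            immune_network.write_graphml(graph, outdir / f"network_{loc}.graphml")
            summaries[loc] = immune_network.summarize_location(
                edges, alpha=config.alpha, mode=config.connectivity_mode)
        ranking = {}
        for loc, s in summaries.items():
            ranking[loc] = {
                "top_cells_by_connectivity":
                    s.connectivity.sort_values(ascending=False).head(3).index.tolist(),
                "top_cells_by_centrality":
                    s.centrality[s.centrality.index.isin(s.connectivity.index)]
                    .sort_values(ascending=False).head(3).index.tolist(),
            }
        if len(summaries) == 2:
            diff = immune_network.compare_locations(summaries["convexity"],
                                                    summaries["skull_base"])
            diff.to_csv(outdir / "location_differences.csv")
            report.results["top_delta_connectivity_cells"] = diff.index[:3].tolist()
        report.results["per_location"] = ranking
        report.stages[stage] = {"seconds": round(time.perf_counter() - t0, 3),
                                "locations": sorted(summaries)}

        # ---- enrichment --------------------------------------------------
        stage = "enrichment"
        t0 = time.perf_counter()
        if config.skip_enrichment or not config.gmt_path:
            report.stages[stage] = {"skipped": True}
        else:
            sets = enrichment.read_gmt(config.gmt_path)
            universe = list(merged.gene_ids)
            enrich_rows = []
            for m in sig_modules:
                mid = int(m.removeprefix("ME"))
                members = [g for g, l in zip(merged.gene_ids, labels) if l == mid]
                for row in enrichment.overrepresentation(members, universe, sets):
                    enrich_rows.append({"module": m, **row})
            pd.DataFrame(enrich_rows).to_csv(outdir / "enrichment.csv", index=False)
            report.stages[stage] = {"seconds": round(time.perf_counter() - t0, 3),
                                    "n_sets": len(sets),
                                    "n_significant_rows": sum(
                                        1 for r in enrich_rows if r["bonferroni_p"] < 0.05)}
    except Exception as exc:  # noqa: BLE001 - stage name must reach the caller
        raise PipelineStageError(stage, report, exc) from exc
    return report


def write_report(report: RunReport, path) -> None:
    """Write the report as JSON plus a human-readable text summary."""
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2))
    lines = [f"menimm v{report.version} run report (seed {report.seed})", ""]
    res = report.results
    lines.append(f"modules detected: {res.get('module_count')}")
    lines.append(f"significant modules (location): {', '.join(res.get('significant_modules', [])) or 'none'}")
    if res.get("location_auc") is not None:
        lines.append(f"location classifier AUC: {res['location_auc']:.3f}")
    for loc, r in res.get("per_location", {}).items():
        lines.append("")
        lines.append(f"[{loc}]")
        lines.append("  top cells by connectivity: " + ", ".join(r["top_cells_by_connectivity"]))
        lines.append("  top cells by centrality:   " + ", ".join(r["top_cells_by_centrality"]))
    if report.stages.get("enrichment", {}).get("skipped"):
        lines.append("")
        lines.append("[enrichment] skipped")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
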