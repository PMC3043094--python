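"""End-to-end orchestration: the two single-study arms and their convergence.

Stage order: SNP selection + window mapping -> GWAS pathway enrichment;
subtraction-design differential expression -> expression pathway
enrichment; then the two convergence operations — the overlap of the
per-study significant pathway sets and the Fisher combined-probability
meta-analysis with Bonferroni correction.

``run_study`` works on in-memory objects (what tests and simulation sweeps
use); ``run_all`` is the file-based front end that also writes every stage
output plus a run manifest with input/output digests.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as core_io
from .enrichment import (
    EnrichmentResult,
    results_frame,
    significant_pathways,
    test_pathways,
)
from .expression import DifferentialGeneLists, differential_analysis
from .meta import OverlapReport, format_overlap, meta_analysis, overlap_report
from .models import ExpressionPanel, GeneModel, GeneSetCollection, PipelineConfig, SnpAssociation
from .simulate import SimulationSpec, generate_dataset, write_dataset
from .snp2gene import GeneIndex, build_gene_list, map_all_snps, select_top_snps, write_assignments

__version__ = "0.1.0"


@dataclass
class StudyResult:
    """Everything the pipeline computes for one dataset."""

    gwas_query: set[str]
    gwas_reference: set[str]
    gwas_enrichment: list[EnrichmentResult]
    gwas_untested: list[str]
    sub_table: pd.DataFrame
    gene_lists: DifferentialGeneLists
    expr_reference: set[str]
    expr_enrichment: list[EnrichmentResult]
    expr_untested: list[str]
    gwas_sig: set[str]
    expr_sig: set[str]
    overlap: OverlapReport
    meta: pd.DataFrame
    uncombined: list[str]

    @property
    def M(self) -> int:
        return len(self.meta)


def run_study(
    snps: list[SnpAssociation],
    genes: list[GeneModel],
    pathways: GeneSetCollection,
    panel: ExpressionPanel,
    config: PipelineConfig,
) -> StudyResult:
    """Run both arms and their convergence on in-memory inputs."""
    index = GeneIndex(genes)

    # GWAS arm: query from the top SNPs, reference from all SNPs
    top = select_top_snps(snps, config.top_snp_count, config.snp_p_threshold)
    gwas_query = build_gene_list(top, index, config.window_bp)
    gwas_reference = build_gene_list(snps, index, config.window_bp)
    gwas_enrichment, gwas_untested = test_pathways(gwas_query, gwas_reference, pathways)

    # expression arm: merged differential list against the panel universe
    sub_table, gene_lists = differential_analysis(panel, config)
    expr_reference = set(panel.genes)
    expr_enrichment, expr_untested = test_pathways(
        gene_lists.merged, expr_reference, pathways
    )

    gwas_sig = significant_pathways(gwas_enrichment, config.pathway_alpha)
    expr_sig = significant_pathways(expr_enrichment, config.pathway_alpha)
    meta, uncombined = meta_analysis(gwas_enrichment, expr_enrichment)
    return StudyResult(
        gwas_query=gwas_query,
        gwas_reference=gwas_reference,
        gwas_enrichment=gwas_enrichment,
        gwas_untested=gwas_untested,
        sub_table=sub_table,
        gene_lists=gene_lists,
        expr_reference=expr_reference,
        expr_enrichment=expr_enrichment,
        expr_untested=expr_untested,
        gwas_sig=gwas_sig,
        expr_sig=expr_sig,
        overlap=overlap_report(gwas_sig, expr_sig),
        meta=meta,
        uncombined=uncombined,
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_study_outputs(result: StudyResult, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gwas_query": out / "gwas_gene_query.txt",
        "gwas_reference": out / "gwas_gene_reference.txt",
        "differential": out / "expression_differential.tsv",
        "genes_up": out / "genes_up.txt",
        "genes_down": out / "genes_down.txt",
        "genes_merged": out / "genes_merged.txt",
        "enrichment_gwas": out / "enrichment_gwas.tsv",
        "enrichment_expression": out / "enrichment_expression.tsv",
        "overlap": out / "overlap.txt",
        "meta": out / "meta_ranked.tsv",
    }
    core_io.write_gene_list(result.gwas_query, paths["gwas_query"])
    core_io.write_gene_list(result.gwas_reference, paths["gwas_reference"])
    _write_tsv(result.sub_table, paths["differential"])
    core_io.write_gene_list(result.gene_lists.up, paths["genes_up"])
    core_io.write_gene_list(result.gene_lists.down, paths["genes_down"])
    core_io.write_gene_list(result.gene_lists.merged, paths["genes_merged"])
    _write_tsv(
        results_frame(result.gwas_enrichment, result.gwas_untested),
        paths["enrichment_gwas"],
    )
    _write_tsv(
        results_frame(result.expr_enrichment, result.expr_untested),
        paths["enrichment_expression"],
    )
    paths["overlap"].write_text(format_overlap(result.overlap))
    _write_tsv(result.meta, paths["meta"])
    return paths


def run_all(config: PipelineConfig, input_paths: dict, out_dir) -> dict:
    """File-based run: read every input, run the study, write outputs + manifest.

    ``input_paths`` needs keys snps, genes, gmt, expr_case, expr_control.
    Any stage failure is re-raised annotated with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 4)
        return value

    snps = _stage("read_snps", lambda: core_io.read_snp_table(input_paths["snps"]))
    genes = _stage("read_genes", lambda: core_io.read_gene_table(input_paths["genes"]))
    pathways = _stage("read_gmt", lambda: core_io.read_gmt(input_paths["gmt"]))
    panel = _stage(
        "read_expression",
        lambda: core_io.read_expression_panel(
            input_paths["expr_case"], input_paths["expr_control"]
        ),
    )
    result = _stage("analysis", lambda: run_study(snps, genes, pathways, panel, config))
    out_paths = _stage("write_outputs", lambda: write_study_outputs(result, out))

    # assignments of the selected SNPs, for provenance
    index = GeneIndex(genes)
    top = select_top_snps(snps, config.top_snp_count, config.snp_p_threshold)
    write_assignments(map_all_snps(top, index, config.window_bp), out / "snp_assignments.tsv")
    out_paths["assignments"] = out / "snp_assignments.tsv"

    manifest = {
        "tool": "pdpathways",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {k: _digest(Path(v)) for k, v in input_paths.items()},
        "outputs": {k: _digest(p) for k, p in out_paths.items()},
        "timings_s": timings,
    }
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    tmp.replace(out / "manifest.json")  # atomic publish
    return manifest


def demo(seed: int, out_dir, spec: SimulationSpec | None = None) -> dict:
    """Generate the default planted fixture, run the pipeline, print a summary."""
    out = Path(out_dir)
    spec = spec if spec is not None else SimulationSpec(rng_seed=seed)
    dataset = generate_dataset(spec)
    input_paths = write_dataset(dataset, out / "data")
    config = PipelineConfig(rng_seed=seed)
    manifest = run_all(config, input_paths, out / "run")

    meta = pd.read_csv(out / "run" / "meta_ranked.tsv", sep="\t")
    print("Top 10 pathways by combined (Fisher) p-value:")
    print(meta.head(10).to_string(index=False))
    print()
    print((out / "run" / "overlap.txt").read_text(), end="")
    return manifest
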