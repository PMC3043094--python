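"""Synthetic genomes, pathways, GWAS summary statistics and staged expression.

The generator plants a known pathway signal so every downstream stage has a
ground truth:

* annotation — non-overlapping genes laid left-to-right per chromosome with
  exponentially distributed lengths and intergenic gaps;
* pathways — fixed-size gene sets sampled without replacement within a set,
  with replacement across sets;
* GWAS — SNPs uniform over each chromosome span; a SNP within ``window_bp``
  of a planted-pathway gene draws its p-value from Beta(a, 1) with a < 1
  (enriching small p-values, mean a/(a+1)), all others from Uniform(0, 1);
* expression — log2 value = per-gene baseline + shared per-region offset
  (the normal between-region variation the control subtraction removes)
  + for planted genes in case subjects a cumulative Braak-stage shift of
  ``stage_shift_per_transition`` log2 units per transition + Gaussian noise.

Each generator draws from its own stream seeded by (rng_seed, generator
offset), so e.g. changing n_snps never perturbs the expression panel.
Everything is byte-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .models import (
    CASE,
    CONTROL,
    DEFAULT_REGIONS,
    ExpressionPanel,
    GeneModel,
    GeneSetCollection,
    SnpAssociation,
)
from .snp2gene import GeneIndex

_STREAM_ANNOTATION = 1
_STREAM_PATHWAYS = 2
_STREAM_GWAS = 3
_STREAM_EXPRESSION = 4


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults are the planted-signal conditions used throughout the test
    suite: 2000 genes on 4 chromosomes, 200 pathways of 50 genes of which
    one is planted, 20000 SNPs with Beta(0.2, 1) p-values near planted
    genes, and a 5-region staged panel (shift 1.0 log2 per transition,
    noise sd 0.3) for 7 cases and 4 controls.
    """

    rng_seed: int = 0
    n_chrom: int = 4
    n_genes: int = 2000
    mean_gene_length_bp: int = 10_000
    mean_intergenic_gap_bp: int = 15_000
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (50, 50)
    planted_pathways: frozenset[str] = frozenset({"pw001"})
    n_snps: int = 20_000
    gwas_effect_beta_a: float = 0.2
    window_bp: int = 20_000
    n_cases: int = 7
    n_controls: int = 4
    regions: tuple[str, ...] = DEFAULT_REGIONS
    stage_shift_per_transition: float = 1.0
    noise_sd: float = 0.3
    baseline_region_offsets: tuple[float, ...] = (0.0, 0.4, -0.3, 0.6, 0.2)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_chrom < 1:
            raise ValueError("need at least one gene and one chromosome")
        if not (0.0 < self.gwas_effect_beta_a <= 1.0):
            raise ValueError("gwas_effect_beta_a must be in (0, 1]; < 1 plants signal")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid pathway_size_range")
        if hi > self.n_genes:
            raise ValueError("pathway size cannot exceed n_genes")
        if len(self.baseline_region_offsets) != len(self.regions):
            raise ValueError("need one baseline offset per region")
        if len(self.regions) < 2:
            raise ValueError("need >= 2 regions")

    def null(self) -> "SimulationSpec":
        """The matched no-signal conditions: uniform GWAS p, no stage shift."""
        return replace(self, gwas_effect_beta_a=1.0, stage_shift_per_transition=0.0)


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.rng_seed, stream])


def gen_annotation(spec: SimulationSpec) -> list[GeneModel]:
    """Non-overlapping genes per chromosome, deterministic under the seed."""
    rng = _rng(spec, _STREAM_ANNOTATION)
    per_chrom = np.full(spec.n_chrom, spec.n_genes // spec.n_chrom)
    per_chrom[: spec.n_genes % spec.n_chrom] += 1
    genes: list[GeneModel] = []
    gid = 0
    for c in range(spec.n_chrom):
        chrom = f"chr{c + 1}"
        pos = 0
        n = int(per_chrom[c])
        gaps = np.maximum(1, rng.exponential(spec.mean_intergenic_gap_bp, n)).astype(int)
        lengths = np.maximum(1, rng.exponential(spec.mean_gene_length_bp, n)).astype(int)
        for gap, length in zip(gaps, lengths):
            start = pos + int(gap) + 1
            end = start + int(length) - 1
            gid += 1
            genes.append(GeneModel(f"g{gid:05d}", chrom, start, end, True))
            pos = end
    return genes


def gen_pathways(spec: SimulationSpec, genes: list[GeneModel]) -> GeneSetCollection:
    """n_pathways gene sets; sizes uniform on the configured range.

    Members are sampled without replacement within a pathway, with
    replacement across pathways (a gene may belong to many sets).
    """
    rng = _rng(spec, _STREAM_PATHWAYS)
    gene_ids = np.array([g.gene_id for g in genes])
    lo, hi = spec.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_pathways)
    items = []
    for i in range(spec.n_pathways):
        pid = f"pw{i + 1:03d}"
        members = rng.choice(gene_ids, size=int(sizes[i]), replace=False)
        items.append((pid, f"synthetic pathway {i + 1}", list(members)))
    collection = GeneSetCollection.from_items(items)
    missing = spec.planted_pathways - set(collection.ids())
    if missing:
        raise ValueError(f"planted pathways not generated: {sorted(missing)}")
    return collection


def planted_genes(spec: SimulationSpec, pathways: GeneSetCollection) -> frozenset[str]:
    out: set[str] = set()
    for pid in spec.planted_pathways:
        out |= pathways.members(pid)
    return frozenset(out)


def gen_gwas(
    spec: SimulationSpec, genes: list[GeneModel], pathways: GeneSetCollection
) -> list[SnpAssociation]:
    """SNPs uniform over chromosome spans; planted-adjacent SNPs get small p.

    A SNP is planted-adjacent when a planted-pathway gene lies within
    ``spec.window_bp``; its p-value is Beta(a, 1), all others Uniform(0, 1).
    """
    rng = _rng(spec, _STREAM_GWAS)
    spans: dict[str, int] = {}
    for g in genes:
        spans[g.chrom] = max(spans.get(g.chrom, 0), g.end + spec.mean_intergenic_gap_bp)
    chroms = sorted(spans)
    weights = np.array([spans[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=spec.n_snps, p=weights / weights.sum())
    positions = 1 + np.floor(rng.random(spec.n_snps) * weights[chrom_idx]).astype(int)
    p_values = rng.uniform(size=spec.n_snps)
    beta_draws = rng.beta(spec.gwas_effect_beta_a, 1.0, size=spec.n_snps)

    planted = planted_genes(spec, pathways)
    planted_index = GeneIndex(g for g in genes if g.gene_id in planted)
    snps: list[SnpAssociation] = []
    for i in range(spec.n_snps):
        chrom = chroms[chrom_idx[i]]
        pos = int(positions[i])
        near_planted = bool(planted_index.window_hits(chrom, pos, spec.window_bp))
        p = beta_draws[i] if near_planted and spec.gwas_effect_beta_a < 1.0 else p_values[i]
        p = float(np.clip(p, np.nextafter(0.0, 1.0), 1.0))
        snps.append(SnpAssociation(f"rs{i + 1:06d}", chrom, pos, p))
    return snps


def gen_expression(
    spec: SimulationSpec, genes: list[GeneModel], pathways: GeneSetCollection
) -> ExpressionPanel:
    """Staged log2 expression panel with the planted case-only Braak shift."""
    rng = _rng(spec, _STREAM_EXPRESSION)
    gene_ids = [g.gene_id for g in genes]
    n_genes, n_regions = len(gene_ids), len(spec.regions)
    cases = [f"case{i + 1:02d}" for i in range(spec.n_cases)]
    controls = [f"ctrl{i + 1:02d}" for i in range(spec.n_controls)]
    subjects = cases + controls
    groups = {s: CASE for s in cases} | {s: CONTROL for s in controls}

    baseline = rng.normal(8.0, 1.5, size=n_genes)
    offsets = np.asarray(spec.baseline_region_offsets, dtype=float)
    values = (
        baseline[:, None, None]
        + offsets[None, None, :]
        + rng.normal(0.0, spec.noise_sd, size=(n_genes, len(subjects), n_regions))
    )
    planted = planted_genes(spec, pathways)
    planted_rows = np.array([g in planted for g in gene_ids])
    stage = np.arange(n_regions, dtype=float)
    shift = spec.stage_shift_per_transition * stage  # cumulative over Braak order
    values[np.ix_(planted_rows, np.arange(len(cases)))] += shift[None, None, :]
    return ExpressionPanel(
        genes=gene_ids, subjects=subjects, groups=groups,
        regions=list(spec.regions), values=values,
    )


@dataclass
class SyntheticDataset:
    spec: SimulationSpec
    genes: list[GeneModel]
    pathways: GeneSetCollection
    snps: list[SnpAssociation]
    panel: ExpressionPanel


def generate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    genes = gen_annotation(spec)
    pathways = gen_pathways(spec, genes)
    return SyntheticDataset(
        spec=spec,
        genes=genes,
        pathways=pathways,
        snps=gen_gwas(spec, genes, pathways),
        panel=gen_expression(spec, genes, pathways),
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the dataset in exactly the formats the core readers consume."""
    from . import io as core_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "snps": out / "snps.tsv",
        "genes": out / "genes.tsv",
        "gmt": out / "pathways.gmt",
        "expr_case": out / "expression_cases.tsv",
        "expr_control": out / "expression_controls.tsv",
    }
    core_io.write_snp_table(dataset.snps, paths["snps"])
    core_io.write_gene_table(dataset.genes, paths["genes"])
    core_io.write_gmt(dataset.pathways, paths["gmt"])
    core_io.write_expression_matrices(
        dataset.panel, paths["expr_case"], paths["expr_control"]
    )
    return paths
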