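"""Readers and writers for the tab-separated and GMT formats the pipeline touches.

All tabular files are tab-separated with a header row.  Readers validate
eagerly and fail with the offending row/line number; the missing-data policy
is to fail loudly rather than impute, because the region-subtraction design
is undefined with missing cells.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import (
    CASE,
    CONTROL,
    DEFAULT_REGIONS,
    ExpressionPanel,
    GeneModel,
    GeneSetCollection,
    PipelineConfig,
    SnpAssociation,
)

log = logging.getLogger(__name__)

SNP_COLUMNS = ["snp_id", "chrom", "pos", "p_value"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "biotype"]
PROTEIN_CODING = "protein_coding"


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_snp_table(path) -> list[SnpAssociation]:
    """Read a SNP association table; order of data rows is preserved.

    Data rows are numbered from 1 in error messages.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, SNP_COLUMNS, path)
    records: list[SnpAssociation] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pos = int(row.pos)
            p = float(row.p_value)
            rec = SnpAssociation(
                snp_id=str(row.snp_id), chrom=str(row.chrom), pos=pos, p_value=p
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed SNP record at row {i}: {exc}") from exc
        if rec.snp_id in seen:
            raise ValueError(f"{path}: duplicate snp_id {rec.snp_id!r} at row {i}")
        seen.add(rec.snp_id)
        records.append(rec)
    return records


def write_snp_table(snps: Iterable[SnpAssociation], path) -> None:
    df = pd.DataFrame(
        [(s.snp_id, s.chrom, s.pos, s.p_value) for s in snps], columns=SNP_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gene_table(path) -> list[GeneModel]:
    """Read a gene annotation table (gene_id, chrom, start, end, biotype)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, GENE_COLUMNS, path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            gene = GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                is_protein_coding=(str(row.biotype) == PROTEIN_CODING),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed gene record at row {i}: {exc}") from exc
        if gene.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {gene.gene_id!r} at row {i}")
        seen.add(gene.gene_id)
        genes.append(gene)
    return genes


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    df = pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.start, g.end,
             PROTEIN_CODING if g.is_protein_coding else "other")
            for g in genes
        ],
        columns=GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format: set_id TAB description TAB member...

    Duplicate members within a line are collapsed; a duplicate set id or a
    line with fewer than three fields is an error (reported with its line
    number).
    """
    items: list[tuple[str, str, list[str]]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: GMT line {lineno} has {len(parts)} fields, need >= 3"
                )
            pid, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if pid in seen:
                raise ValueError(f"{path}: duplicate set id {pid!r} at line {lineno}")
            if not members:
                raise ValueError(f"{path}: GMT line {lineno} ({pid}) has no members")
            seen.add(pid)
            items.append((pid, desc, members))
    return GeneSetCollection.from_items(items)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a GeneSetCollection in GMT format (members sorted for stable output)."""
    with open(path, "w") as fh:
        for pid, name, members in collection.items():
            fh.write("\t".join([pid, name, *sorted(members)]) + "\n")


def _parse_expression_matrix(path, regions: Sequence[str]):
    """Return (genes, {subject: {region: column values}}) for one matrix file."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    subjects: dict[str, dict[str, np.ndarray]] = {}
    for col in df.columns:
        if ":" not in col:
            raise ValueError(
                f"{path}: column {col!r} is not in subject:region form"
            )
        subject, region = col.split(":", 1)
        if region not in regions:
            raise ValueError(
                f"{path}: column {col!r} has region {region!r} outside the "
                f"configured Braak order {list(regions)}"
            )
        subjects.setdefault(subject, {})[region] = df[col].to_numpy(dtype=float)
    for subject, cols in subjects.items():
        for region in regions:
            if region not in cols:
                raise ValueError(
                    f"{path}: subject {subject!r} is missing region {region!r}; "
                    "the subtraction design requires every region per subject"
                )
    return list(df.index.astype(str)), subjects


def read_expression_panel(
    case_path, control_path, regions: Sequence[str] = DEFAULT_REGIONS
) -> ExpressionPanel:
    """Assemble an ExpressionPanel from case and control log2 matrices.

    Genes present in only one file are dropped (with a logged count); every
    subject must have a column for every configured region.
    """
    case_genes, case_subjects = _parse_expression_matrix(case_path, regions)
    ctrl_genes, ctrl_subjects = _parse_expression_matrix(control_path, regions)

    shared = [g for g in case_genes if g in set(ctrl_genes)]
    dropped = (len(case_genes) - len(shared)) + (len(ctrl_genes) - len(shared))
    if dropped:
        log.warning(
            "expression panel: dropped %d gene rows not shared by both files", dropped
        )
    if not shared:
        raise ValueError("no genes shared between case and control matrices")

    case_pos = {g: i for i, g in enumerate(case_genes)}
    ctrl_pos = {g: i for i, g in enumerate(ctrl_genes)}
    subjects = sorted(case_subjects) + sorted(ctrl_subjects)
    groups = {s: CASE for s in case_subjects} | {s: CONTROL for s in ctrl_subjects}
    if len(groups) != len(subjects):
        raise ValueError("subject ids overlap between case and control files")

    values = np.empty((len(shared), len(subjects), len(regions)))
    for j, subject in enumerate(subjects):
        source, pos = (
            (case_subjects, case_pos) if groups[subject] == CASE else (ctrl_subjects, ctrl_pos)
        )
        rows = [pos[g] for g in shared]
        for k, region in enumerate(regions):
            values[:, j, k] = source[subject][region][rows]
    return ExpressionPanel(
        genes=shared, subjects=subjects, groups=groups,
        regions=list(regions), values=values,
    )


def write_expression_matrices(panel: ExpressionPanel, case_path, control_path) -> None:
    """Write a panel back to the two subject:region matrices the reader consumes."""
    for path, subset in (
        (case_path, panel.case_subjects),
        (control_path, panel.control_subjects),
    ):
        cols = {}
        for s in subset:
            j = panel.subject_index(s)
            for k, r in enumerate(panel.regions):
                cols[f"{s}:{r}"] = panel.values[:, j, k]
        df = pd.DataFrame(cols, index=pd.Index(panel.genes, name="gene_id"))
        df.to_csv(path, sep="\t", float_format="%.6f")


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
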