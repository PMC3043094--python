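"""Domain types shared by every pipeline stage.

Coordinates are 1-based and inclusive at both ends (dbSNP/ENSEMBL
convention).  Expression values are log2-scale by contract; nothing in the
pipeline re-transforms them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterator, Mapping, Sequence

import numpy as np

CASE = "case"
CONTROL = "control"

#: Braak-ordered brain regions used throughout: dorsal motor nucleus of the
#: vagus, locus coeruleus, substantia nigra, putamen, insular cortex.
DEFAULT_REGIONS = ("DMV", "LCER", "SNGRA", "PTMN", "INSLA")


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP: genomic location plus association p-value."""

    snp_id: str
    chrom: str
    pos: int
    p_value: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: pos must be >= 1, got {self.pos}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"SNP {self.snp_id}: p_value must be in (0,1], got {self.p_value}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic interval ([start, end] inclusive, 1-based)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    is_protein_coding: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneSetCollection:
    """Named pathways as sets of gene ids (the in-memory form of a GMT file)."""

    def __init__(self, sets: Mapping[str, tuple[str, frozenset[str]]]):
        for pid, (_, members) in sets.items():
            if not members:
                raise ValueError(f"pathway {pid} has no members")
        self._sets = dict(sets)

    @classmethod
    def from_items(
        cls, items: Sequence[tuple[str, str, Sequence[str]]]
    ) -> "GeneSetCollection":
        sets: dict[str, tuple[str, frozenset[str]]] = {}
        for pid, name, members in items:
            if pid in sets:
                raise ValueError(f"duplicate pathway id {pid}")
            sets[pid] = (name, frozenset(members))
        return cls(sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._sets

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets

    def ids(self) -> list[str]:
        return list(self._sets)

    def name(self, pathway_id: str) -> str:
        return self._sets[pathway_id][0]

    def members(self, pathway_id: str) -> frozenset[str]:
        return self._sets[pathway_id][1]

    def items(self) -> Iterator[tuple[str, str, frozenset[str]]]:
        for pid, (name, members) in self._sets.items():
            yield pid, name, members

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for _, (_, members) in self._sets.items():
            out |= members
        return frozenset(out)


@dataclass
class ExpressionPanel:
    """log2 expression indexed by gene x subject x ordered Braak region.

    ``values[i, j, k]`` is the expression of ``genes[i]`` in ``subjects[j]``
    at ``regions[k]``; regions are in Braak order so adjacent columns are
    consecutive disease stages.  Every cell must be present: the subtraction
    design is undefined with missing regions.
    """

    genes: list[str]
    subjects: list[str]
    groups: dict[str, str]  # subject -> "case" | "control"
    regions: list[str]
    values: np.ndarray  # shape (n_genes, n_subjects, n_regions)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.genes), len(self.subjects), len(self.regions))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != (genes, subjects, regions) {expected}"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression panel contains missing values")
        if len(self.regions) < 2:
            raise ValueError("need >= 2 ordered regions")
        unknown = [s for s in self.subjects if self.groups.get(s) not in (CASE, CONTROL)]
        if unknown:
            raise ValueError(f"subjects without case/control label: {unknown}")
        if len(self.case_subjects) < 1:
            raise ValueError("need >= 1 case subject")
        if len(self.control_subjects) < 2:
            raise ValueError("need >= 2 control subjects (control variance)")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in panel")

    @property
    def case_subjects(self) -> list[str]:
        return [s for s in self.subjects if self.groups[s] == CASE]

    @property
    def control_subjects(self) -> list[str]:
        return [s for s in self.subjects if self.groups[s] == CONTROL]

    @property
    def n_pairs(self) -> int:
        return len(self.regions) - 1

    @property
    def pair_labels(self) -> list[str]:
        return [
            f"{self.regions[i]}->{self.regions[i + 1]}" for i in range(self.n_pairs)
        ]

    def subject_index(self, subject: str) -> int:
        try:
            return self.subjects.index(subject)
        except ValueError:
            raise KeyError(f"unknown subject {subject!r}") from None

    def value(self, gene: str, subject: str, region: str) -> float:
        return float(
            self.values[
                self.genes.index(gene),
                self.subject_index(subject),
                self.regions.index(region),
            ]
        )


@dataclass
class PipelineConfig:
    """Thresholds and the seed that drive a pipeline run.

    window_bp: SNP-to-gene window on either side of the SNP (bp).
    top_snp_count / snp_p_threshold: query SNPs are those with p below the
        threshold, keeping at most the top count.
    fold_change_threshold: linear-scale fold change; calls require
        |adjusted log2 delta| >= log2(threshold).
    q_threshold: BH q cut-off for differential calls.
    pathway_alpha: per-study pathway significance level (inclusive).
    """

    window_bp: int = 20_000
    top_snp_count: int = 5_000
    snp_p_threshold: float = 0.01
    fold_change_threshold: float = 1.6
    q_threshold: float = 0.05
    pathway_alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")
        if self.top_snp_count < 1:
            raise ValueError("top_snp_count must be >= 1")
        if not (0.0 < self.snp_p_threshold <= 1.0):
            raise ValueError("snp_p_threshold must be in (0,1]")
        if self.fold_change_threshold <= 1.0:
            raise ValueError("fold_change_threshold must be > 1 (linear scale)")
        if not (0.0 < self.q_threshold <= 1.0):
            raise ValueError("q_threshold must be in (0,1]")
        if not (0.0 < self.pathway_alpha <= 1.0):
            raise ValueError("pathway_alpha must be in (0,1]")

    @property
    def log2_fold_threshold(self) -> float:
        return float(np.log2(self.fold_change_threshold))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))
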