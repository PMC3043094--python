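"""Map SNPs to protein-coding genes with a symmetric window and nearest-gene fallback.

The window rule assigns every gene whose interval intersects
[pos - window_bp, pos + window_bp], inclusive at exactly window_bp.  When no
gene lies in the window, the nearest gene strictly left and the nearest
strictly right of the SNP on the same chromosome are both assigned
(irrespective of distance); one side may be absent near a chromosome end.
A gene hit by several SNPs enters the resulting gene list once.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .models import GeneModel, SnpAssociation

log = logging.getLogger(__name__)

RULE_WINDOW = "window"
RULE_NEAREST = "nearest_fallback"


@dataclass(frozen=True)
class SnpGeneAssignment:
    snp_id: str
    assigned_genes: frozenset[str]
    rule_used: str


class GeneIndex:
    """Per-chromosome interval index over protein-coding genes.

    Non-coding genes are dropped at construction; window queries use an
    interval tree, nearest-gene fallback uses sorted endpoint arrays.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        coding = [g for g in genes if g.is_protein_coding]
        ids = [g.gene_id for g in coding]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in annotation")
        self._trees: dict[str, IntervalTree] = {}
        self._by_end: dict[str, list[tuple[int, str]]] = {}
        self._by_start: dict[str, list[tuple[int, str]]] = {}
        per_chrom: dict[str, list[GeneModel]] = {}
        for g in coding:
            per_chrom.setdefault(g.chrom, []).append(g)
        for chrom, glist in per_chrom.items():
            # interval tree uses half-open intervals; genes are inclusive
            self._trees[chrom] = IntervalTree.from_tuples(
                (g.start, g.end + 1, g.gene_id) for g in glist
            )
            self._by_end[chrom] = sorted((g.end, g.gene_id) for g in glist)
            self._by_start[chrom] = sorted((g.start, g.gene_id) for g in glist)

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)

    def window_hits(self, chrom: str, pos: int, window_bp: int) -> set[str]:
        """Genes whose [start, end] intersects [pos-window_bp, pos+window_bp]."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        lo = pos - window_bp
        hi = pos + window_bp + 1  # half-open query end; +window_bp is inclusive
        return {iv.data for iv in tree.overlap(lo, hi)}

    def nearest_flanks(self, chrom: str, pos: int) -> set[str]:
        """Nearest gene strictly left of pos and nearest strictly right.

        Ties in distance (shared boundary coordinate) are broken by the
        lexicographically smaller gene id, one gene per side.
        """
        out: set[str] = set()
        by_end = self._by_end.get(chrom, [])
        by_start = self._by_start.get(chrom, [])
        # left flank: maximal end < pos
        i = bisect_left(by_end, (pos, ""))
        if i > 0:
            best_end = by_end[i - 1][0]
            j = bisect_left(by_end, (best_end, ""))
            out.add(min(gid for e, gid in by_end[j:i] if e == best_end))
        # right flank: minimal start > pos
        k = bisect_right(by_start, (pos, "￿"))
        if k < len(by_start):
            best_start = by_start[k][0]
            m = bisect_right(by_start, (best_start, "￿"))
            out.add(min(gid for s, gid in by_start[k:m] if s == best_start))
        return out


def map_snp_to_genes(
    snp: SnpAssociation, index: GeneIndex, window_bp: int
) -> SnpGeneAssignment:
    """Assign genes to one SNP by the window rule, falling back to flanks.

    A SNP on a chromosome with no protein-coding genes gets an empty
    assignment (callers log the count).
    """
    hits = index.window_hits(snp.chrom, snp.pos, window_bp)
    if hits:
        return SnpGeneAssignment(snp.snp_id, frozenset(hits), RULE_WINDOW)
    flanks = index.nearest_flanks(snp.chrom, snp.pos)
    return SnpGeneAssignment(snp.snp_id, frozenset(flanks), RULE_NEAREST)


def map_all_snps(
    snps: Sequence[SnpAssociation], index: GeneIndex, window_bp: int
) -> list[SnpGeneAssignment]:
    assignments = [map_snp_to_genes(s, index, window_bp) for s in snps]
    unplaced = sum(1 for a in assignments if not a.assigned_genes)
    if unplaced:
        log.warning(
            "%d SNPs lie on chromosomes with no protein-coding genes", unplaced
        )
    return assignments


def select_top_snps(
    snps: Iterable[SnpAssociation], top_count: int, p_threshold: float
) -> list[SnpAssociation]:
    """SNPs with p < p_threshold, most significant first, at most top_count.

    Ties in p are broken by lexicographic snp_id so truncation at the cutoff
    boundary is deterministic.
    """
    passing = [s for s in snps if s.p_value < p_threshold]
    passing.sort(key=lambda s: (s.p_value, s.snp_id))
    return passing[:top_count]


def build_gene_list(
    snps: Sequence[SnpAssociation], index: GeneIndex, window_bp: int
) -> set[str]:
    """Union of per-SNP assignments; a gene hit by several SNPs counts once."""
    out: set[str] = set()
    for a in map_all_snps(snps, index, window_bp):
        out |= a.assigned_genes
    return out


def write_assignments(assignments: Sequence[SnpGeneAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\trule\tgenes\n")
        for a in assignments:
            fh.write(f"{a.snp_id}\t{a.rule_used}\t{','.join(sorted(a.assigned_genes))}\n")
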