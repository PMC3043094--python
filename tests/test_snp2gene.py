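import numpy as np
import pytest

from pdpathways.models import GeneModel, SnpAssociation
from pdpathways.snp2gene import (
    RULE_NEAREST,
    RULE_WINDOW,
    GeneIndex,
    build_gene_list,
    map_snp_to_genes,
    select_top_snps,
)


def snp(snp_id, pos, p=0.5, chrom="chr1"):
    return SnpAssociation(snp_id, chrom, pos, p)


def brute_force_assignment(s, genes, window):
    """All-pairs oracle: interval distance scan over every gene."""
    coding = [g for g in genes if g.is_protein_coding and g.chrom == s.chrom]
    dist = {g.gene_id: max(0, g.start - s.pos, s.pos - g.end) for g in coding}
    hits = {gid for gid, d in dist.items() if d <= window}
    if hits:
        return hits, RULE_WINDOW
    flanks = set()
    left = [g for g in coding if g.end < s.pos]
    if left:
        best = min(s.pos - g.end for g in left)
        flanks.add(min(g.gene_id for g in left if s.pos - g.end == best))
    right = [g for g in coding if g.start > s.pos]
    if right:
        best = min(g.start - s.pos for g in right)
        flanks.add(min(g.gene_id for g in right if g.start - s.pos == best))
    return flanks, RULE_NEAREST


class TestMapSnpToGenes:
    def test_snp_inside_gene(self, three_genes):
        a = map_snp_to_genes(snp("s", 12_000), GeneIndex(three_genes), 20_000)
        assert a.assigned_genes == {"A"} and a.rule_used == RULE_WINDOW

    def test_window_catches_both_sides(self, three_genes):
        # A ends 18 kb away, B starts 17 kb away: both within 20 kb
        a = map_snp_to_genes(snp("s", 33_000), GeneIndex(three_genes), 20_000)
        assert a.assigned_genes == {"A", "B"} and a.rule_used == RULE_WINDOW

    def test_fallback_takes_nearest_on_each_side(self, three_genes):
        # B and C are both 30 kb away, outside the window
        a = map_snp_to_genes(snp("s", 90_000), GeneIndex(three_genes), 20_000)
        assert a.assigned_genes == {"B", "C"} and a.rule_used == RULE_NEAREST

    def test_window_inclusive_at_exact_boundary(self, three_genes):
        a = map_snp_to_genes(snp("s", 35_000), GeneIndex(three_genes), 20_000)
        assert "A" in a.assigned_genes  # distance to A's end is exactly 20000

    def test_chromosome_end_has_one_flank(self, three_genes):
        a = map_snp_to_genes(snp("s", 5_000, chrom="chr1"), GeneIndex(three_genes), 2_000)
        assert a.assigned_genes == {"A"} and a.rule_used == RULE_NEAREST

    def test_absent_chromosome_gives_empty_assignment(self, three_genes):
        a = map_snp_to_genes(snp("s", 5_000, chrom="chrX"), GeneIndex(three_genes), 20_000)
        assert a.assigned_genes == frozenset()

    def test_noncoding_genes_ignored(self):
        genes = [
            GeneModel("nc", "chr1", 900, 1_100, is_protein_coding=False),
            GeneModel("pc", "chr1", 5_000, 6_000),
        ]
        a = map_snp_to_genes(snp("s", 1_000), GeneIndex(genes), 500)
        assert a.assigned_genes == {"pc"} and a.rule_used == RULE_NEAREST

    def test_equidistant_flank_tie_broken_by_gene_id(self):
        genes = [
            GeneModel("gb", "chr1", 100, 200),
            GeneModel("ga", "chr1", 150, 200),  # same end: tie at distance 100
            GeneModel("gz", "chr1", 900, 950),
        ]
        a = map_snp_to_genes(snp("s", 300), GeneIndex(genes), 50)
        assert a.rule_used == RULE_NEAREST
        assert a.assigned_genes == {"ga", "gz"}


class TestSelectTopSnps:
    def test_keeps_only_sub_threshold(self):
        snps = [snp(f"rs{i}", 100 + i, p) for i, p in
                enumerate([0.5, 0.001, 0.02, 0.009, 0.0099, 0.3, 0.8, 0.009, 0.2, 0.7])]
        top = select_top_snps(snps, 5000, 0.01)
        assert {s.snp_id for s in top} == {"rs1", "rs3", "rs4", "rs7"}
        assert [s.p_value for s in top] == sorted(s.p_value for s in top)

    def test_truncates_to_top_count(self):
        snps = [snp(f"rs{i:04d}", i + 1, 0.001 + i * 1e-6) for i in range(6000)]
        top = select_top_snps(snps, 5000, 0.01)
        assert len(top) == 5000
        assert top[0].snp_id == "rs0000"

    def test_tie_at_cutoff_boundary_broken_lexicographically(self):
        snps = [snp("rsB", 1, 0.001), snp("rsA", 2, 0.001), snp("rsC", 3, 0.0001)]
        top = select_top_snps(snps, 2, 0.01)
        assert [s.snp_id for s in top] == ["rsC", "rsA"]

    def test_threshold_is_strict(self):
        assert select_top_snps([snp("a", 1, 0.01)], 10, 0.01) == []


class TestBuildGeneList:
    def test_gene_hit_by_two_snps_counted_once(self, three_genes):
        idx = GeneIndex(three_genes)
        assert build_gene_list([snp("s1", 11_000), snp("s2", 14_000)], idx, 20_000) == {"A"}

    def test_empty_snp_collection(self, three_genes):
        assert build_gene_list([], GeneIndex(three_genes), 20_000) == set()

    def test_union_of_window_and_fallback(self, three_genes):
        idx = GeneIndex(three_genes)
        got = build_gene_list([snp("s1", 12_000), snp("s2", 90_000)], idx, 20_000)
        assert got == {"A", "B", "C"}


def random_instance(rng):
    n_genes = rng.integers(1, 51)
    n_chrom = rng.integers(1, 4)
    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(1, 200_000))
        genes.append(
            GeneModel(f"g{i:03d}", chrom, start, start + int(rng.integers(0, 20_000)),
                      is_protein_coding=bool(rng.random() < 0.9))
        )
    n_snps = int(rng.integers(1, 201))
    snps = [
        snp(f"rs{j}", int(rng.integers(1, 250_000)), chrom=f"chr{rng.integers(1, n_chrom + 1)}")
        for j in range(n_snps)
    ]
    window = int(rng.integers(0, 30_000))
    return genes, snps, window


@pytest.mark.parametrize("seed", range(20))
def test_assignments_match_all_pairs_oracle(seed):
    """Random overlapping annotations: index-based mapping equals brute force."""
    rng = np.random.default_rng(seed)
    genes, snps, window = random_instance(rng)
    index = GeneIndex(genes)
    for s in snps:
        got = map_snp_to_genes(s, index, window)
        want_genes, want_rule = brute_force_assignment(s, genes, window)
        assert set(got.assigned_genes) == want_genes, (s, window)
        if want_genes:
            assert got.rule_used == want_rule


def test_window_enlargement_is_monotone():
    rng = np.random.default_rng(7)
    genes, snps, window = random_instance(rng)
    index = GeneIndex(genes)
    for s in snps:
        small = map_snp_to_genes(s, index, window)
        large = map_snp_to_genes(s, index, window * 2 + 1)
        if small.rule_used == RULE_WINDOW:
            assert small.assigned_genes <= large.assigned_genes


def test_query_subset_of_reference():
    rng = np.random.default_rng(3)
    genes, snps, window = random_instance(rng)
    index = GeneIndex(genes)
    top = select_top_snps(snps, 50, 0.7)
    assert build_gene_list(top, index, window) <= build_gene_list(snps, index, window)
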