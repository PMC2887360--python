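import pytest

from phosphatome import families as fam
from phosphatome.context import (
    CoOrgPair,
    find_coorganized_pairs,
    find_local_synteny,
    gene_distance,
)
from phosphatome.families import FamilyAssignment, classify_genome
from phosphatome.genome_io import Gene, Genome
from phosphatome.orthology import make_pair


def _genome(gid, n, reverse=False):
    genes = []
    order = range(n - 1, -1, -1) if reverse else range(n)
    for i, _ in enumerate(order):
        genes.append(
            Gene(f"{gid}_{i:03d}", 1 + i * 100, i * 100 + 90, "+", i, "MKVA")
        )
    return Genome(gid, genes)


def _assign(genome, families_by_index):
    out = []
    for g in genome:
        family = families_by_index.get(g.index, fam.OTHER)
        out.append(FamilyAssignment(locus_tag=g.locus_tag, family=family))
    return out


class TestGeneDistance:
    def test_adjacent_genes_have_distance_zero(self):
        g = _genome("g", 10)
        assert gene_distance(g, "g_007", "g_008") == 0

    def test_five_intervening_genes(self):
        g = _genome("g", 10)
        assert gene_distance(g, "g_002", "g_008") == 5

    def test_same_locus_rejected(self):
        g = _genome("g", 3)
        with pytest.raises(ValueError, match="undefined"):
            gene_distance(g, "g_001", "g_001")

    def test_unknown_locus_rejected(self):
        g = _genome("g", 3)
        with pytest.raises(KeyError):
            gene_distance(g, "g_001", "nope")


class TestCoOrganization:
    @pytest.mark.parametrize(
        "pp_index,expected_distance,found",
        [
            (11, 0, True),  # direct neighbors
            (13, 2, True),
            (16, 5, True),  # threshold boundary
            (17, 6, False),  # one beyond the threshold
        ],
    )
    def test_distance_threshold(self, pp_index, expected_distance, found):
        g = _genome("g", 30)
        assigns = _assign(g, {10: fam.ELK, pp_index: fam.PP2C})
        pairs = find_coorganized_pairs(g, assigns, max_distance=5)
        if found:
            assert len(pairs) == 1
            assert pairs[0].distance == expected_distance
            assert pairs[0].direct == (expected_distance == 0)
        else:
            assert pairs == []

    def test_invariant_under_genome_reversal(self):
        g = _genome("g", 30)
        assigns = _assign(g, {10: fam.ELK, 13: fam.PP2C})
        forward = find_coorganized_pairs(g, assigns)
        # reverse the gene order: same loci, mirrored indices
        rev_genes = [
            Gene(gene.locus_tag, 1 + (29 - gene.index) * 100,
                 (29 - gene.index) * 100 + 90, gene.strand, 29 - gene.index,
                 gene.protein)
            for gene in g
        ]
        rev = Genome("g", sorted(rev_genes, key=lambda x: x.start))
        backward = find_coorganized_pairs(rev, assigns)
        assert {(p.kinase_locus, p.pp_locus, p.distance) for p in forward} == {
            (p.kinase_locus, p.pp_locus, p.distance) for p in backward
        }

    def test_raising_max_distance_is_monotone(self):
        g = _genome("g", 30)
        assigns = _assign(g, {5: fam.ELK, 8: fam.PP2C, 20: fam.ELK, 21: fam.SPOIIE})
        near = {
            (p.kinase_locus, p.pp_locus)
            for p in find_coorganized_pairs(g, assigns, max_distance=1)
        }
        far = {
            (p.kinase_locus, p.pp_locus)
            for p in find_coorganized_pairs(g, assigns, max_distance=5)
        }
        assert near <= far

    def test_ptpz_not_counted_as_opposing_phosphatase(self):
        g = _genome("g", 10)
        assigns = _assign(g, {3: fam.ELK, 4: fam.PTPZ})
        assert find_coorganized_pairs(g, assigns) == []

    def test_direct_flag_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CoOrgPair("k", "p", 2, True)

    def test_planted_pairs_recovered_exactly(self, default_sim):
        for gid, genome in default_sim.genomes.items():
            assigns = classify_genome(genome, default_sim.calls[gid])
            detected = {
                (p.kinase_locus, p.pp_locus, p.distance)
                for p in find_coorganized_pairs(genome, assigns)
            }
            assert detected == set(default_sim.truth.coorg[gid])


class TestLocalSynteny:
    def _setup(self, offsets_b, n=40):
        """Anchor PP pair at index 10/10 plus neighbor ortholog pairs at
        offsets 1..k in genome A and ``offsets_b`` in genome B."""
        ga, gb = _genome("ga", n), _genome("gb", n)
        assigns_a = _assign(ga, {10: fam.PP2C})
        assigns_b = _assign(gb, {10: fam.PP2C})
        pairs = [make_pair(("ga", "ga_010"), ("gb", "gb_010"), 900, 1e-80)]
        for k, off_b in enumerate(offsets_b, start=1):
            pairs.append(
                make_pair(
                    ("ga", f"ga_{10 + k:03d}"),
                    ("gb", f"gb_{10 + off_b:03d}"),
                    800,
                    1e-60,
                )
            )
        return ga, gb, assigns_a, assigns_b, pairs

    def test_conserved_ordered_neighborhood_is_a_block(self):
        ga, gb, aa, ab, pairs = self._setup([1, 2, 3])
        blocks = find_local_synteny(ga, gb, aa, ab, pairs, window=5, min_conserved=2)
        assert len(blocks) == 1
        assert blocks[0].orientation == "same"
        assert blocks[0].n_conserved == 3

    def test_reversed_neighborhood_is_a_block(self):
        ga, gb, aa, ab, pairs = self._setup([-1, -2, -3])
        blocks = find_local_synteny(ga, gb, aa, ab, pairs)
        assert len(blocks) == 1
        assert blocks[0].orientation == "reversed"

    def test_scrambled_neighbor_order_is_rejected(self):
        ga, gb, aa, ab, pairs = self._setup([2, 1, 3])
        assert find_local_synteny(ga, gb, aa, ab, pairs) == []

    def test_anchor_without_neighbors_is_no_block(self):
        ga, gb, aa, ab, pairs = self._setup([])
        assert find_local_synteny(ga, gb, aa, ab, pairs) == []

    def test_non_phosphatase_anchor_ignored(self):
        ga, gb, aa, ab, pairs = self._setup([1, 2])
        aa = _assign(ga, {10: fam.ELK})  # anchor is not a phosphatase
        assert find_local_synteny(ga, gb, aa, ab, pairs) == []

    def test_neighbors_outside_window_do_not_count(self):
        ga, gb, aa, ab, pairs = self._setup([1, 2])
        blocks = find_local_synteny(ga, gb, aa, ab, pairs, window=5)
        assert len(blocks) == 1
        assert find_local_synteny(ga, gb, aa, ab, pairs, window=0) == []

    def test_planted_block_recovered_from_ground_truth_pairs(self, default_sim):
        gids = sorted(default_sim.genomes)[:2]
        ga, gb = (default_sim.genomes[g] for g in gids)
        aa = classify_genome(ga, default_sim.calls[gids[0]])
        ab = classify_genome(gb, default_sim.calls[gids[1]])
        pairs = [
            make_pair(*sorted(p), 900, 1e-80)
            for p in default_sim.truth.pairs_between(*gids)
        ]
        blocks = find_local_synteny(ga, gb, aa, ab, pairs, window=5, min_conserved=2)
        truth_anchors = {
            tuple(m[1] for m in b["anchor"]) for b in default_sim.truth.synteny
        }
        assert {(b.anchor.locus_a, b.anchor.locus_b) for b in blocks} == truth_anchors
        for b in blocks:
            assert b.n_conserved == default_sim.config.synteny_neighbors
            assert b.orientation == "same"
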