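import math
import random

import pytest
from Bio.Align import substitution_matrices

from phosphatome.genome_io import Gene, Genome
from phosphatome.orthology import (
    AlignmentScoringParams,
    align_local,
    build_ortholog_groups,
    evalue,
    local_score,
    make_pair,
    reciprocal_best_hits,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_oracle(a: str, b: str, gap_open=11.0, gap_extend=1.0) -> float:
    """Textbook Gotoh local-alignment DP (quadratic space, no tricks).

    A gap of length k costs ``gap_open + k * gap_extend``, matching the
    package's scoring convention.
    """
    neg = -math.inf
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]
    F = [[neg] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    first_gap = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - first_gap, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first_gap, F[i - 1][j] - gap_extend)
            sub = H[i - 1][j - 1] + BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _genome(gid, proteins):
    genes = [
        Gene(f"{gid.lower()}{i+1}", 1 + i * 1000, i * 1000 + 3 * len(p), "+", i, p)
        for i, p in enumerate(proteins)
    ]
    return Genome(gid, genes)


class TestAlignLocal:
    def test_identity_score_is_diagonal_sum(self):
        # BLOSUM62 diagonal: A=4, C=9, D=6, E=5, F=6
        score, region = align_local("ACDEF", "ACDEF")
        assert score == 30
        assert region == (0, 5, 0, 5)

    def test_all_negative_pair_scores_zero(self):
        score, region = align_local("A", "W")
        assert score == 0 and region == (0, 0, 0, 0)

    def test_symmetry(self):
        a, b = "MKVLINAAGDEW", "MKVLLNAAGQEW"
        assert align_local(a, b)[0] == align_local(b, a)[0]

    def test_alphabet_validated(self):
        with pytest.raises(ValueError, match="outside alphabet"):
            align_local("ACJ", "ACD")

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = random.Random(42)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(60):
            a = "".join(rng.choice(aa) for _ in range(rng.randint(1, 30)))
            b = "".join(rng.choice(aa) for _ in range(rng.randint(1, 30)))
            assert local_score(a, b) == sw_oracle(a, b), (a, b)


class TestEvalue:
    def test_zero_score_gives_kmn(self):
        p = AlignmentScoringParams()
        assert evalue(0, 100, 200, p) == pytest.approx(p.karlin_k * 100 * 200)

    def test_hand_computed_closed_form(self):
        # K*m*n*exp(-lambda*S) at K=0.041, m=n=100, lambda=0.267, S=100
        e = evalue(100, 100, 100, AlignmentScoringParams())
        assert e == pytest.approx(0.041 * 1e4 * math.exp(-26.7))
        assert e == pytest.approx(1.05e-9, rel=0.05)

    def test_linear_in_target_length(self):
        e1 = evalue(50, 100, 100)
        e2 = evalue(50, 100, 200)
        assert e2 == pytest.approx(2 * e1)

    def test_monotone_decreasing_in_score(self):
        assert evalue(60, 100, 100) < evalue(50, 100, 100)

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            evalue(-1, 10, 10)


def _distinct_long_proteins(n, length=80, seed=0):
    rng = random.Random(seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return ["".join(rng.choice(aa) for _ in range(length)) for _ in range(n)]


class TestReciprocalBestHits:
    def test_identical_proteomes_pair_every_protein(self):
        prots = _distinct_long_proteins(3)
        ga, gb = _genome("GA", prots), _genome("GB", prots)
        pairs = reciprocal_best_hits(ga, gb)
        assert len(pairs) == 3
        assert {(p.locus_a, p.locus_b) for p in pairs} == {
            ("ga1", "gb1"), ("ga2", "gb2"), ("ga3", "gb3"),
        }
        assert all(p.evalue <= 1e-10 for p in pairs)

    def test_asymmetric_best_hit_is_rejected(self):
        base = _distinct_long_proteins(1, length=120, seed=3)[0]
        mutated = "W" * 6 + base[6:]  # a1: weaker copy of a2
        # GA = {a1: mutated, a2: base}; GB = {b1: base}
        ga = _genome("GA", [mutated, base])
        gb = _genome("GB", [base])
        pairs = reciprocal_best_hits(ga, gb)
        # b1's best is a2 (exact), so a1 gets no pair
        assert {(p.locus_a, p.locus_b) for p in pairs} == {("ga2", "gb1")}

    def test_symmetric_under_genome_swap(self):
        prots = _distinct_long_proteins(4, seed=5)
        ga, gb = _genome("GA", prots[:2]), _genome("GB", prots[:2])
        ab = reciprocal_best_hits(ga, gb)
        ba = reciprocal_best_hits(gb, ga)
        assert {p.key() for p in ab} == {p.key() for p in ba}

    def test_raising_cutoff_never_removes_pairs(self):
        prots = _distinct_long_proteins(3, seed=9)
        ga, gb = _genome("GA", prots), _genome("GB", prots)
        strict = {p.key() for p in reciprocal_best_hits(ga, gb, cutoff=1e-40)}
        loose = {p.key() for p in reciprocal_best_hits(ga, gb, cutoff=1e-10)}
        assert strict <= loose

    def test_self_comparison_rejected(self):
        g = _genome("GA", _distinct_long_proteins(2))
        with pytest.raises(ValueError, match="different genomes"):
            reciprocal_best_hits(g, g)


class TestOrthologGroups:
    def test_chain_across_three_genomes_forms_triplet(self):
        pairs = [
            make_pair(("A", "a1"), ("B", "b1"), 500, 1e-50),
            make_pair(("B", "b1"), ("C", "c1"), 480, 1e-45),
        ]
        groups = build_ortholog_groups(pairs)
        assert len(groups) == 1
        assert groups[0].members == [("A", "a1"), ("B", "b1"), ("C", "c1")]

    def test_disjoint_pairs_stay_separate(self):
        pairs = [
            make_pair(("A", "a1"), ("B", "b1"), 500, 1e-50),
            make_pair(("A", "a2"), ("C", "c1"), 480, 1e-45),
        ]
        assert len(build_ortholog_groups(pairs)) == 2

    def test_same_genome_conflict_drops_weakest_edge(self):
        pairs = [
            make_pair(("A", "a1"), ("B", "b1"), 500, 1e-50),
            make_pair(("A", "a2"), ("B", "b1"), 300, 1e-20),
        ]
        groups = build_ortholog_groups(pairs)
        assert len(groups) == 1
        assert groups[0].members == [("A", "a1"), ("B", "b1")]


class TestSyntheticRecovery:
    def test_planted_orthologs_recovered_without_false_pairs(self, small_sim):
        gids = sorted(small_sim.genomes)
        ga, gb = (small_sim.genomes[g] for g in gids)
        pairs = reciprocal_best_hits(ga, gb)
        truth = small_sim.truth.pairs_between(*gids)
        found = {p.key() for p in pairs}
        assert truth <= found
        assert not (found - truth)

    def test_seed_filter_agrees_with_exhaustive_search(self, small_sim):
        gids = sorted(small_sim.genomes)
        ga, gb = (small_sim.genomes[g] for g in gids)
        exhaustive = {p.key() for p in reciprocal_best_hits(ga, gb)}
        seeded = {
            p.key()
            for p in reciprocal_best_hits(ga, gb, seed_filter=(4, 4))
        }
        assert seeded == exhaustive
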