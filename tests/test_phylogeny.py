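import numpy as np
import pytest

from phosphatome.phylogeny import (
    DistanceMatrix,
    MultipleAlignment,
    NewickParseError,
    bootstrap_support,
    msa_pdistance,
    neighbor_joining,
    pairwise_distance_matrix,
    parse_newick,
    progressive_msa,
    write_newick,
)


def random_additive_matrix(n, rng):
    """Path-distance matrix of a random binary tree with branch lengths in
    [0.1, 1] — the independent oracle for NJ consistency."""
    D = np.zeros((n, n))
    nodes = {i: {i: 0.0} for i in range(n)}
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[int(i)], active[int(j)]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        for leaf_a, da in nodes[a].items():
            for leaf_b, db in nodes[b].items():
                D[leaf_a, leaf_b] = D[leaf_b, leaf_a] = da + la + db + lb
        merged = {leaf: d + la for leaf, d in nodes[a].items()}
        merged.update({leaf: d + lb for leaf, d in nodes[b].items()})
        nodes[nxt] = merged
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return D


class TestPairwiseDistances:
    def test_identical_sequences_distance_zero(self):
        dm = pairwise_distance_matrix(["MKVA", "MKVA"])
        assert dm.values[0, 1] == 0.0

    def test_single_mismatch_quarter(self):
        dm = pairwise_distance_matrix(["AAAA", "AAAT"])
        assert dm.values[0, 1] == pytest.approx(0.25)

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance_matrix(["MKVA"])

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(("a", "b"), np.array([[1.0, 1.0], [1.0, 0.0]]))


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # path distances of ((A:1,B:2):1,(C:3,D:4))
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C", "D"), D))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        rec = tree.distance_matrix()
        order = [rec.labels.index(l) for l in ("A", "B", "C", "D")]
        assert np.abs(rec.values[np.ix_(order, order)] - D).max() < 1e-12

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), D))
        lengths = {l.label: l.length for l in tree.root.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_equidistant_taxa_get_zero_internal_edge_deterministically(self):
        D = np.ones((4, 4)) - np.eye(4)
        labels = ("A", "B", "C", "D")
        t1 = neighbor_joining(DistanceMatrix(labels, D))
        t2 = neighbor_joining(DistanceMatrix(labels, D))
        assert write_newick(t1) == write_newick(t2)
        # internal edge length 0: path distances all remain 1
        rec = t1.distance_matrix()
        assert np.abs(rec.values - D).max() < 1e-12

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("a", "b"), np.zeros((2, 2))))

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            D = random_additive_matrix(n, rng)
            labels = tuple(f"t{i}" for i in range(n))
            tree = neighbor_joining(DistanceMatrix(labels, D))
            rec = tree.distance_matrix()
            order = [rec.labels.index(l) for l in labels]
            assert np.abs(rec.values[np.ix_(order, order)] - D).max() < 1e-9

    def test_agrees_with_scikit_bio_on_additive_matrices(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 8
            D = random_additive_matrix(n, rng)
            labels = [f"t{i}" for i in range(n)]
            ours = neighbor_joining(DistanceMatrix(tuple(labels), D))
            theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
            their_biparts = set()
            for node in theirs.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < n - 1:
                    other = frozenset(labels) - side
                    their_biparts.add(
                        min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
                    )
            assert ours.bipartitions() == their_biparts


class TestProgressiveMsa:
    def test_two_sequences_is_pairwise_alignment(self):
        msa = progressive_msa(["MKVAAG", "MKVG"])
        assert len(msa) == 2
        assert msa.ungapped(0) == "MKVAAG" and msa.ungapped(1) == "MKVG"

    def test_identical_sequences_align_gap_free(self):
        msa = progressive_msa(["MKVA"] * 3)
        assert all(row == "MKVA" for row in msa.rows)

    def test_rows_ungap_to_inputs_on_random_sets(self):
        rng = np.random.default_rng(11)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(5):
            k = int(rng.integers(3, 7))
            seqs = [
                "".join(aa[rng.integers(0, 20, size=int(rng.integers(10, 40)))])
                for _ in range(k)
            ]
            msa = progressive_msa(seqs)
            assert [msa.ungapped(i) for i in range(k)] == seqs

    def test_alignment_rows_must_have_equal_length(self):
        with pytest.raises(ValueError, match="equal length"):
            MultipleAlignment(("a", "b"), ("MK-", "MK"))


def _two_clade_alignment(n_per_clade=4, ncols=120, seed=0):
    """Two internally identical, mutually very different clades."""
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    clade_a = "".join(aa[rng.integers(0, 20, size=ncols)])
    clade_b = "".join(aa[rng.integers(0, 20, size=ncols)])
    rows, labels = [], []
    for i in range(n_per_clade):
        # one private substitution per row so distances are not all zero
        row = list(clade_a)
        row[i] = "A" if row[i] != "A" else "C"
        rows.append("".join(row))
        labels.append(f"a{i}")
    for i in range(n_per_clade):
        row = list(clade_b)
        row[i] = "A" if row[i] != "A" else "C"
        rows.append("".join(row))
        labels.append(f"b{i}")
    return MultipleAlignment(tuple(labels), tuple(rows))


class TestBootstrap:
    def test_single_replicate_supports_are_all_or_nothing(self):
        msa = _two_clade_alignment()
        tree = bootstrap_support(msa, n_replicates=1, seed=4)
        supports = [
            node.support
            for node in _walk(tree.root)
            if node.support is not None
        ]
        assert supports and set(supports) <= {0, 100}

    def test_same_seed_reproduces_supports(self):
        msa = _two_clade_alignment()
        t1 = bootstrap_support(msa, n_replicates=20, seed=9)
        t2 = bootstrap_support(msa, n_replicates=20, seed=9)
        assert write_newick(t1) == write_newick(t2)

    def test_well_separated_clades_get_high_central_support(self):
        msa = _two_clade_alignment()
        tree = bootstrap_support(msa, n_replicates=50, seed=1)
        central = frozenset({"a0", "a1", "a2", "a3"})
        support = _support_of(tree, central)
        assert support is not None and support >= 90

    def test_supports_bounded(self):
        msa = _two_clade_alignment(seed=2)
        tree = bootstrap_support(msa, n_replicates=25, seed=3)
        for node in _walk(tree.root):
            if node.support is not None:
                assert 0 <= node.support <= 100


def _walk(node):
    yield node
    for c in node.children:
        yield from _walk(c)


def _support_of(tree, side):
    all_taxa = tree.taxa
    for node in _walk(tree.root):
        if node.children and node.support is not None:
            labels = node.leaf_labels()
            if labels == side or labels == all_taxa - side:
                return node.support
    return None


class TestNewick:
    def test_three_taxon_format(self):
        D = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), D))
        assert write_newick(tree) == "(A:1.000000,B:1.000000,C:1.000000);"

    def test_round_trip_preserves_topology_lengths_supports(self):
        msa = _two_clade_alignment(seed=5)
        tree = bootstrap_support(msa, n_replicates=10, seed=5)
        text = write_newick(tree)
        back = parse_newick(text)
        assert back.bipartitions() == tree.bipartitions()
        assert write_newick(back) == text

    def test_dendropy_reads_our_newick(self):
        dendropy = pytest.importorskip("dendropy")
        msa = _two_clade_alignment(seed=6)
        tree = bootstrap_support(msa, n_replicates=5, seed=6)
        dt = dendropy.Tree.get(data=write_newick(tree), schema="newick")
        assert {t.taxon.label for t in dt.leaf_node_iter()} == set(tree.taxa)

    def test_support_hidden_below_threshold_in_rendering_only(self):
        msa = _two_clade_alignment(seed=7)
        tree = bootstrap_support(msa, n_replicates=10, seed=7)
        full = write_newick(tree)
        pruned = write_newick(tree, hide_support_below=101)
        # hiding is rendering-only: the tree still carries all supports
        assert any(n.support is not None for n in _walk(tree.root))
        assert len(pruned) <= len(full)

    @pytest.mark.parametrize("bad", ["(A,B;", "(A,(B,C);", "A:1.0", "(A,B))C;"])
    def test_malformed_newick_rejected(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)


def test_msa_pdistance_ignores_gap_gap_columns():
    msa = MultipleAlignment(("a", "b", "c"), ("AA--", "AA--", "AAGG"))
    dm = msa_pdistance(msa)
    assert dm.get("a", "b") == 0.0  # gap-gap columns excluded entirely
    assert dm.get("a", "c") == pytest.approx(0.5)  # gaps vs residues differ
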