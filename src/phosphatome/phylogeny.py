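"""Distance-based phylogeny: pairwise distances, progressive MSA,
Saitou-Nei neighbor joining, and column-bootstrap support values.

The workflow mirrors the classical ClustalX + NJ + bootstrap recipe:

1. pairwise global alignment (BLOSUM62, affine gaps) gives p-distances
   ``d = 1 - identities / aligned columns`` (gap-gap columns excluded,
   gap-vs-residue columns count as mismatches), optionally Kimura-corrected;
2. a progressive multiple alignment is built over an NJ guide tree by
   profile-profile alignment (mean-of-pairs BLOSUM62 column scores, affine
   gaps);
3. neighbor joining on the distance matrix yields an unrooted tree whose
   root node is the final trifurcation; joins pick the minimum of the
   standard Q criterion, ties breaking toward the smallest taxon-label
   pair, and negative branch lengths are clamped to zero (flagged);
4. bootstrap support resamples alignment columns with replacement,
   recomputes distances + NJ per replicate, and scores each internal
   bipartition of the reference tree as the percentage of replicates
   containing it.

Trees serialize to Newick with branch lengths at 6 decimals and bootstrap
supports as internal node labels; parsing restores topology, lengths and
supports exactly (write-parse round trip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .orthology import AlignmentScoringParams, _make_aligner

GAP = "-"


# ---------------------------------------------------------------------------
# Distance matrix


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def _pair_identity_fraction(row_a: str, row_b: str) -> tuple[int, int]:
    """(identities, comparable columns) over an aligned pair; gap-gap
    columns are excluded, gap-vs-residue counts as a comparable mismatch."""
    ident = comparable = 0
    for x, y in zip(row_a, row_b):
        if x == GAP and y == GAP:
            continue
        comparable += 1
        if x == y and x != GAP:
            ident += 1
    return ident, comparable


def kimura_correct(p: float) -> float:
    """Kimura's (1983) empirical protein-distance correction."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        # saturation guard: cap at the largest representable distance
        return 10.0
    return -math.log(arg)


def pairwise_distance_matrix(
    seqs: Sequence[str],
    labels: Sequence[str] | None = None,
    params: AlignmentScoringParams | None = None,
    kimura: bool = False,
) -> DistanceMatrix:
    """p-distances from global affine-gap alignment of every sequence pair."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    labels = tuple(labels) if labels is not None else tuple(
        f"seq{i}" for i in range(len(seqs))
    )
    if len(labels) != len(seqs):
        raise ValueError("labels/sequences length mismatch")
    params = params or AlignmentScoringParams()
    aligner = _make_aligner(params, "global")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(seqs[i], seqs[j])[0]
            row_a, row_b = str(aln[0]), str(aln[1])
            ident, comparable = _pair_identity_fraction(row_a, row_b)
            p = 1.0 - ident / comparable if comparable else 1.0
            d[i, j] = d[j, i] = kimura_correct(p) if kimura else p
    return DistanceMatrix(labels=labels, values=d)


# ---------------------------------------------------------------------------
# Tree model


@dataclass
class TreeNode:
    label: str | None = None  # taxon label on leaves
    length: float = 0.0  # branch length to parent
    support: int | None = None  # bootstrap % on internal nodes
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(l.label for l in self.leaves())


@dataclass
class PhyloTree:
    """Unrooted tree stored with its root at the final NJ trifurcation."""

    root: TreeNode
    negative_lengths_clamped: bool = False

    @property
    def taxa(self) -> frozenset[str]:
        return self.root.leaf_labels()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the canonical (smaller or
        lexicographically first) side of the leaf-label split."""
        all_taxa = self.taxa
        out: set[frozenset[str]] = set()
        def walk(node: TreeNode) -> None:
            for child in node.children:
                side = child.leaf_labels()
                if 1 < len(side) < len(all_taxa) - 1:
                    out.add(_canonical_side(side, all_taxa))
                walk(child)
        walk(self.root)
        return out

    def distance_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path distances (sum of branch lengths)."""
        labels = tuple(sorted(self.taxa))
        index = {t: i for i, t in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode, depth: float, acc: dict[str, float]) -> dict[str, float]:
            if node.is_leaf:
                acc[node.label] = depth
                return acc
            child_maps = []
            for c in node.children:
                child_maps.append(walk(c, c.length, {}))
            # combine: cross distances between different children
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for ta, da in child_maps[a].items():
                        for tb, db in child_maps[b].items():
                            dist = da + db
                            d[index[ta], index[tb]] = dist
                            d[index[tb], index[ta]] = dist
            for cm in child_maps:
                for t, dist in cm.items():
                    acc[t] = dist + depth
            return acc

        walk(self.root, 0.0, {})
        return DistanceMatrix(labels=labels, values=d)


def _canonical_side(side: frozenset[str], all_taxa: frozenset[str]) -> frozenset[str]:
    other = all_taxa - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Joins minimize ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``; among equal-Q
    candidates the pair with the smallest sorted label pair is taken.
    Negative branch lengths are clamped to 0 and flagged on the tree.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: dict[str, TreeNode] = {
        label: TreeNode(label=label) for label in dm.labels
    }
    # sort keys: smallest label pair wins ties deterministically
    dist: dict[frozenset[str], float] = {}
    active = sorted(dm.labels)
    for i, a in enumerate(dm.labels):
        for j in range(i + 1, len(dm.labels)):
            dist[frozenset((a, dm.labels[j]))] = float(dm.values[i, j])

    clamped = False
    join_counter = 0

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best_q = math.inf
        best_pair: tuple[str, str] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                pair = tuple(sorted((a, b)))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and (best_pair is None or pair < best_pair)
                ):
                    best_q = q
                    best_pair = pair
        a, b = best_pair
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = d(a, b) - la
        if la < 0 or lb < 0:
            clamped = clamped or la < -1e-12 or lb < -1e-12
            la, lb = max(la, 0.0), max(lb, 0.0)
        join_counter += 1
        new_label = f"@join{join_counter}"
        node = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length = la
        nodes[b].length = lb
        nodes[new_label] = node
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_label, c))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = sorted(set(active) - {a, b} | {new_label})

    # resolve the final three nodes around a central trifurcation
    x, y, z = active
    lx = 0.5 * (d(x, y) + d(x, z) - d(y, z))
    ly = 0.5 * (d(x, y) + d(y, z) - d(x, z))
    lz = 0.5 * (d(x, z) + d(y, z) - d(x, y))
    for lab, length in ((x, lx), (y, ly), (z, lz)):
        if length < 0:
            clamped = clamped or length < -1e-12
            length = 0.0
        nodes[lab].length = max(length, 0.0)
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    return PhyloTree(root=root, negative_lengths_clamped=clamped)


# ---------------------------------------------------------------------------
# Multiple alignment


@dataclass
class MultipleAlignment:
    labels: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("aligned rows must have equal length")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def columns(self, indices: Sequence[int]) -> "MultipleAlignment":
        rows = tuple("".join(r[i] for i in indices) for r in self.rows)
        return MultipleAlignment(labels=self.labels, rows=rows)


def _blosum_with_gap(params: AlignmentScoringParams) -> tuple[np.ndarray, dict[str, int]]:
    mat = substitution_matrices.load(params.matrix_name)
    alphabet = str(mat.alphabet)
    idx = {c: i for i, c in enumerate(alphabet)}
    n = len(alphabet)
    full = np.zeros((n + 1, n + 1))
    full[:n, :n] = np.asarray(mat)
    idx[GAP] = n  # gap scores 0 against everything in column scoring
    return full, idx


def _profile_counts(rows: Sequence[str], idx: dict[str, int]) -> np.ndarray:
    ncols = len(rows[0])
    counts = np.zeros((ncols, max(idx.values()) + 1))
    for r in rows:
        for c, ch in enumerate(r):
            counts[c, idx[ch]] += 1
    return counts


def _align_profiles(
    rows_a: Sequence[str],
    rows_b: Sequence[str],
    params: AlignmentScoringParams,
) -> tuple[list[str], list[str]]:
    """Global affine-gap profile-profile alignment (mean-of-pairs scores)."""
    mat, idx = _blosum_with_gap(params)
    ca = _profile_counts(rows_a, idx)
    cb = _profile_counts(rows_b, idx)
    la, lb = ca.shape[0], cb.shape[0]
    na, nb = len(rows_a), len(rows_b)
    S = (ca @ mat @ cb.T) / (na * nb)  # column-vs-column mean pair score

    go = -(params.gap_open + params.gap_extend)
    ge = -params.gap_extend
    NEG = -1e18
    # three-state affine DP: M match, X gap in B (A column vs gaps),
    # Y gap in A
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = go + ge * (j - 1)
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_x[2:, 0] = 1  # leading gap runs extend themselves
    ptr_y[0, 2:] = 2
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Si = S[i - 1]
        for j in range(1, lb + 1):
            # M: consume one column from each
            best = Mi1[j - 1]; arg = 0
            if Xi1[j - 1] > best:
                best = Xi1[j - 1]; arg = 1
            if Yi1[j - 1] > best:
                best = Yi1[j - 1]; arg = 2
            M[i, j] = best + Si[j - 1]
            ptr_m[i, j] = arg
            # X: A column against gap
            bx = Mi1[j] + go; ax = 0
            if Xi1[j] + ge > bx:
                bx = Xi1[j] + ge; ax = 1
            if Yi1[j] + go > bx:
                bx = Yi1[j] + go; ax = 2
            X[i, j] = bx
            ptr_x[i, j] = ax
            # Y: B column against gap
            by = M[i, j - 1] + go; ay = 0
            if X[i, j - 1] + go > by:
                by = X[i, j - 1] + go; ay = 1
            if Y[i, j - 1] + ge > by:
                by = Y[i, j - 1] + ge; ay = 2
            Y[i, j] = by
            ptr_y[i, j] = ay

    # traceback from the best end state
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append("M")
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("X")
            state = int(ptr_x[i, j])
            i -= 1
        else:
            ops.append("Y")
            state = int(ptr_y[i, j])
            j -= 1
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ai = bi = 0
    for op in ops:
        if op == "M":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ai]
            for k, r in enumerate(rows_b):
                out_b[k] += r[bi]
            ai += 1
            bi += 1
        elif op == "X":
            for k, r in enumerate(rows_a):
                out_a[k] += r[ai]
            for k in range(len(rows_b)):
                out_b[k] += GAP
            ai += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
            for k, r in enumerate(rows_b):
                out_b[k] += r[bi]
            bi += 1
    return out_a, out_b


def progressive_msa(
    seqs: Sequence[str],
    labels: Sequence[str] | None = None,
    params: AlignmentScoringParams | None = None,
) -> MultipleAlignment:
    """Progressive multiple alignment over an NJ guide tree.

    Two sequences reduce to their pairwise global alignment.  Otherwise an
    NJ guide tree is built on pairwise p-distances and profiles are merged
    leaf-to-root; the root trifurcation merges its children left to right.
    Deterministic for fixed inputs.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    params = params or AlignmentScoringParams()
    labels = tuple(labels) if labels is not None else tuple(
        f"seq{i}" for i in range(len(seqs))
    )
    by_label = dict(zip(labels, seqs))
    if len(seqs) == 2:
        rows_a, rows_b = _align_profiles([seqs[0]], [seqs[1]], params)
        return MultipleAlignment(labels=labels, rows=(rows_a[0], rows_b[0]))

    dm = pairwise_distance_matrix(seqs, labels, params)
    guide = neighbor_joining(dm)

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.label], [by_label[node.label]]
        child_results = [merge(c) for c in node.children]
        acc_labels, acc_rows = child_results[0]
        for nxt_labels, nxt_rows in child_results[1:]:
            rows_a, rows_b = _align_profiles(acc_rows, nxt_rows, params)
            acc_labels = acc_labels + nxt_labels
            acc_rows = rows_a + rows_b
        return acc_labels, acc_rows

    out_labels, out_rows = merge(guide.root)
    order = {lab: i for i, lab in enumerate(out_labels)}
    rows = tuple(out_rows[order[lab]] for lab in labels)
    return MultipleAlignment(labels=labels, rows=rows)


# ---------------------------------------------------------------------------
# Bootstrap


def msa_pdistance(msa: MultipleAlignment, kimura: bool = False) -> DistanceMatrix:
    """Pairwise p-distance over alignment columns (pairwise deletion of
    gap-gap columns; gap-vs-residue counts as a difference)."""
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident, comparable = _pair_identity_fraction(msa.rows[i], msa.rows[j])
            p = 1.0 - ident / comparable if comparable else 1.0
            d[i, j] = d[j, i] = kimura_correct(p) if kimura else p
    return DistanceMatrix(labels=msa.labels, values=d)


def bootstrap_support(
    msa: MultipleAlignment,
    n_replicates: int = 1000,
    seed: int = 0,
    kimura: bool = False,
) -> PhyloTree:
    """Reference NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate using an
    independent RNG stream per replicate index (so results do not depend on
    evaluation order); the support of each internal bipartition of the
    reference tree is the percentage of replicate trees containing it.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if len(msa) < 3:
        raise ValueError("need at least 3 sequences")
    ref = neighbor_joining(msa_pdistance(msa, kimura))
    all_taxa = ref.taxa
    ref_biparts = ref.bipartitions()
    counts = {bp: 0 for bp in ref_biparts}
    ncols = msa.n_columns
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        idx = rng.integers(0, ncols, size=ncols)
        rep_msa = msa.columns(list(idx))
        rep_tree = neighbor_joining(msa_pdistance(rep_msa, kimura))
        rep_biparts = rep_tree.bipartitions()
        for bp in ref_biparts:
            if bp in rep_biparts:
                counts[bp] += 1

    def annotate(node: TreeNode) -> None:
        for child in node.children:
            side = child.leaf_labels()
            if 1 < len(side) < len(all_taxa) - 1:
                bp = _canonical_side(side, all_taxa)
                child.support = round(100 * counts[bp] / n_replicates)
            annotate(child)

    annotate(ref.root)
    return ref


# ---------------------------------------------------------------------------
# Newick


def write_newick(
    tree: PhyloTree,
    decimals: int = 6,
    hide_support_below: int | None = None,
) -> str:
    """Serialize to Newick; supports appear as internal node labels.

    ``hide_support_below`` omits supports under a threshold from the
    rendering (the underlying tree keeps them); by default all supports
    are written so that write/parse round-trips exactly.
    """

    def fmt(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            body = node.label
        else:
            inner = ",".join(fmt(c, False) for c in node.children)
            label = ""
            if node.support is not None and not (
                hide_support_below is not None
                and node.support < hide_support_below
            ):
                label = str(node.support)
            body = f"({inner}){label}"
        if top:
            return body
        return f"{body}:{node.length:.{decimals}f}"

    return fmt(tree.root, True) + ";"


class NewickParseError(ValueError):
    pass


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string written by :func:`write_newick`."""
    text = text.strip()
    if not text.endswith(";"):
        raise NewickParseError("missing terminal ';'")
    s = text[:-1]
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise NewickParseError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NewickParseError(f"unexpected character {s[pos]!r} at {pos}")
            label = _read_token()
            if label:
                node.support = int(round(float(label)))
        else:
            label = _read_token()
            if not label:
                raise NewickParseError(f"expected leaf label at position {pos}")
            node.label = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            token = _read_token()
            try:
                node.length = float(token)
            except ValueError:
                raise NewickParseError(f"bad branch length {token!r}") from None
        return node

    def _read_token() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos]

    root = parse_node()
    if pos != len(s):
        raise NewickParseError(f"trailing characters at position {pos}")
    return PhyloTree(root=root)


def write_alignment_fasta(path, msa: MultipleAlignment) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for label, row in zip(msa.labels, msa.rows):
            fh.write(f">{label}\n{row}\n")
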