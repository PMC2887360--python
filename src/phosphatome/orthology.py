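"""Cross-genome orthology by reciprocal best hit (RBH).

Two proteins in different genomes are called orthologs when each is the
other's best-scoring match and both directions are significant at
E <= 1e-10.  Instead of heuristic BLASTP we score every cross-genome pair
with optimal Smith-Waterman local alignment (BLOSUM62, affine gaps), which
is deterministic and strictly more sensitive; significance uses the
Karlin-Altschul formula E = K * m * n * exp(-lambda * S) with fixed
gapped-BLOSUM62 constants and database-style scaling (n = total residue
count of the target proteome).

Multi-genome ortholog groups are connected components of the RBH graph;
a component with two members from one genome is repaired by greedily
dropping its weakest (highest-E) edge until each genome appears at most
once per component.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Genome, PROTEIN_ALPHABET


@dataclass(frozen=True)
class AlignmentScoringParams:
    """Scoring model for local alignment and its significance.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST
    convention).  ``karlin_lambda`` (nats per score unit) and ``karlin_k``
    are the Karlin-Altschul parameters of the score distribution; the
    defaults are the standard gapped BLOSUM62 11/1 values.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


def _make_aligner(params: AlignmentScoringParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    aligner.mode = mode
    # first gap residue costs open+extend, each further residue costs extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _check_alphabet(seq: str, label: str) -> None:
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"{label}: residues outside alphabet: {sorted(bad)}")


def align_local(
    a: str,
    b: str,
    params: AlignmentScoringParams | None = None,
) -> tuple[float, tuple[int, int, int, int]]:
    """Optimal Smith-Waterman score and aligned-region coordinates.

    Returns ``(score, (a_start, a_end, b_start, b_end))`` with 0-based
    half-open coordinates of the optimal local alignment; for sequences
    with no positive-scoring cell the score is 0 and the region is empty.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    params = params or AlignmentScoringParams()
    _check_alphabet(a, "first sequence")
    _check_alphabet(b, "second sequence")
    aligner = _make_aligner(params, "local")
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, (0, 0, 0, 0)
    aln = aligner.align(a, b)[0]
    a_blocks, b_blocks = aln.aligned
    region = (
        int(a_blocks[0][0]),
        int(a_blocks[-1][1]),
        int(b_blocks[0][0]),
        int(b_blocks[-1][1]),
    )
    return float(score), region


def local_score(a: str, b: str, params: AlignmentScoringParams | None = None) -> float:
    """Smith-Waterman score only (fast path used by RBH)."""
    params = params or AlignmentScoringParams()
    aligner = _make_aligner(params, "local")
    return float(max(0.0, aligner.score(a, b)))


def evalue(
    score: float,
    m: int,
    n: int,
    params: AlignmentScoringParams | None = None,
) -> float:
    """Karlin-Altschul expected number of chance hits at or above ``score``.

    ``E = K * m * n * exp(-lambda * score)``; ``m`` is the query length and
    ``n`` the target length (or total database residue count).
    """
    if score < 0:
        raise ValueError("score must be non-negative")
    params = params or AlignmentScoringParams()
    return params.karlin_k * m * n * math.exp(-params.karlin_lambda * score)


@dataclass(frozen=True)
class OrthologPair:
    """An unordered cross-genome RBH pair; endpoints stored in canonical order."""

    genome_a: str
    locus_a: str
    genome_b: str
    locus_b: str
    score: float
    evalue: float  # the worse (larger) of the two directional E-values

    def __post_init__(self) -> None:
        if self.genome_a == self.genome_b:
            raise ValueError("ortholog pair endpoints must be in different genomes")
        if (self.genome_a, self.locus_a) > (self.genome_b, self.locus_b):
            raise ValueError("endpoints not in canonical order; use make_pair")

    @property
    def endpoints(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return (self.genome_a, self.locus_a), (self.genome_b, self.locus_b)

    def key(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.endpoints)


def make_pair(
    endpoint_a: tuple[str, str],
    endpoint_b: tuple[str, str],
    score: float,
    e: float,
) -> OrthologPair:
    """Construct an :class:`OrthologPair` with canonical endpoint order."""
    first, second = sorted([endpoint_a, endpoint_b])
    return OrthologPair(first[0], first[1], second[0], second[1], score, e)


def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def reciprocal_best_hits(
    genome_a: Genome,
    genome_b: Genome,
    params: AlignmentScoringParams | None = None,
    cutoff: float = 1e-10,
    seed_filter: tuple[int, int] | None = None,
) -> list[OrthologPair]:
    """All RBH ortholog pairs between two genomes.

    A pair (a, b) is emitted iff b is a's best hit in ``genome_b``, a is
    b's best hit in ``genome_a``, and both directional E-values are at or
    below ``cutoff``.  Score ties for "best" break toward the
    lexicographically smaller locus tag, and such a tie-broken best still
    counts.

    ``seed_filter=(k, min_shared)`` optionally restricts exact alignment to
    sequence pairs sharing at least ``min_shared`` distinct k-mers — a
    BLAST-like seeding heuristic for large runs.  The default (None) scores
    every cross-genome pair exactly.
    """
    if genome_a.genome_id == genome_b.genome_id:
        raise ValueError("RBH compares two different genomes")
    if not len(genome_a) or not len(genome_b):
        raise ValueError("both genomes must contain proteins")
    params = params or AlignmentScoringParams()
    aligner = _make_aligner(params, "local")

    loci_a = sorted(genome_a.loci)
    loci_b = sorted(genome_b.loci)
    prot_a = genome_a.proteins()
    prot_b = genome_b.proteins()

    if seed_filter is not None:
        k, min_shared = seed_filter
        kmers_a = {la: _kmers(prot_a[la], k) for la in loci_a}
        kmers_b = {lb: _kmers(prot_b[lb], k) for lb in loci_b}

    scores: dict[tuple[str, str], float] = {}
    for la in loci_a:
        for lb in loci_b:
            if seed_filter is not None and len(kmers_a[la] & kmers_b[lb]) < min_shared:
                continue
            s = max(0.0, float(aligner.score(prot_a[la], prot_b[lb])))
            if s > 0:
                scores[(la, lb)] = s

    def best_for_a(la: str) -> tuple[str, float] | None:
        candidates = [(lb, scores.get((la, lb), 0.0)) for lb in loci_b]
        candidates = [(lb, s) for lb, s in candidates if s > 0]
        if not candidates:
            return None
        # max score; ties break toward the smaller locus tag
        return min(candidates, key=lambda t: (-t[1], t[0]))

    def best_for_b(lb: str) -> tuple[str, float] | None:
        candidates = [(la, s) for la in loci_a if (s := scores.get((la, lb), 0.0)) > 0]
        if not candidates:
            return None
        return min(candidates, key=lambda t: (-t[1], t[0]))

    n_a = genome_a.total_residues
    n_b = genome_b.total_residues

    pairs: list[OrthologPair] = []
    for la in loci_a:
        best = best_for_a(la)
        if best is None:
            continue
        lb, s = best
        back = best_for_b(lb)
        if back is None or back[0] != la:
            continue
        e_forward = evalue(s, len(prot_a[la]), n_b, params)
        e_back = evalue(s, len(prot_b[lb]), n_a, params)
        worst = max(e_forward, e_back)
        if worst <= cutoff:
            pairs.append(
                make_pair(
                    (genome_a.genome_id, la), (genome_b.genome_id, lb), s, worst
                )
            )
    pairs.sort(key=lambda p: (p.genome_a, p.locus_a, p.genome_b, p.locus_b))
    return pairs


def all_pairwise_rbh(
    genomes: Sequence[Genome],
    params: AlignmentScoringParams | None = None,
    cutoff: float = 1e-10,
    seed_filter: tuple[int, int] | None = None,
) -> list[OrthologPair]:
    """RBH pairs for every unordered genome pair, in deterministic order."""
    pairs: list[OrthologPair] = []
    for ga, gb in itertools.combinations(
        sorted(genomes, key=lambda g: g.genome_id), 2
    ):
        pairs.extend(reciprocal_best_hits(ga, gb, params, cutoff, seed_filter))
    return pairs


@dataclass
class OrthologGroup:
    """A multi-genome ortholog group: at most one member per genome."""

    members: list[tuple[str, str]]  # sorted (genome_id, locus)
    pairs: list[OrthologPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("ortholog group needs at least two members")
        genomes = [g for g, _ in self.members]
        if len(set(genomes)) != len(genomes):
            raise ValueError("ortholog group has two members from one genome")


def build_ortholog_groups(pairs: Iterable[OrthologPair]) -> list[OrthologGroup]:
    """Assemble ortholog groups as connected components of the RBH graph.

    A component containing two loci from the same genome is split by
    repeatedly removing its weakest edge (highest E-value; ties break on
    endpoint labels) until every remaining component is genome-unique.
    Components reduced below two members are dropped.
    """
    graph = nx.Graph()
    for p in pairs:
        (na, nb) = p.endpoints
        graph.add_edge(na, nb, pair=p)

    groups: list[OrthologGroup] = []
    components = [graph.subgraph(c).copy() for c in nx.connected_components(graph)]
    while components:
        comp = components.pop()
        genomes = [g for g, _ in comp.nodes]
        if len(set(genomes)) == len(genomes):
            if comp.number_of_nodes() >= 2:
                members = sorted(comp.nodes)
                comp_pairs = sorted(
                    (data["pair"] for _, _, data in comp.edges(data=True)),
                    key=lambda p: (p.genome_a, p.locus_a, p.genome_b, p.locus_b),
                )
                groups.append(OrthologGroup(members=members, pairs=comp_pairs))
            continue
        worst = max(
            comp.edges(data=True),
            key=lambda e: (e[2]["pair"].evalue, tuple(sorted((e[0], e[1])))),
        )
        comp.remove_edge(worst[0], worst[1])
        comp.remove_nodes_from(list(nx.isolates(comp)))
        components.extend(
            comp.subgraph(c).copy() for c in nx.connected_components(comp)
        )
    groups.sort(key=lambda g: g.members)
    return groups


# ---------------------------------------------------------------------------
# TSV output

PAIRS_TABLE_COLUMNS = ("genome_a", "locus_a", "genome_b", "locus_b", "score", "evalue")


def write_pairs(path, pairs: Iterable[OrthologPair]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(PAIRS_TABLE_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.genome_a}\t{p.locus_a}\t{p.genome_b}\t{p.locus_b}\t"
                f"{p.score:.1f}\t{p.evalue:.3e}\n"
            )


def write_groups(path, groups: Iterable[OrthologGroup]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("group_id\tmembers\n")
        for i, g in enumerate(groups, start=1):
            members = ",".join(f"{gid}:{locus}" for gid, locus in g.members)
            fh.write(f"og{i:04d}\t{members}\n")
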