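"""Gene-neighborhood analyses: kinase-phosphatase co-organization within a
genome and ortholog-anchored local synteny between genomes.

Gene distance is purely positional: the number of intervening genes in
gene order (``|index_a - index_b| - 1``; adjacent genes have distance 0),
strand-ignored, CDS only.  A kinase gene and a phosphatase gene are
*co-organized* when at most five genes separate them (configurable); the
distance-0 case is a *direct* pair.

Local synteny is anchored on a phosphatase ortholog pair: the block is
accepted when at least ``min_conserved`` additional ortholog pairs fall
within a +/- ``window``-gene neighborhood of both anchors and their
relative gene order is consistent (identical or fully reversed).  The
window/threshold formalization replaces a manual neighborhood inspection;
both parameters are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .families import (
    FamilyAssignment,
    KINASE_FAMILIES,
    PP_FAMILIES,
    PTPZ,
    assignments_by_locus,
)
from .genome_io import Genome
from .orthology import OrthologPair

#: phosphatase families considered in kinase-opposition analyses:
#: PtpZ-like proteins are excluded by convention (they are not believed to
#: counteract ELKs)
DEFAULT_PP_FAMILIES = frozenset(PP_FAMILIES - {PTPZ})


def gene_distance(genome: Genome, locus_a: str, locus_b: str) -> int:
    """Number of genes strictly between two loci in gene order."""
    if locus_a == locus_b:
        raise ValueError(f"gene_distance of {locus_a} with itself is undefined")
    ga = genome.gene(locus_a)
    gb = genome.gene(locus_b)
    return abs(ga.index - gb.index) - 1


@dataclass(frozen=True)
class CoOrgPair:
    """A kinase gene and a phosphatase gene within the distance threshold."""

    kinase_locus: str
    pp_locus: str
    distance: int
    direct: bool

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if self.direct != (self.distance == 0):
            raise ValueError("direct flag inconsistent with distance")


def find_coorganized_pairs(
    genome: Genome,
    assignments: Iterable[FamilyAssignment] | Mapping[str, FamilyAssignment],
    max_distance: int = 5,
    kinase_families: frozenset[str] = KINASE_FAMILIES,
    pp_families: frozenset[str] = DEFAULT_PP_FAMILIES,
) -> list[CoOrgPair]:
    """All kinase-phosphatase gene pairs within ``max_distance`` genes."""
    if isinstance(assignments, Mapping):
        by_locus = dict(assignments)
    else:
        by_locus = assignments_by_locus(assignments)
    kinases = [
        g for g in genome if by_locus.get(g.locus_tag) is not None
        and by_locus[g.locus_tag].family in kinase_families
    ]
    pps = [
        g for g in genome if by_locus.get(g.locus_tag) is not None
        and by_locus[g.locus_tag].family in pp_families
    ]
    pairs: list[CoOrgPair] = []
    for k in kinases:
        for p in pps:
            dist = abs(k.index - p.index) - 1
            if 0 <= dist <= max_distance:
                pairs.append(
                    CoOrgPair(
                        kinase_locus=k.locus_tag,
                        pp_locus=p.locus_tag,
                        distance=dist,
                        direct=dist == 0,
                    )
                )
    pairs.sort(key=lambda c: (c.distance, c.kinase_locus, c.pp_locus))
    return pairs


@dataclass(frozen=True)
class SyntenyBlock:
    """A conserved phosphatase gene neighborhood between two genomes."""

    anchor: OrthologPair
    neighbor_pairs: tuple[OrthologPair, ...]
    window: int
    orientation: str  # 'same' or 'reversed'

    @property
    def n_conserved(self) -> int:
        return len(self.neighbor_pairs)


def find_local_synteny(
    genome_a: Genome,
    genome_b: Genome,
    assignments_a: Iterable[FamilyAssignment] | Mapping[str, FamilyAssignment],
    assignments_b: Iterable[FamilyAssignment] | Mapping[str, FamilyAssignment],
    pairs: Sequence[OrthologPair],
    window: int = 5,
    min_conserved: int = 2,
    pp_families: frozenset[str] = frozenset(PP_FAMILIES),
) -> list[SyntenyBlock]:
    """Ortholog-anchored local synteny blocks around phosphatase genes.

    For every ortholog pair whose two loci are both phosphatase-family
    genes, collect the other ortholog pairs lying within ``window`` genes
    of both anchors; a block is emitted when at least ``min_conserved``
    such neighbor pairs exist and their relative gene order is the same in
    both genomes (or fully reversed).
    """
    fam_a = (
        dict(assignments_a)
        if isinstance(assignments_a, Mapping)
        else assignments_by_locus(assignments_a)
    )
    fam_b = (
        dict(assignments_b)
        if isinstance(assignments_b, Mapping)
        else assignments_by_locus(assignments_b)
    )

    def endpoints_for(pair: OrthologPair) -> tuple[str, str] | None:
        """(locus in genome_a, locus in genome_b), or None if off-pair."""
        mapping = dict([ (pair.genome_a, pair.locus_a), (pair.genome_b, pair.locus_b) ])
        if genome_a.genome_id in mapping and genome_b.genome_id in mapping:
            return mapping[genome_a.genome_id], mapping[genome_b.genome_id]
        return None

    local_pairs = [
        (p, ep) for p in pairs if (ep := endpoints_for(p)) is not None
    ]

    blocks: list[SyntenyBlock] = []
    for anchor, (la, lb) in local_pairs:
        aa = fam_a.get(la)
        ab = fam_b.get(lb)
        if aa is None or ab is None:
            continue
        if aa.family not in pp_families or ab.family not in pp_families:
            continue
        ia = genome_a.gene(la).index
        ib = genome_b.gene(lb).index
        neighbors: list[tuple[int, int, OrthologPair]] = []
        for p, (xa, xb) in local_pairs:
            if p.key() == anchor.key():
                continue
            da = genome_a.gene(xa).index - ia
            db = genome_b.gene(xb).index - ib
            if abs(da) <= window and abs(db) <= window:
                neighbors.append((da, db, p))
        if len(neighbors) < min_conserved:
            continue
        neighbors.sort(key=lambda t: t[0])
        offsets_b = [db for _, db, _ in neighbors]
        same = all(x < y for x, y in zip(offsets_b, offsets_b[1:]))
        reversed_ = all(x > y for x, y in zip(offsets_b, offsets_b[1:]))
        if not (same or reversed_):
            continue
        blocks.append(
            SyntenyBlock(
                anchor=anchor,
                neighbor_pairs=tuple(p for _, _, p in neighbors),
                window=window,
                orientation="same" if same else "reversed",
            )
        )
    blocks.sort(key=lambda b: (b.anchor.genome_a, b.anchor.locus_a, b.anchor.locus_b))
    return blocks


# ---------------------------------------------------------------------------
# TSV output


def write_coorg_pairs(path, pairs: Iterable[CoOrgPair]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("kinase\tphosphatase\tdistance\tdirect\n")
        for p in pairs:
            fh.write(
                f"{p.kinase_locus}\t{p.pp_locus}\t{p.distance}\t"
                f"{'yes' if p.direct else 'no'}\n"
            )


def write_synteny_blocks(path, blocks: Iterable[SyntenyBlock]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("anchor_a\tanchor_b\tn_conserved\torientation\n")
        for b in blocks:
            fh.write(
                f"{b.anchor.locus_a}\t{b.anchor.locus_b}\t"
                f"{b.n_conserved}\t{b.orientation}\n"
            )
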