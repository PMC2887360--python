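"""Synthetic multi-genome datasets with a machine-readable ground truth.

The generator emulates the pipeline's real inputs — per-genome protein
FASTA, gene-coordinate GFF and pfam/COG domain-call tables — with planted
structure at every level the pipeline detects:

* family members carrying the correct pfam/COG evidence and embedded
  signature motifs (planted PPP proteins contain GDXHG, GDXXDRG, GNHE and
  an (I/L/V)D(S/T)G instance; planted ApaH-like proteins are rejection-
  sampled to *lack* the (I/L/V)D(S/T)G motif; ELKs carry a DLKPEN
  catalytic loop; rhodanese proteins lack the Cdc25 motif),
* ortholog groups built star-wise from one ancestor per group, mutated
  into each genome by independent point substitutions (motif positions
  masked so family evidence survives),
* kinase-phosphatase co-organized pairs at exact configured gene
  distances, and
* a local-synteny block: a shared phosphatase anchor whose neighborhood
  of ortholog pairs is conserved in the same order between two genomes.

Placement keeps unplanned signal out: kinase-family and phosphatase-family
genes outside the planted co-organized pairs are laid out in separate
genome zones with a buffer wider than the co-organization threshold, so
the planted pair list *is* the complete pair list.  Background genes carry
random sequence and no schema-matching calls.

Everything is deterministic for a fixed seed (a single
``numpy.random.default_rng`` stream consumed in fixed order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import families as fam
from .genome_io import (
    AMINO_ACIDS,
    DomainCall,
    Gene,
    Genome,
    write_domain_table,
    write_genome,
)
from .motifs import CDC25_MOTIF, PPP_MOTIFS, compile_pattern, contains

# generator-level pseudo-families (classifier-level truth differs)
APAH = "APAH"  # -> family PPP_CANDIDATE, subtype APAH_CANDIDATE
CALCINEURIN_OTHER = "CALCINEURIN_OTHER"  # PF00149 + unrelated COG -> OTHER

_AA = np.array(list(AMINO_ACIDS))

#: concrete pattern instances planted per generator family
_PLANT_MOTIFS: dict[str, list[str]] = {
    fam.PPP_CANDIDATE: ["GDXHG", "GDXXDRG", "GNHE", "(I/L/V)D(S/T)G"],
    fam.ELK: ["DLKPEN"],
}

#: domain-call accessions per generator family: (pfam, cog)
_FAMILY_CALLS: dict[str, tuple[str, str]] = {
    fam.PP2C: ("PF00481", "COG0631"),
    fam.SPOIIE: ("PF07228", "COG2208"),
    fam.PPP_CANDIDATE: ("PF00149", "COG0639"),
    APAH: ("PF00149", "COG0639"),
    fam.PTP: ("", "COG2453"),
    fam.LOW_MW_PTP: ("", "COG0394"),
    fam.DSP_PTP: ("", "COG2365"),
    fam.PTP_OTHER: ("", "COG4551"),
    fam.PTPZ: ("", "COG4464"),
    fam.ELK: ("", "COG0515"),
    fam.NON_ELK_KINASE: ("", "COG2172"),
    fam.ANTI_ANTI_SIGMA: ("", "COG1366"),
    fam.RHODANESE: ("PF00581", "COG0607"),
    CALCINEURIN_OTHER: ("PF00149", "COG3568"),
}

_FUSION_PLANT: dict[str, tuple[str, str]] = {
    # family -> (accessory accession, fusion flag)
    fam.PP2C: ("PF00027", "cNMP"),
    fam.SPOIIE: ("PF00672", "HAMP"),
}

#: classifier-level family for each generator family
_TRUE_FAMILY: dict[str, str] = {
    **{f: f for f in _FAMILY_CALLS},
    APAH: fam.PPP_CANDIDATE,
    CALCINEURIN_OTHER: fam.OTHER,
}

_KINASE_GEN_FAMILIES = frozenset({fam.ELK, fam.NON_ELK_KINASE})
_PP_GEN_FAMILIES = frozenset(
    {fam.PP2C, fam.SPOIIE, fam.PPP_CANDIDATE, APAH, fam.PTP, fam.LOW_MW_PTP,
     fam.DSP_PTP, fam.PTP_OTHER}
)  # PTPZ excluded: it does not participate in co-organization analyses

_ILV_DST_G = PPP_MOTIFS["ILV_DST_G"]

#: buffer (in genes) between unpaired kinase and phosphatase zones; one more
#: than the default co-organization threshold so no accidental pair arises
_ZONE_GAP = 7


class InfeasibleConfigError(ValueError):
    """Planted structure does not fit in the configured genome size."""


def default_family_counts() -> dict[str, int]:
    """Planted members per family per genome.

    Chosen to echo the relative myxobacterial family sizes (kinases several
    times more numerous than any single phosphatase family, PP2c-type the
    largest phosphatase class) scaled to a 200-gene synthetic replicon.
    """
    return {
        fam.ELK: 10,
        fam.NON_ELK_KINASE: 1,
        fam.PP2C: 4,
        fam.SPOIIE: 2,
        fam.PPP_CANDIDATE: 3,
        APAH: 2,
        fam.PTP: 2,
        fam.LOW_MW_PTP: 1,
        fam.DSP_PTP: 1,
        fam.PTP_OTHER: 1,
        fam.PTPZ: 1,
        fam.ANTI_ANTI_SIGMA: 1,
        fam.RHODANESE: 2,
        CALCINEURIN_OTHER: 1,
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_genomes: int = 3
    genes_per_genome: int = 200
    family_counts: dict[str, int] = field(default_factory=default_family_counts)
    fusion_fraction: float = 0.25
    ortholog_fraction: float = 0.5
    mutation_rate: float = 0.05  # per-residue point-substitution probability
    coorg_distances: tuple[int, ...] = (0, 2, 5)  # one ELK-PP2C pair each
    n_synteny_blocks: int = 1
    synteny_neighbors: int = 3
    synteny_window: int = 5  # scatter keeps stray ortholog genes farther apart
    length_range: tuple[int, int] = (250, 350)

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.n_genomes < 1:
            raise ValueError("need at least one genome")
        if self.length_range[0] < 50 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid protein length range")

    @property
    def genome_ids(self) -> list[str]:
        return [f"G{i}" for i in range(self.n_genomes)]


@dataclass
class GroundTruth:
    """Planted structure, keyed the same way the pipeline reports results."""

    families: dict[str, dict[str, str]]  # genome -> locus -> family
    subtypes: dict[str, dict[str, str]]  # genome -> locus -> subtype flag
    fusions: dict[str, dict[str, list[str]]]
    motifs: dict[str, dict[str, list[tuple[str, int]]]]  # (motif, 1-based pos)
    ortholog_groups: list[list[tuple[str, str]]]  # [(genome, locus), ...]
    coorg: dict[str, list[tuple[str, str, int]]]  # (kinase, pp, distance)
    synteny: list[dict]

    @property
    def ortholog_pairs(self) -> set[frozenset[tuple[str, str]]]:
        pairs: set[frozenset[tuple[str, str]]] = set()
        for group in self.ortholog_groups:
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    if group[i][0] != group[j][0]:
                        pairs.add(frozenset({tuple(group[i]), tuple(group[j])}))
        return pairs

    def pairs_between(self, ga: str, gb: str) -> set[frozenset[tuple[str, str]]]:
        return {
            p for p in self.ortholog_pairs
            if {e[0] for e in p} == {ga, gb}
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "families": self.families,
            "subtypes": self.subtypes,
            "fusions": self.fusions,
            "motifs": self.motifs,
            "ortholog_groups": [
                [list(m) for m in group] for group in self.ortholog_groups
            ],
            "coorg": {g: [list(t) for t in v] for g, v in self.coorg.items()},
            "synteny": self.synteny,
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            families=payload["families"],
            subtypes=payload["subtypes"],
            fusions=payload["fusions"],
            motifs={
                g: {l: [(m, p) for m, p in v] for l, v in d.items()}
                for g, d in payload["motifs"].items()
            },
            ortholog_groups=[
                [tuple(m) for m in group] for group in payload["ortholog_groups"]
            ],
            coorg={
                g: [tuple(t) for t in v] for g, v in payload["coorg"].items()
            },
            synteny=payload["synteny"],
        )


@dataclass
class SimResult:
    config: SimConfig
    genomes: dict[str, Genome]
    calls: dict[str, list[DomainCall]]
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for gid, genome in self.genomes.items():
            write_genome(out_dir, genome)
            write_domain_table(out_dir / f"{gid}.domains.tsv", self.calls[gid])
        self.truth.to_json(out_dir / "ground_truth.json")
        with open(out_dir / "genomes.txt", "w", encoding="utf-8", newline="\n") as fh:
            for gid in sorted(self.genomes):
                fh.write(gid + "\n")
        return out_dir


# ---------------------------------------------------------------------------
# sequence-level helpers


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(_AA[rng.integers(0, len(_AA), size=length)])


def mutate_sequence(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    mask: Iterable[int] | None = None,
) -> str:
    """Independent per-position point substitution at the given rate.

    Each selected position is replaced by a uniformly chosen *different*
    residue.  Positions in ``mask`` (0-based) are never mutated, which is
    how planted motif instances survive ortholog divergence.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    masked = frozenset(mask or ())
    chars = list(seq)
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        if int(i) in masked:
            continue
        current = chars[i]
        alternatives = [a for a in AMINO_ACIDS if a != current]
        chars[i] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(chars)


def _instantiate_motif(pattern_text: str, rng: np.random.Generator) -> str:
    """A concrete residue string matching a motif pattern."""
    pat = compile_pattern(pattern_text)
    out = []
    for el in pat.elements:
        if el is None:
            out.append(str(_AA[int(rng.integers(0, len(_AA)))]))
        else:
            members = sorted(el)
            out.append(members[int(rng.integers(0, len(members)))])
    return "".join(out)


def _embed_motifs(
    seq: str, instances: Sequence[str], rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Embed motif instances at random non-overlapping interior positions.

    Returns the new sequence and the 0-based start of each instance (in
    input order).
    """
    occupied: list[tuple[int, int]] = []
    starts: list[int] = []
    chars = list(seq)
    margin = 5
    for inst in instances:
        for _ in range(200):
            start = int(rng.integers(margin, len(seq) - len(inst) - margin))
            span = (start, start + len(inst))
            if all(span[1] <= a or span[0] >= b for a, b in occupied):
                occupied.append(span)
                starts.append(start)
                chars[span[0] : span[1]] = list(inst)
                break
        else:  # pragma: no cover - needs a pathologically short sequence
            raise InfeasibleConfigError("cannot place motifs without overlap")
    return "".join(chars), starts


@dataclass
class _GeneSpec:
    gen_family: str  # generator family label, or 'BACKGROUND'
    protein: str
    motif_positions: list[tuple[str, int]] = field(default_factory=list)  # 1-based
    mask: frozenset[int] = frozenset()  # 0-based masked positions
    fusion: str = ""  # fusion flag to plant, '' for none
    group_id: int = -1  # ortholog group index, -1 for private


def _spec_constraint_ok(gen_family: str, seq: str) -> bool:
    if gen_family == APAH and contains(seq, _ILV_DST_G):
        return False
    if gen_family == fam.RHODANESE and contains(seq, CDC25_MOTIF):
        return False
    return True


def _make_family_sequence(
    gen_family: str, length: int, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int]], frozenset[int]]:
    """Random sequence with the family's motifs embedded; retried until the
    family's exclusion constraints hold."""
    true_family = _TRUE_FAMILY[gen_family]
    motif_texts = _PLANT_MOTIFS.get(true_family if gen_family != APAH else "", [])
    names = (
        ["GDXHG", "GDXXDRG", "GNHE", "ILV_DST_G"]
        if true_family == fam.PPP_CANDIDATE and gen_family != APAH
        else (["DLKPEN"] if true_family == fam.ELK else [])
    )
    for _ in range(200):
        seq = random_protein(length, rng)
        positions: list[tuple[str, int]] = []
        mask: set[int] = set()
        if motif_texts:
            instances = [_instantiate_motif(t, rng) for t in motif_texts]
            seq, starts = _embed_motifs(seq, instances, rng)
            for name, inst, start in zip(names, instances, starts):
                positions.append((name, start + 1))
                mask.update(range(start, start + len(inst)))
        if _spec_constraint_ok(gen_family, seq):
            return seq, positions, frozenset(mask)
    raise InfeasibleConfigError(
        f"could not satisfy sequence constraints for {gen_family}"
    )


def _derive_copy(
    gen_family: str,
    ancestor: str,
    mask: frozenset[int],
    rate: float,
    rng: np.random.Generator,
) -> str:
    for _ in range(200):
        seq = mutate_sequence(ancestor, rate, rng, mask=mask)
        if _spec_constraint_ok(gen_family, seq):
            return seq
    raise InfeasibleConfigError(
        f"could not derive a constraint-satisfying copy for {gen_family}"
    )


def _calls_for(
    locus: str, spec: _GeneSpec, plen: int
) -> list[DomainCall]:
    if spec.gen_family == "BACKGROUND":
        return []
    pfam, cog = _FAMILY_CALLS[spec.gen_family]
    dom_end = min(plen, 10 + 220)
    out = [DomainCall(locus, pfam, cog, 10, dom_end)]
    if spec.fusion:
        acc = {v: k for k, v in fam.FUSION_ACCESSIONS.items() if k.startswith("PF")}[
            spec.fusion
        ]
        out.append(DomainCall(locus, acc, "", max(1, plen - 59), plen - 5))
    return out


# ---------------------------------------------------------------------------
# generation


def generate(config: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Generate a multi-genome synthetic dataset plus its ground truth.

    Deterministic for a fixed ``config.seed``.  Raises
    :class:`InfeasibleConfigError` before writing anything if the planted
    structure cannot fit.
    """
    rng = np.random.default_rng(config.seed)
    gids = config.genome_ids
    counts = dict(config.family_counts)
    n_slots = config.genes_per_genome

    # -- ortholog group planning (star-shaped: one ancestor per group) ------
    # Shared groups span all genomes; each contributes one member per genome.
    shared_per_family = {
        f: int(np.floor(config.ortholog_fraction * c)) if config.n_genomes > 1 else 0
        for f, c in counts.items()
    }
    # The synteny anchor must be a shared PP2C group between G0 and G1.
    if config.n_synteny_blocks > 0:
        if config.n_genomes < 2:
            raise InfeasibleConfigError("synteny blocks need at least 2 genomes")
        if shared_per_family.get(fam.PP2C, 0) < config.n_synteny_blocks:
            raise InfeasibleConfigError(
                "synteny blocks require at least as many shared PP2C groups"
            )
    if len(config.coorg_distances) > counts.get(fam.ELK, 0):
        raise InfeasibleConfigError("not enough planted ELKs for co-org pairs")
    n_coorg_pp2c = len(config.coorg_distances)
    if n_coorg_pp2c + config.n_synteny_blocks > counts.get(fam.PP2C, 0):
        raise InfeasibleConfigError(
            "not enough planted PP2C genes for co-org pairs and synteny anchors"
        )

    group_specs: list[dict] = []  # one per ortholog group
    per_genome_specs: dict[str, list[_GeneSpec]] = {g: [] for g in gids}

    def new_length() -> int:
        lo, hi = config.length_range
        return int(rng.integers(lo, hi + 1))

    # shared family groups
    for f in sorted(counts):
        for _ in range(shared_per_family[f]):
            length = new_length()
            ancestor, positions, mask = _make_family_sequence(f, length, rng)
            gid_members = {}
            for g in gids:
                seq = _derive_copy(f, ancestor, mask, config.mutation_rate, rng)
                gid_members[g] = _GeneSpec(
                    gen_family=f,
                    protein=seq,
                    motif_positions=list(positions),
                    mask=mask,
                    group_id=len(group_specs),
                )
            group_specs.append({"family": f, "members": gid_members})

    # background ortholog groups used as synteny neighbors (G0/G1 only)
    synteny_neighbor_groups: list[int] = []
    for _ in range(config.n_synteny_blocks * config.synteny_neighbors):
        length = new_length()
        ancestor = random_protein(length, rng)
        gid_members = {}
        for g in gids[:2]:
            gid_members[g] = _GeneSpec(
                gen_family="BACKGROUND",
                protein=mutate_sequence(ancestor, config.mutation_rate, rng),
                group_id=len(group_specs),
            )
        synteny_neighbor_groups.append(len(group_specs))
        group_specs.append({"family": "BACKGROUND", "members": gid_members})

    # private family members
    for g in gids:
        for f in sorted(counts):
            n_private = counts[f] - shared_per_family[f]
            for _ in range(n_private):
                length = new_length()
                seq, positions, mask = _make_family_sequence(f, length, rng)
                per_genome_specs[g].append(
                    _GeneSpec(
                        gen_family=f,
                        protein=seq,
                        motif_positions=list(positions),
                        mask=mask,
                    )
                )

    # fusion planting: a fraction of PP2C / SPOIIE members get an accessory
    # domain call (cNMP / HAMP respectively)
    for g in gids:
        pool = [
            s
            for s in per_genome_specs[g]
            + [gs["members"][g] for gs in group_specs if g in gs["members"]]
            if s.gen_family in _FUSION_PLANT
        ]
        for s in pool:
            if rng.random() < config.fusion_fraction:
                s.fusion = _FUSION_PLANT[s.gen_family][1]

    # -- placement ----------------------------------------------------------
    # Layout per genome: [reserved windows][kinase zone][gap][PP zone][rest]
    placements: dict[str, dict[int, _GeneSpec]] = {g: {} for g in gids}

    shared_members = {
        g: [gs["members"][g] for gs in group_specs if g in gs["members"]]
        for g in gids
    }

    # pick synteny anchors: first shared PP2C groups
    shared_pp2c_groups = [
        i for i, gs in enumerate(group_specs) if gs["family"] == fam.PP2C
    ][: config.n_synteny_blocks]

    truth_coorg: dict[str, list[tuple[str, str, int]]] = {g: [] for g in gids}
    synteny_layouts: list[dict] = []

    for g in gids:
        cursor = int(rng.integers(0, 4))  # small random leading offset

        def reserve(length_needed: int) -> int:
            nonlocal cursor
            start = cursor
            if start + length_needed > n_slots:
                raise InfeasibleConfigError(
                    f"{g}: planted windows exceed genome size"
                )
            cursor = start + length_needed + (_ZONE_GAP + 1)
            return start

        pool = {s_id: s for s_id, s in enumerate(per_genome_specs[g])}
        # shared members usable for co-org windows (synteny anchors excluded)
        anchor_ids = {
            id(group_specs[gi]["members"][g])
            for gi in shared_pp2c_groups
            if g in group_specs[gi]["members"]
        }
        shared_pool = {
            id(s): s
            for s in shared_members[g]
            if id(s) not in anchor_ids and s.gen_family != "BACKGROUND"
        }
        placed_ids: set[int] = set()

        def take(family: str) -> _GeneSpec:
            for s_id in sorted(pool):
                if pool[s_id].gen_family == family:
                    return pool.pop(s_id)
            for s_id in sorted(shared_pool):
                if shared_pool[s_id].gen_family == family:
                    return shared_pool.pop(s_id)
            raise InfeasibleConfigError(f"{g}: no planted {family} left to place")

        # synteny blocks first (genomes G0 and G1 share layout offsets)
        if g in gids[:2]:
            for b in range(config.n_synteny_blocks):
                anchor_spec = group_specs[shared_pp2c_groups[b]]["members"][g]
                neighbor_ids = synteny_neighbor_groups[
                    b * config.synteny_neighbors : (b + 1) * config.synteny_neighbors
                ]
                start = reserve(1 + config.synteny_neighbors)
                placements[g][start] = anchor_spec
                placed_ids.add(id(anchor_spec))
                for off, gi in enumerate(neighbor_ids, start=1):
                    spec = group_specs[gi]["members"][g]
                    placements[g][start + off] = spec
                    placed_ids.add(id(spec))
                if g == gids[0]:
                    synteny_layouts.append(
                        {"group": shared_pp2c_groups[b], "neighbors": neighbor_ids}
                    )

        # co-organized ELK-PP2C pairs at exact distances
        for d in config.coorg_distances:
            elk = take(fam.ELK)
            pp = take(fam.PP2C)
            start = reserve(d + 2)
            placements[g][start] = elk
            placements[g][start + d + 1] = pp
            placed_ids.update((id(elk), id(pp)))
            truth_coorg[g].append((start, start + d + 1, d))  # indices for now

        # zone layout for the remaining planted genes
        remaining = list(pool.values()) + [
            s for s in shared_members[g] if id(s) not in placed_ids
        ]
        kin = [s for s in remaining if s.gen_family in _KINASE_GEN_FAMILIES]
        pps = [s for s in remaining if s.gen_family in _PP_GEN_FAMILIES]
        others = [
            s for s in remaining
            if s.gen_family not in _KINASE_GEN_FAMILIES
            and s.gen_family not in _PP_GEN_FAMILIES
        ]
        free = list(range(cursor, n_slots))
        total = len(kin) + len(pps) + len(others)
        need = total + _ZONE_GAP
        if len(free) < need:
            raise InfeasibleConfigError(
                f"{g}: {len(free)} free slots cannot hold planted genes ({need})"
            )
        # zones sized proportionally over the whole free region (kinases and
        # phosphatases separated by a buffer wider than the co-org threshold)
        avail = len(free) - _ZONE_GAP
        kin_len = max(len(kin), round(avail * len(kin) / total)) if kin else 0
        other_len = max(len(others), round(avail * len(others) / total)) if others else 0
        pp_len = avail - kin_len - other_len
        if pp_len < len(pps):
            raise InfeasibleConfigError(f"{g}: phosphatase zone too small")
        kin_zone = free[:kin_len]
        pp_zone = free[kin_len + _ZONE_GAP : kin_len + _ZONE_GAP + pp_len]
        other_zone = free[kin_len + _ZONE_GAP + pp_len :]
        # Ortholog-group genes are stratified across equal zone segments so
        # that same-genome spacing exceeds the synteny window — otherwise
        # chance clusters of ortholog pairs would mimic synteny blocks.
        w = config.synteny_window

        def place_zone(zone: list[int], specs: list[_GeneSpec]) -> dict[int, _GeneSpec]:
            out: dict[int, _GeneSpec] = {}
            shared = [s for s in specs if s.group_id >= 0]
            private = [s for s in specs if s.group_id < 0]
            taken: set[int] = set()
            if shared:
                seg = len(zone) // len(shared)
                if seg < w + 1:
                    raise InfeasibleConfigError(
                        f"{g}: zone too small to scatter ortholog genes"
                    )
                for k, s in enumerate(shared):
                    off = int(rng.integers(0, seg - w)) if seg > w else 0
                    slot = zone[k * seg + off]
                    out[slot] = s
                    taken.add(k * seg + off)
            if private:
                open_idx = [i for i in range(len(zone)) if i not in taken]
                chosen = rng.choice(len(open_idx), size=len(private), replace=False)
                order = rng.permutation(len(private))
                for c, pi in zip(sorted(int(x) for x in chosen), order):
                    out[zone[open_idx[c]]] = private[int(pi)]
            return out

        for _ in range(200):
            trial: dict[int, _GeneSpec] = {}
            for zone, specs in ((kin_zone, kin), (pp_zone, pps), (other_zone, others)):
                if specs:
                    trial.update(place_zone(zone, specs))
            ortho_slots = sorted(slot for slot, s in trial.items() if s.group_id >= 0)
            if all(b - a > w for a, b in zip(ortho_slots, ortho_slots[1:])):
                placements[g].update(trial)
                break
        else:
            raise InfeasibleConfigError(
                f"{g}: cannot scatter ortholog genes beyond the synteny window"
            )

    # -- assemble genomes, calls and truth ----------------------------------
    genomes: dict[str, Genome] = {}
    calls: dict[str, list[DomainCall]] = {}
    truth_families: dict[str, dict[str, str]] = {}
    truth_subtypes: dict[str, dict[str, str]] = {}
    truth_fusions: dict[str, dict[str, list[str]]] = {}
    truth_motifs: dict[str, dict[str, list[tuple[str, int]]]] = {}
    locus_of_spec: dict[int, str] = {}  # id(spec) -> locus tag

    for g in gids:
        genes: list[Gene] = []
        gcalls: list[DomainCall] = []
        truth_families[g] = {}
        truth_subtypes[g] = {}
        truth_fusions[g] = {}
        truth_motifs[g] = {}
        for idx in range(n_slots):
            spec = placements[g].get(idx)
            if spec is None:
                spec = _GeneSpec(
                    gen_family="BACKGROUND", protein=random_protein(new_length(), rng)
                )
            locus = f"{g.lower()}_{idx:04d}"
            locus_of_spec[id(spec)] = locus
            start = 1 + idx * 1500
            end = start + 3 * len(spec.protein) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Gene(locus_tag=locus, start=start, end=end, strand=strand,
                     index=idx, protein=spec.protein)
            )
            gcalls.extend(_calls_for(locus, spec, len(spec.protein)))
            true_family = (
                fam.OTHER if spec.gen_family == "BACKGROUND"
                else _TRUE_FAMILY[spec.gen_family]
            )
            truth_families[g][locus] = true_family
            subtype = ""
            if spec.gen_family == fam.PPP_CANDIDATE:
                subtype = fam.CONSENSUS_COMPLETE
            elif spec.gen_family == APAH:
                subtype = fam.APAH_CANDIDATE
            elif spec.gen_family == fam.RHODANESE:
                subtype = fam.CDC25_NEGATIVE
            truth_subtypes[g][locus] = subtype
            truth_fusions[g][locus] = [spec.fusion] if spec.fusion else []
            truth_motifs[g][locus] = list(spec.motif_positions)
        genomes[g] = Genome(genome_id=g, genes=genes)
        calls[g] = gcalls
        # convert co-org slot indices to locus tags
        truth_coorg[g] = [
            (f"{g.lower()}_{ka:04d}", f"{g.lower()}_{pa:04d}", d)
            for ka, pa, d in truth_coorg[g]
        ]

    ortholog_groups = [
        sorted(
            (g, locus_of_spec[id(spec)])
            for g, spec in gs["members"].items()
        )
        for gs in group_specs
    ]

    synteny_truth = []
    for layout in synteny_layouts:
        anchor_group = ortholog_groups[layout["group"]]
        anchor = [m for m in anchor_group if m[0] in gids[:2]]
        synteny_truth.append(
            {
                "anchor": [list(m) for m in sorted(anchor)],
                "neighbors": [
                    [list(m) for m in ortholog_groups[gi]]
                    for gi in layout["neighbors"]
                ],
                "window": config.synteny_neighbors,
                "orientation": "same",
            }
        )

    truth = GroundTruth(
        families=truth_families,
        subtypes=truth_subtypes,
        fusions=truth_fusions,
        motifs=truth_motifs,
        ortholog_groups=ortholog_groups,
        coorg=truth_coorg,
        synteny=synteny_truth,
    )
    result = SimResult(config=config, genomes=genomes, calls=calls, truth=truth)
    audit(result)
    if out_dir is not None:
        result.write(out_dir)
    return result


# ---------------------------------------------------------------------------
# audit & metrics


def audit(result: SimResult) -> None:
    """Internal consistency check: ground truth matches the emitted data."""
    cfg = result.config
    for g, genome in result.genomes.items():
        fams = result.truth.families[g]
        assert set(fams) == set(genome.loci), f"{g}: truth/locus mismatch"
        for locus, positions in result.truth.motifs[g].items():
            seq = genome.gene(locus).protein
            for name, pos in positions:
                pat = PPP_MOTIFS.get(name)
                if pat is None:
                    pat = compile_pattern("DLKPEN", "DLKPEN")
                window = seq[pos - 1 : pos - 1 + len(pat)]
                assert contains(window, pat), (
                    f"{g}:{locus}: planted motif {name} missing at {pos}"
                )
        for locus, subtype in result.truth.subtypes[g].items():
            if subtype == fam.APAH_CANDIDATE:
                assert not contains(genome.gene(locus).protein, _ILV_DST_G)
    for g in result.genomes:
        planted = [
            f for f in result.truth.families[g].values() if f != fam.OTHER
        ]
        expected = sum(
            c for f, c in cfg.family_counts.items()
            if _TRUE_FAMILY[f] != fam.OTHER
        )
        assert len(planted) == expected, (
            f"{g}: planted {len(planted)} family genes, expected {expected}"
        )


def classification_metrics(
    truth: GroundTruth,
    assignments: dict[str, list],
) -> dict[str, tuple[float, float]]:
    """Per-family (precision, recall) of classifier output vs ground truth."""
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    for g, assigns in assignments.items():
        for a in assigns:
            true_f = truth.families[g][a.locus_tag]
            pred_f = a.family
            if pred_f == true_f:
                tp[pred_f] = tp.get(pred_f, 0) + 1
            else:
                fp[pred_f] = fp.get(pred_f, 0) + 1
                fn[true_f] = fn.get(true_f, 0) + 1
    out: dict[str, tuple[float, float]] = {}
    for f in set(tp) | set(fp) | set(fn):
        denom_p = tp.get(f, 0) + fp.get(f, 0)
        denom_r = tp.get(f, 0) + fn.get(f, 0)
        precision = tp.get(f, 0) / denom_p if denom_p else 1.0
        recall = tp.get(f, 0) / denom_r if denom_r else 1.0
        out[f] = (precision, recall)
    return out


def rbh_benchmark_config(
    seed: int,
    n_planted: int = 20,
    n_decoys: int = 150,
    length: int = 300,
    mutation_rate: float = 0.05,
) -> SimConfig:
    """Two-genome config for ortholog-recovery benchmarking: ``n_planted``
    shared ELK ortholog pairs among ``n_decoys`` random decoys per genome."""
    return SimConfig(
        seed=seed,
        n_genomes=2,
        genes_per_genome=n_planted + n_decoys,
        family_counts={fam.ELK: n_planted},
        fusion_fraction=0.0,
        ortholog_fraction=1.0,
        mutation_rate=mutation_rate,
        coorg_distances=(),
        n_synteny_blocks=0,
        synteny_neighbors=0,
        length_range=(length, length),
    )
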