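"""Per-genome phosphatome summary tables and the end-to-end pipeline.

The summary mirrors the conventional kinome/phosphatome comparison table:
per genome, the ELK count, the four phosphatase columns (PP2c-type,
SpoIIE-like, PPP, and a PTP column that sums the tyrosine-phosphatase
classes: PTP + low-MW PTP + DSP PTP + other predicted PTPs, with PtpZ-like
proteins excluded by convention), their total, and the ELK/PP ratio
rendered as ``x.y/1`` with half-up rounding at one decimal (``NA/1`` when
there are no phosphatases).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .families import (
    ELK,
    FamilyAssignment,
    FamilySchema,
    PP2C,
    PPP_CANDIDATE,
    PTP_CLASS_FAMILIES,
    SPOIIE,
    classify_genome,
    family_counts,
    write_assignments,
)
from .context import find_coorganized_pairs, find_local_synteny, write_coorg_pairs, write_synteny_blocks
from .genome_io import calls_by_locus, read_domain_table, read_genome
from .orthology import (
    AlignmentScoringParams,
    build_ortholog_groups,
    reciprocal_best_hits,
    write_groups,
    write_pairs,
)
from .phylogeny import bootstrap_support, progressive_msa, write_newick


def format_ratio(elk: int, total_pp: int) -> str:
    """Render an ELK/PP ratio as ``x.y/1`` (half-up at one decimal).

    A zero phosphatase total yields ``NA/1``.
    """
    if elk < 0 or total_pp < 0:
        raise ValueError("counts must be non-negative")
    if total_pp == 0:
        return "NA/1"
    q = (Decimal(elk) / Decimal(total_pp)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return f"{q}/1"


@dataclass(frozen=True)
class SummaryRow:
    genome_id: str
    elk: int
    pp2c: int
    spoiie: int
    ppp: int
    ptp: int  # summed PTP classes (PtpZ-like excluded)
    total_pp: int
    ratio_text: str

    def __post_init__(self) -> None:
        if self.total_pp != self.pp2c + self.spoiie + self.ppp + self.ptp:
            raise ValueError("total_PP must equal the sum of its addends")


def summary_from_counts(
    genome_id: str,
    elk: int,
    pp2c: int,
    spoiie: int,
    ppp: int,
    ptp: int,
) -> SummaryRow:
    """Build a summary row from already-known per-family counts."""
    total = pp2c + spoiie + ppp + ptp
    return SummaryRow(
        genome_id=genome_id,
        elk=elk,
        pp2c=pp2c,
        spoiie=spoiie,
        ppp=ppp,
        ptp=ptp,
        total_pp=total,
        ratio_text=format_ratio(elk, total),
    )


def summarize(
    genome_id: str, assignments: Iterable[FamilyAssignment]
) -> SummaryRow:
    counts = family_counts(assignments)
    ptp = sum(counts.get(f, 0) for f in PTP_CLASS_FAMILIES)
    return summary_from_counts(
        genome_id=genome_id,
        elk=counts.get(ELK, 0),
        pp2c=counts.get(PP2C, 0),
        spoiie=counts.get(SPOIIE, 0),
        ppp=counts.get(PPP_CANDIDATE, 0),
        ptp=ptp,
    )


SUMMARY_COLUMNS = [
    "genome_id", "ELKs", "PP2c_type", "SpoIIE_like", "PPPs", "PTPs",
    "all_PPs", "ratio_ELK_PP",
]


def summary_table(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "ELKs": r.elk,
                "PP2c_type": r.pp2c,
                "SpoIIE_like": r.spoiie,
                "PPPs": r.ppp,
                "PTPs": r.ptp,
                "all_PPs": r.total_pp,
                "ratio_ELK_PP": r.ratio_text,
            }
            for r in rows
        ],
        columns=SUMMARY_COLUMNS,
    )


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str
    genome_ids: tuple[str, ...] = ()  # default: read data_dir/genomes.txt
    schema_path: str | None = None  # default: shipped schema
    evalue_cutoff: float = 1e-10
    max_distance: int = 5  # co-organization gene-distance threshold
    synteny_window: int = 5
    synteny_min_conserved: int = 2
    bootstrap_replicates: int = 1000
    tree_families: tuple[str, ...] = (PP2C,)
    min_tree_taxa: int = 4
    seed: int = 0
    seed_filter: tuple[int, int] | None = None  # (k, min shared k-mers)

    def to_dict(self) -> dict:
        # out_dir is run-location metadata, not part of the analysis
        # identity, so it stays out of the manifest hash
        return {
            "data_dir": str(self.data_dir),
            "genome_ids": list(self.genome_ids),
            "schema_path": self.schema_path,
            "evalue_cutoff": self.evalue_cutoff,
            "max_distance": self.max_distance,
            "synteny_window": self.synteny_window,
            "synteny_min_conserved": self.synteny_min_conserved,
            "bootstrap_replicates": self.bootstrap_replicates,
            "tree_families": list(self.tree_families),
            "min_tree_taxa": self.min_tree_taxa,
            "seed": self.seed,
            "seed_filter": list(self.seed_filter) if self.seed_filter else None,
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    assignments: dict[str, list[FamilyAssignment]]
    pairs: list
    groups: list
    coorg: dict[str, list]
    synteny: dict[tuple[str, str], list]
    trees: dict[str, object]
    summary: list[SummaryRow]
    out_dir: Path = field(default_factory=Path)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """classify -> orthologs -> context -> trees -> summary.

    Reads ``<id>.faa`` / ``<id>.gff`` / ``<id>.domains.tsv`` per genome
    from ``config.data_dir``, writes every stage's TSV/Newick output plus a
    run manifest under ``config.out_dir``.  Idempotent: outputs for a fixed
    config are byte-identical across reruns.
    """
    data_dir = Path(config.data_dir)
    if not data_dir.is_dir():
        raise FileNotFoundError(f"data directory not found: {data_dir}")
    gids = list(config.genome_ids)
    if not gids:
        listing = data_dir / "genomes.txt"
        if not listing.exists():
            raise FileNotFoundError(
                f"no genome_ids configured and {listing} is missing"
            )
        gids = [l.strip() for l in listing.read_text().splitlines() if l.strip()]
    if not gids:
        raise ValueError("pipeline config names no genomes")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    schema = (
        FamilySchema.from_tsv(config.schema_path)
        if config.schema_path
        else FamilySchema.default()
    )
    params = AlignmentScoringParams()

    genomes = {}
    calls = {}
    for gid in sorted(gids):
        genomes[gid] = read_genome(data_dir, gid)
        calls[gid] = read_domain_table(
            data_dir / f"{gid}.domains.tsv", genomes[gid]
        )

    # classify
    assignments = {
        gid: classify_genome(genomes[gid], calls[gid], schema)
        for gid in sorted(genomes)
    }
    for gid, assigns in assignments.items():
        write_assignments(out_dir / f"{gid}.assignments.tsv", assigns)

    # orthologs
    pairs = []
    sorted_gids = sorted(genomes)
    for i, ga in enumerate(sorted_gids):
        for gb in sorted_gids[i + 1 :]:
            pairs.extend(
                reciprocal_best_hits(
                    genomes[ga], genomes[gb], params,
                    cutoff=config.evalue_cutoff,
                    seed_filter=config.seed_filter,
                )
            )
    groups = build_ortholog_groups(pairs)
    write_pairs(out_dir / "ortholog_pairs.tsv", pairs)
    write_groups(out_dir / "ortholog_groups.tsv", groups)

    # genome context
    coorg = {}
    for gid in sorted_gids:
        coorg[gid] = find_coorganized_pairs(
            genomes[gid], assignments[gid], max_distance=config.max_distance
        )
        write_coorg_pairs(out_dir / f"{gid}.coorg.tsv", coorg[gid])
    synteny = {}
    for i, ga in enumerate(sorted_gids):
        for gb in sorted_gids[i + 1 :]:
            blocks = find_local_synteny(
                genomes[ga], genomes[gb],
                assignments[ga], assignments[gb],
                pairs,
                window=config.synteny_window,
                min_conserved=config.synteny_min_conserved,
            )
            synteny[(ga, gb)] = blocks
            write_synteny_blocks(out_dir / f"synteny.{ga}-{gb}.tsv", blocks)

    # per-family bootstrap NJ trees across genomes
    trees = {}
    for family in config.tree_families:
        labels = []
        seqs = []
        for gid in sorted_gids:
            for a in assignments[gid]:
                if a.family == family:
                    labels.append(f"{gid}_{a.locus_tag}")
                    seqs.append(genomes[gid].gene(a.locus_tag).protein)
        if len(seqs) < config.min_tree_taxa:
            continue
        msa = progressive_msa(seqs, labels, params)
        tree = bootstrap_support(
            msa, n_replicates=config.bootstrap_replicates, seed=config.seed
        )
        trees[family] = tree
        with open(out_dir / f"tree.{family}.nwk", "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write(write_newick(tree) + "\n")

    # summary
    summary = [summarize(gid, assignments[gid]) for gid in sorted_gids]
    df = summary_table(summary)
    df.to_csv(out_dir / "summary.tsv", sep="\t", index=False, lineterminator="\n")

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "genomes": sorted_gids,
        "n_ortholog_pairs": len(pairs),
        "n_ortholog_groups": len(groups),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        config=config,
        assignments=assignments,
        pairs=pairs,
        groups=groups,
        coorg=coorg,
        synteny=synteny,
        trees=trees,
        summary=summary,
        out_dir=out_dir,
    )
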