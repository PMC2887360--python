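#!/usr/bin/env python
"""Kinase-phosphatase co-organization and ortholog-anchored synteny.

Scans each genome for kinase genes within five genes of a phosphatase
gene (the co-organization criterion), then checks every phosphatase
ortholog pair between genome pairs for a conserved, consistently ordered
gene neighborhood (window 5, >= 2 conserved neighbor pairs).
"""

import csv
from pathlib import Path

from phosphatome.context import (
    find_coorganized_pairs,
    find_local_synteny,
    write_coorg_pairs,
    write_synteny_blocks,
)
from phosphatome.families import classify_genome
from phosphatome.genome_io import read_domain_table, read_genome
from phosphatome.orthology import make_pair

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "synthetic_data"


def read_pairs():
    pairs = []
    with open(ROOT / "ortholog_pairs.tsv", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pairs.append(
                make_pair(
                    (row["genome_a"], row["locus_a"]),
                    (row["genome_b"], row["locus_b"]),
                    float(row["score"]),
                    float(row["evalue"]),
                )
            )
    return pairs


def main() -> None:
    gids = sorted((DATA / "genomes.txt").read_text().split())
    genomes, assignments = {}, {}
    for gid in gids:
        genomes[gid] = read_genome(DATA, gid)
        calls = read_domain_table(DATA / f"{gid}.domains.tsv", genomes[gid])
        assignments[gid] = classify_genome(genomes[gid], calls)

    for gid in gids:
        coorg = find_coorganized_pairs(genomes[gid], assignments[gid])
        write_coorg_pairs(ROOT / f"{gid}.coorg.tsv", coorg)
        direct = [p for p in coorg if p.direct]
        print(
            f"{gid}: {len(coorg)} co-organized kinase-phosphatase pairs "
            f"({len(direct)} direct neighbors)"
        )

    pairs = read_pairs()
    for i, ga in enumerate(gids):
        for gb in gids[i + 1 :]:
            blocks = find_local_synteny(
                genomes[ga], genomes[gb],
                assignments[ga], assignments[gb],
                pairs, window=5, min_conserved=2,
            )
            write_synteny_blocks(ROOT / f"synteny.{ga}-{gb}.tsv", blocks)
            for b in blocks:
                print(
                    f"{ga}-{gb}: synteny block at {b.anchor.locus_a}/"
                    f"{b.anchor.locus_b}, {b.n_conserved} conserved "
                    f"neighbors, order {b.orientation}"
                )
            if not blocks:
                print(f"{ga}-{gb}: no local synteny")


if __name__ == "__main__":
    main()
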