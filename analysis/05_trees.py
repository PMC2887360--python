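#!/usr/bin/env python
"""Bootstrap neighbor-joining trees for the phosphatase families.

For each family with enough members across the three genomes: progressive
multiple alignment (NJ guide tree, profile-profile BLOSUM62), NJ on
alignment p-distances, and column-bootstrap supports (200 replicates here;
the classical recipe uses 1000).  Trees are written as Newick with
supports as internal node labels.
"""

from pathlib import Path

from phosphatome.families import classify_genome
from phosphatome.genome_io import read_domain_table, read_genome
from phosphatome.phylogeny import bootstrap_support, progressive_msa, write_newick

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "synthetic_data"
FAMILIES = ("PP2C", "SPOIIE", "PPP_CANDIDATE", "ELK")
REPLICATES = 200
SEED = 2024


def main() -> None:
    gids = sorted((DATA / "genomes.txt").read_text().split())
    members: dict[str, list[tuple[str, str]]] = {f: [] for f in FAMILIES}
    for gid in gids:
        genome = read_genome(DATA, gid)
        calls = read_domain_table(DATA / f"{gid}.domains.tsv", genome)
        for a in classify_genome(genome, calls):
            if a.family in members:
                members[a.family].append(
                    (f"{gid}_{a.locus_tag}", genome.gene(a.locus_tag).protein)
                )

    for family, records in members.items():
        if len(records) < 4:
            print(f"{family}: only {len(records)} members, skipping tree")
            continue
        labels = [r[0] for r in records]
        msa = progressive_msa([r[1] for r in records], labels)
        tree = bootstrap_support(msa, n_replicates=REPLICATES, seed=SEED)
        out = ROOT / f"tree.{family}.nwk"
        out.write_text(write_newick(tree) + "\n")
        supports = sorted(
            n.support for n in _walk(tree.root) if n.support is not None
        )
        strong = sum(1 for s in supports if s >= 50)
        print(
            f"{family}: {len(records)} taxa, {len(supports)} internal edges, "
            f"{strong} with support >= 50 -> {out.name}"
        )


def _walk(node):
    yield node
    for child in node.children:
        yield from _walk(child)


if __name__ == "__main__":
    main()
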