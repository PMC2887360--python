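#!/usr/bin/env python
"""Generate the study's synthetic 3-genome dataset.

Three 200-gene replicons with planted kinase/phosphatase families,
signature motifs, star-shaped ortholog groups (5% per-residue divergence),
ELK-PP2C co-organized pairs at gene distances 0/2/5, and one conserved
phosphatase gene neighborhood shared by the first two genomes.  Inputs for
every later analysis step land in scratch/synthetic_data/ (regenerated on
demand; only derived tables are kept under results/).
"""

from pathlib import Path

from phosphatome.simulate import SimConfig, generate

OUT = Path(__file__).resolve().parent.parent / "scratch" / "synthetic_data"
SEED = 2024


def main() -> None:
    config = SimConfig(seed=SEED)
    result = generate(config, out_dir=OUT)
    print(f"wrote {len(result.genomes)} genomes to {OUT}")
    for gid in sorted(result.genomes):
        genome = result.genomes[gid]
        planted = sum(
            1 for f in result.truth.families[gid].values() if f != "OTHER"
        )
        print(f"  {gid}: {len(genome)} genes, {planted} planted family members")
    print(f"  ortholog groups: {len(result.truth.ortholog_groups)}")
    print(f"  co-organized pairs/genome: {len(config.coorg_distances)}")
    print(f"  synteny blocks (G0-G1): {config.n_synteny_blocks}")


if __name__ == "__main__":
    main()
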