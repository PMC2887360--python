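import pytest

from phosphatome.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def default_sim():
    """One noise-free synthetic 3-genome dataset shared across tests."""
    return generate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A compact 2-genome dataset for pipeline-level tests."""
    cfg = SimConfig(
        seed=5,
        n_genomes=2,
        genes_per_genome=100,
        family_counts={
            "ELK": 4, "PP2C": 3, "SPOIIE": 1, "PPP_CANDIDATE": 1,
            "APAH": 1, "PTP": 1, "RHODANESE": 1,
        },
        coorg_distances=(0, 2),
        n_synteny_blocks=1,
        synteny_neighbors=2,
        length_range=(120, 160),
    )
    return generate(cfg)
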