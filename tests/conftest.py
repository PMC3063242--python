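import random

import pytest

from frtscan import (
    PlantedSite,
    RepeatFamily,
    SyntheticGenomeSpec,
    default_consensus,
    generate_genome,
)

WT_FRT = "GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC"


@pytest.fixture(scope="session")
def model():
    return default_consensus()


@pytest.fixture()
def rng():
    return random.Random(20260930)


def random_windows(n, seed=0):
    """n random uppercase 34-mers."""
    r = random.Random(seed)
    return ["".join(r.choice("ACGT") for _ in range(34)) for _ in range(n)]


@pytest.fixture(scope="session")
def fixture_genome(tmp_path_factory, model):
    """A small multi-chromosome genome with plants and a repeat family,
    shared across tests that only read it."""
    spec = SyntheticGenomeSpec(
        chromosomes=[("chr1", 80_000, 0.41), ("chr2", 40_000, 0.45)],
        planted_sites=[
            PlantedSite("chr1", 5_000, k=8),
            PlantedSite("chr1", 20_000, k=7),
            PlantedSite("chr1", 41_000, k=5, orientation="-"),
            PlantedSite("chr2", 9_000, k=6),
        ],
        repeat_families=[RepeatFamily("chr2", copies=6, mutation_rate=0.0)],
        seed=11,
        contig_length=25_000,
    )
    out = tmp_path_factory.mktemp("genome")
    return generate_genome(spec, out, model)
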