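from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

import mitocompare as mc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: where the GenBank records deposited for the study would live, if present
DEPOSITED_DIR = Path(__file__).parent / "data" / "deposited"


def deposited(accession: str) -> Path:
    return DEPOSITED_DIR / f"{accession}.gb"


@pytest.fixture(scope="session")
def default_genome():
    """The stachybotrys-like fixture genome and its plant log (seed 1)."""
    return mc.generate_mitogenome(mc.GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def cohort(default_genome):
    """Three near-identical individuals with planted mutations (seed 7)."""
    genome, _ = default_genome
    records, log = mc.mutate_individuals(genome, 3, 36, 33, seed=7)
    return genome, records, log


def make_toy_genome(
    sequence: str,
    features: list[tuple],
    genome_id: str = "toy",
    circular: bool = True,
) -> mc.MitoGenome:
    """Build a small genome from (name, kind, segments[, strand]) tuples."""
    feats = []
    for f in features:
        name, kind, segments = f[0], f[1], f[2]
        strand = f[3] if len(f) > 3 else 1
        feats.append(mc.GeneFeature(name, kind, list(segments), strand))
    return mc.MitoGenome(genome_id, sequence, circular, feats)
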