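import numpy as np
import pytest
from hypothesis import settings

from snppop.genotype_io import GenotypeMatrix, HaplotypeMatrix, MarkerRecord
from snppop.simulate import SimConfig, simulate_population

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_markers(positions, chromosomes=None, prefix="m"):
    """Marker list with A/B alleles at the given positions."""
    if chromosomes is None:
        chromosomes = [1] * len(positions)
    return [
        MarkerRecord(f"{prefix}{k}", int(c), int(p), "A", "B")
        for k, (c, p) in enumerate(zip(chromosomes, positions))
    ]


def make_genotypes(calls, positions=None, chromosomes=None, populations=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [(j + 1) * 10_000 for j in range(m)]
    markers = make_markers(positions, chromosomes)
    sample_ids = [f"s{i}" for i in range(n)]
    pops = populations or ["pop1"] * n
    return GenotypeMatrix(sample_ids, pops, markers, calls)


def make_haplotypes(haps, positions=None, chromosomes=None):
    haps = np.asarray(haps, dtype=np.uint8)
    n2, m = haps.shape
    assert n2 % 2 == 0
    if positions is None:
        positions = [(j + 1) * 10_000 for j in range(m)]
    markers = make_markers(positions, chromosomes)
    ids = [f"s{i}" for i in range(n2 // 2)]
    return HaplotypeMatrix(ids, ["pop1"] * len(ids), markers, haps)


@pytest.fixture(scope="session")
def wf_population():
    """One equilibrium Wright-Fisher population: 4 x 5 Mb chromosomes at
    ~58 kb output spacing, Ne=100, 100 diploids sampled (phased + genotypes)."""
    cfg = SimConfig(
        ne=100,
        n_generations=400,
        n_chromosomes=4,
        chrom_length_bp=5_000_000,
        marker_spacing_bp=58_000,
        sample_size=100,
        seed=42,
    )
    return simulate_population(cfg)
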