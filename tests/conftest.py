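import numpy as np
import pytest

from hicnets import ContactDomain, GenomicInterval, SyntheticGenomeSpec, generate_genome


def make_domain(chrom, start, end, label=None):
    return ContactDomain(GenomicInterval(chrom, start, end), label)


@pytest.fixture(scope="session")
def small_genome():
    """A compact synthetic genome shared by read-only tests."""
    spec = SyntheticGenomeSpec(n_chromosomes=3, domains_per_chromosome=40)
    return generate_genome(spec, seed=7)


@pytest.fixture(scope="session")
def banded_genome():
    """Synthetic genome with planted trans bands (DR-signal tests)."""
    spec = SyntheticGenomeSpec(
        n_chromosomes=3,
        domains_per_chromosome=80,
        band_amplitude=3.0,
        band_fraction=0.2,
    )
    return generate_genome(spec, seed=11)


@pytest.fixture(scope="session")
def boosted_genome():
    """Synthetic genome with homotypic cis and A1 trans boosts (enrichment tests)."""
    spec = SyntheticGenomeSpec(
        n_chromosomes=3,
        domains_per_chromosome=80,
        homotypic_boost=3.0,
        a1_trans_boost=3.0,
    )
    return generate_genome(spec, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
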