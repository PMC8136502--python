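import numpy as np
import pytest

from sineboundary.config import SimConfig
from sineboundary import synthetic


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Down-scaled study conditions shared across tests (200 kb genomes)."""
    return SimConfig(
        seed=7,
        genome_length=200_000,
        n_shared_insertions=60,
        n_specific_insertions_per_strain=15,
        insertion_length_range=(150, 250),
        n_reads=20_000,
        peak_count=10,
        plant_short_control=True,
        plant_low_occupancy_control=True,
    )


@pytest.fixture(scope="session")
def small_library(small_cfg):
    return synthetic.make_consensus_library(small_cfg)


@pytest.fixture(scope="session")
def small_genomes(small_cfg, small_library):
    return synthetic.simulate_genome_pair(small_cfg, small_library)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
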