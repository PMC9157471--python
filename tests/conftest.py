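import numpy as np
import pytest

from splicewindow.sequence_io import GenomeSequence
from splicewindow.synthetic_genome import SimulationParams, simulate_genome


BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome():
    """~20 kb genome with planted introns, shared across read-only tests."""
    params = SimulationParams(n_genes=15, introns_per_gene=(1, 3), seed=99)
    return simulate_genome(params)


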