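import numpy as np
import pytest

from bearlink.datatypes import GenotypeTable
from bearlink.simulate import SimulationConfig, generate_genotypes


@pytest.fixture
def toy_genotypes() -> GenotypeTable:
    """4 individuals x 3 loci, hand-checkable allele counts."""
    alleles = np.array([
        [[1, 1], [2, 3], [1, 2]],
        [[1, 2], [2, 2], [1, 1]],
        [[2, 2], [3, 3], [2, 2]],
        [[1, 1], [2, 3], [0, 0]],
    ])
    return GenotypeTable(["a", "b", "c", "d"], ["L1", "L2", "L3"], alleles)


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture
def synthetic_genotypes(default_config):
    return generate_genotypes(default_config)
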