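import numpy as np
import pytest

from g4utr.maps_model import MutationRateTable
from g4utr.oe_substitution import HeptamerSubstitutionTable
from g4utr.synthetic_data import (
    SimulationConfig,
    make_transcriptome,
    random_heptamer_table,
    random_rate_table,
)


@pytest.fixture(scope="session")
def cfg() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_transcriptome():
    """60-gene synthetic transcriptome with planted motifs (seed 7)."""
    return make_transcriptome(SimulationConfig(n_genes=60), seed=7)


@pytest.fixture(scope="session")
def rate_table() -> MutationRateTable:
    return random_rate_table(seed=1)


@pytest.fixture(scope="session")
def heptamer_table() -> HeptamerSubstitutionTable:
    return random_heptamer_table(seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
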