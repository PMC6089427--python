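import numpy as np
import pytest
from hypothesis import settings

from barcodedelim import SimConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def three_lineage_sim():
    """Three clearly separated lineages of four sequences each."""
    return simulate_dataset(SimConfig(n_lineages=3, seqs_per_lineage=4, seed=11))


@pytest.fixture(scope="session")
def ten_lineage_sim():
    """The default study conditions: 10 lineages x 5, intra 0.005, inter 0.08."""
    return simulate_dataset(SimConfig(seed=2024))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
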