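import numpy as np
import pytest

from clonescape import simulate_genome


@pytest.fixture(scope="session")
def small_annotation():
    return simulate_genome(n_genes=200, n_chromosomes=4, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
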