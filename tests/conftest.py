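import numpy as np
import pytest

from ampedit import ReadSimConfig, example_spec, simulate_reads


@pytest.fixture(scope="session")
def spec():
    """A 250 bp single-cut amplicon with one donor substitution."""
    return example_spec(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def errorfree_sim(spec):
    """2,000 error-free reads at the default outcome proportions."""
    return simulate_reads(ReadSimConfig(spec=spec, n_reads=2000, seed=7, error_rate=0.0))
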