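import numpy as np
import pytest

from staa.synthetic import SyntheticConfig, generate, standard_tissue


@pytest.fixture(scope="session")
def tissue():
    """The canonical 600-spot, 4-strip-domain fixture."""
    return standard_tissue()


@pytest.fixture(scope="session")
def small_tissue():
    """A 100-spot, 2-domain tissue for fast training contracts."""
    return generate(SyntheticConfig(n_spots=100, n_genes=60, n_domains=2,
                                    marker_genes_per_domain=8, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
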