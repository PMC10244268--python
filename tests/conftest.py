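import numpy as np
import pytest
from hypothesis import settings

import pdise as P

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """200-site, 30-taxon Gaussian-niche community with its generating truth."""
    config = P.SimulationConfig(n_sites=200, n_taxa=30, seed=7)
    chem = P.generate_gradient(config)
    niches = P.generate_niches(config)
    matrix = P.generate_community(chem, niches, config)
    return matrix, chem, niches, config


@pytest.fixture(scope="session")
def bimodal_dataset():
    """800-site two-pool community with strongly suppressed intermediates."""
    config = P.SimulationConfig(
        n_sites=800, n_taxa=150, bimodal=True, suppression=0.2, seed=11
    )
    chem = P.generate_gradient(config)
    niches = P.generate_niches(config)
    matrix = P.generate_bimodal_regime(chem, niches, config)
    return matrix, chem, niches, config


@pytest.fixture(scope="session")
def shared_null_800():
    """Null dip distribution at n=800, shared across Monte-Carlo tests."""
    return P.null_dip_distribution(800, 500, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
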