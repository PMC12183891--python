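import numpy as np
import pytest

from vipertherm import SyntheticConfig, TaxonTraits, generate_dataset
from vipertherm.ectotherm import cylinder_geometry


@pytest.fixture(scope="session")
def small_dataset():
    """12 synthetic sites with all 7 scenarios, 3 taxa, and truth."""
    cfg = SyntheticConfig(n_sites=12, seed=7)
    sites, taxa, truth = generate_dataset(cfg, n_taxa=3)
    return cfg, sites, taxa, truth


@pytest.fixture
def viper_traits():
    return TaxonTraits(name="viper", vtmax=33.0, mass=100.0)


@pytest.fixture
def viper_geom(viper_traits):
    return cylinder_geometry(viper_traits)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
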