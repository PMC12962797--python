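import numpy as np
import pandas as pd
import pytest

from metabeta import ArchetypeConfig, AssemblageSet, generate_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_landscape():
    """A small mixed-archetype landscape shared across tests."""
    cfg = ArchetypeConfig(n_species=100, seed=7, sampling_fraction=0.25)
    return generate_landscape(n_sites=3, patches_per_district=9, config=cfg)


@pytest.fixture
def two_patch_half_overlap():
    """Two equal-size patches sharing half their equally-abundant species."""
    counts = pd.DataFrame(
        {"p1": [1, 1, 1, 1, 0, 0], "p2": [0, 0, 1, 1, 1, 1]},
        index=[f"s{i}" for i in range(6)])
    return AssemblageSet(counts, site="S", district="D", treatment="control")
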