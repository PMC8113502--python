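import numpy as np
import pandas as pd
import pytest

from phylotraits.io import TRAIT_COLUMNS, SiteDesign, TraitTable
from phylotraits.simulate import SyntheticConfig, simulate_dataset


def make_tiny_frame(**overrides) -> pd.DataFrame:
    """Three-row trait table covering two sites and two species."""
    base = {
        "tree_id": ["t1", "t2", "t3"],
        "species": ["Ocotea alpina", "Ocotea alpina", "Clusia dura"],
        "plot": ["P1000_1", "P1000_1", "P2000_1"],
        "site": [1000, 1000, 2000],
    }
    rng = np.random.default_rng(0)
    for i, c in enumerate(TRAIT_COLUMNS):
        base[c] = np.round(np.exp(rng.normal(1 + 0.1 * i, 0.2, 3)), 4)
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def tiny_table() -> TraitTable:
    return TraitTable(make_tiny_frame())


@pytest.fixture(scope="session")
def sim_data():
    """Default synthetic gradient: 3 sites x 3 plots, 20/20/12 species,
    8-10 individuals per species."""
    return simulate_dataset(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_sim_data():
    """Reduced gradient for fast end-to-end tests."""
    design = SiteDesign(
        species_per_site=(6, 6, 4), individuals_min=5, individuals_max=6
    )
    return simulate_dataset(SyntheticConfig(seed=7, design=design))
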