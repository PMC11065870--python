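import numpy as np
import pytest

from glycolattice.glycomass import AdductTable, ResidueTable
from glycolattice.synthesize import SimulationConfig


@pytest.fixture(scope="session")
def residues() -> ResidueTable:
    return ResidueTable.default()


@pytest.fixture(scope="session")
def adducts() -> AdductTable:
    return AdductTable.default()


@pytest.fixture()
def clean_config() -> SimulationConfig:
    """WT-like glycoform population without PTM/lipid adducts or noise."""
    return SimulationConfig(
        seed=11, n_samples=1500, noise_level=0.0, phospho_prob=0.0, lipid_site_probs={}
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
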