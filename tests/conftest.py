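import numpy as np
import pandas as pd
import pytest

from pathcna.catalog import default_catalog
from pathcna.graphfeat import NetworkFeatureCache
from pathcna.netbuild import ProfileMatrix, common_metabolites, network_from_profile
from pathcna.synthfix import SimulationConfig, simulate_panel, toy5


@pytest.fixture(scope="session")
def toy():
    return toy5()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


#: scaled-down simulation used where full defaults would be needlessly slow
SMALL_SIM = SimulationConfig(n_lines=40, n_blocks=6, block_size_min=3, block_size_max=6,
                             n_distractors=10, n_instances_per_class=8, seed=7)


@pytest.fixture(scope="session")
def small_panel():
    return simulate_panel(SMALL_SIM)


@pytest.fixture(scope="session")
def small_networks(small_panel):
    profiles, _ = small_panel
    return [network_from_profile(p) for p in profiles]


@pytest.fixture(scope="session")
def small_caches(small_networks):
    return {n.season_label: NetworkFeatureCache(n, seed=0) for n in small_networks}


@pytest.fixture(scope="session")
def small_common(small_networks):
    return common_metabolites(small_networks)


@pytest.fixture()
def tiny_profile():
    rng = np.random.default_rng(11)
    data = pd.DataFrame(rng.normal(size=(20, 6)),
                        index=[f"s{i}" for i in range(20)],
                        columns=list("ABCDEF"))
    return ProfileMatrix(data, "tiny")
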