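import numpy as np
import pandas as pd
import pytest

from oncodep import synthetic_data as sd
from oncodep.screen_io import SampleMeta


@pytest.fixture(scope="session")
def small_scenario():
    return sd.ScreenScenario(n_genes=100, guides_per_gene=4,
                             n_control_guides=50, seed=7)


@pytest.fixture(scope="session")
def small_library(small_scenario):
    return sd.simulate_library(small_scenario)


@pytest.fixture(scope="session")
def small_design():
    return sd.standard_design(n_replicates=2, control_replicates=2)


@pytest.fixture(scope="session")
def small_screen(small_library, small_design, small_scenario):
    return sd.simulate_screen(small_library, small_design, small_scenario)


@pytest.fixture
def tiny_counts():
    """4 guides x 3 samples with a plasmid column, hand-sized for arithmetic."""
    from oncodep.screen_io import CountMatrix

    counts = pd.DataFrame(
        {"plasmid": [100, 200, 300, 400],
         "A_DMSO_1": [10, 20, 30, 40],
         "A_DMSO_2": [400, 300, 200, 100]},
        index=["g1", "g2", "g3", "g4"])
    counts.index.name = "guide_id"
    samples = [SampleMeta("plasmid", "other", "plasmid", 1),
               SampleMeta("A_DMSO_1", "control", "DMSO", 1),
               SampleMeta("A_DMSO_2", "control", "DMSO", 2)]
    return CountMatrix(counts, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
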