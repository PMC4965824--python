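import io as _stringio

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from biofacies.io import OtuTable, SampleMetadata, WellLog
from biofacies.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def three_tip_tree():
    return TreeNode.read(_stringio.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def four_tip_tree():
    return TreeNode.read(_stringio.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def tiny_table():
    return OtuTable(
        taxa_ids=("A", "B", "C"),
        sample_ids=("s1", "s2"),
        counts=np.array([[900, 100], [100, 800], [0, 100]]),
    )


@pytest.fixture
def metadata_two_facies():
    frame = pd.DataFrame(
        {
            "well_id": ["W1", "W1"],
            "facies": ["oxidized", "reduced"],
            "elevation_m": [98.0, 96.5],
            "rel_elevation_m": [0.6, -0.9],
        },
        index=["s1", "s2"],
    )
    return SampleMetadata(frame)


@pytest.fixture
def well_logs_four():
    return [
        WellLog("C7870", 0.0, 0.0, 115.2, 98.4, 97.4),
        WellLog("C7869", 20.0, 0.0, 114.7, 101.9, 100.7),
        WellLog("C7868", 0.0, 20.0, 114.8, 97.7, 97.4),
        WellLog("C7867", 20.0, 20.0, 115.2, 97.2, 94.8),
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study (20 samples, 64 taxa)."""
    config = SimulationConfig(
        seed=7, n_taxa=64, n_wells=2, depths_per_well=5, replicates_per_depth=2
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def default_dataset():
    """The default-scale synthetic study (80 samples, 256 taxa)."""
    return simulate_dataset(SimulationConfig(seed=11))
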