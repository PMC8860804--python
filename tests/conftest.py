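import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small two-condition dataset with one planted lag link and one
    planted PAC link, shared across tests that only need structure."""
    from dirconn.simulate import (
        PlantedLagLink,
        PlantedPacLink,
        SimulationConfig,
        gen_dataset,
    )

    cfg = SimulationConfig(
        n_subjects=3,
        n_rois=6,
        n_trials=2,
        trial_duration=4.0,
        artifact_fraction=0.1,
        planted_dpli_links=(PlantedLagLink(0, 1, 0.5, 0.9),),
        planted_pac_links=(PlantedPacLink(2, 3, 0.9),),
        seed=11,
    )
    return gen_dataset(cfg)
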