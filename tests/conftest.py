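import numpy as np
import pytest

from band.data import TrialDataset
from band.simulate import SimConfig, generate_dataset


def tiny_sim_config(**overrides) -> SimConfig:
    """Small, fast simulator configuration shared across unit tests."""
    defaults = dict(
        n_neurons=12,
        T=40,
        prep_bins=15,
        trials_per_epoch={"BL": 2, "AD": 2, "WO": 2},
        seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset():
    dataset, truth = generate_dataset(tiny_sim_config())
    return dataset, truth


@pytest.fixture()
def toy_dataset():
    """Hand-built 10-trial dataset with controlled labels."""
    rng = np.random.default_rng(42)
    spikes = rng.poisson(0.3, size=(10, 20, 4))
    behavior = rng.normal(0.0, 5.0, size=(10, 20, 2))
    return TrialDataset(
        spikes=spikes,
        behavior=behavior,
        bin_width=0.01,
        condition=np.arange(10) % 5 + 1,
        epoch=np.array(["BL"] * 4 + ["AD"] * 3 + ["WO"] * 3),
        prep_bins=8,
    )
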