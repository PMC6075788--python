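import numpy as np
import pytest

from strsa.preprocess import EpochSet
from strsa.synthetic import EpochTiming, gen_epochs, gen_feature_banks, gen_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs(rng):
    """4 electrodes x 50 samples x 12 trials, 3 categories, 250 Hz."""
    times = np.arange(-40.0, 160.0, 4.0)
    cats = ("a", "b", "c")
    labels = np.array(list(cats) * 4, dtype=object)
    voltages = rng.normal(0, 5.0, size=(4, len(times), 12))
    return EpochSet(
        voltages=voltages,
        labels=labels,
        times=times,
        sampling_hz=250.0,
        participant_id="sub-xx",
        categories=cats,
    )


@pytest.fixture(scope="session")
def desk_layout():
    return gen_layout(32, 0.45, seed=7)


@pytest.fixture(scope="session")
def desk_banks_truth():
    return gen_feature_banks(
        30, 10, (20,) * 8, np.linspace(0.2, 3.0, 8), seed=3, noise_sd=10.0
    )


@pytest.fixture(scope="session")
def desk_epochs(desk_layout, desk_banks_truth):
    banks, truth = desk_banks_truth
    return gen_epochs(
        desk_layout,
        banks,
        truth,
        n_trials_per_category=10,
        epoch=EpochTiming(100.0, 750.0, 250.0),
        seed=21,
        participant_id="sub-00",
    )
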