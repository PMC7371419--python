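import numpy as np
import pytest

import reactime as rt


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size simulation settings shared by the fast tests."""
    return rt.SimConfig(n_subjects=1, n_trials_per_class=30, noise_scale=1.0, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return rt.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_evidence(small_config, small_dataset):
    train, test, _ = small_dataset
    win = rt.informative_train_window(small_config)
    tt = train.times[rt.window_indices(train.times, *win)]
    return rt.crossval_evidence(train, tt, k_folds=5, seed=0, test_epochs=test)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, labels, fs=300.0, subjects=None, t0=0.0):
    data = np.asarray(data, dtype=float)
    times = t0 + np.arange(data.shape[2]) / fs
    return rt.Epochs(data, labels, times, fs, subjects)
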