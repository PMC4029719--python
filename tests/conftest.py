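import numpy as np
import pytest

from emgexo import (
    ActivationParams,
    TrialConfig,
    WindowSpec,
    generate_session,
    generate_trial,
    make_dataset,
    split_data,
    train,
)
from emgexo.network import TrainSpec


@pytest.fixture
def window_1024() -> WindowSpec:
    return WindowSpec(fs_hz=1024.0)


@pytest.fixture
def config_4s() -> TrialConfig:
    return TrialConfig(period_s=4.0, seed=7)


@pytest.fixture
def trial_4s(config_4s):
    return generate_trial(config_4s, ActivationParams())


@pytest.fixture(scope="session")
def small_session():
    """12 trials at T=4 s: enough for a real train/test split, fast."""
    cfg = TrialConfig(period_s=4.0, seed=11)
    return generate_session(cfg, ActivationParams(), n_trials=12)


@pytest.fixture(scope="session")
def trained_model(small_session):
    """A model trained on the small session plus its held-out split."""
    window = WindowSpec(fs_hz=1024.0)
    ds = make_dataset(small_session, window)
    train_set, test_set = split_data(ds, 0.8, seed=11)
    model, losses = train(train_set, TrainSpec(seed=11))
    return model, train_set, test_set, losses


def brute_force_rms(x: np.ndarray, length: int, step: int) -> np.ndarray:
    """Independent per-window re-evaluation of the RMS definition."""
    x = np.atleast_2d(x)
    out = []
    start = 0
    while start + length <= x.shape[-1]:
        w = x[:, start : start + length]
        out.append(np.sqrt(np.sum(w**2, axis=-1) / length))
        start += step
    return np.array(out)
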