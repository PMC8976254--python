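import warnings
from datetime import date

import numpy as np
import pytest

from sleepverse.preprocess import SensorConfig
from sleepverse.synthetic import SimulationParams, simulate_dataset
from sleepverse.windows import grid_from_string

warnings.filterwarnings("ignore", category=UserWarning, module="statsmodels")
warnings.filterwarnings("ignore", category=RuntimeWarning, module="statsmodels")


@pytest.fixture(scope="session")
def tiny_params():
    return SimulationParams(
        n_participants=4,
        n_days=14,
        seed=11,
        effect_sizes={"ssq": {"sleep_time": 4.0}},
        noise_sd={"ssq": 8.0, "na": 8.0, "depression": 8.0},
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_params):
    return simulate_dataset(tiny_params)


@pytest.fixture(scope="session")
def noise_free_dataset():
    params = SimulationParams(
        n_participants=3,
        n_days=4,
        seed=5,
        sensor_flip_prob=0.0,
        notification_flash_rate=0.0,
        accel_sleep_noise_sd=0.0,
    )
    return params, simulate_dataset(params)


def make_grid(states: str, pid="p1", night=date(2024, 3, 4), sensor="charging"):
    """Build a NightGrid from a compact state string; the string is
    right-padded with awake windows to 144 entries."""
    padded = states + "a" * (144 - len(states))
    return grid_from_string(pid, night, SensorConfig(sensor), padded)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
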