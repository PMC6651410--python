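import numpy as np
import pytest

from comcop.synthetic import NoiseSpec, sample_subject, simulate_trial


@pytest.fixture(scope="session")
def subject():
    return sample_subject(7)


@pytest.fixture(scope="session")
def trial(subject):
    return simulate_trial(subject, "normal", seed=3)


@pytest.fixture(scope="session")
def quiet_trial(subject):
    """Same motion as ``trial`` but with a noise-free IMU."""
    silent = NoiseSpec(accel_sigma=0.0, gyro_sigma=0.0, mag_sigma=0.0, drift_rate=0.0)
    return simulate_trial(subject, "normal", seed=3, noise=silent)


@pytest.fixture
def rng():
    # fresh, seeded stream per test so results are order-independent
    return np.random.default_rng(12345)
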