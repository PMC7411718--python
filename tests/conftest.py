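import numpy as np
import pytest

from gaitid.io_insole import FootChannels, InsoleRecording
from gaitid.synthetic import simulate_cohort


def random_recording(rng: np.random.Generator, n_left=None, n_right=None):
    """A random recording that satisfies the sensor data model."""
    n_left = n_left or int(rng.integers(1, 40))
    n_right = n_right or int(rng.integers(1, 40))

    def block(n):
        return FootChannels(
            pressure=rng.integers(0, 3, size=(n, 8)),
            accel=rng.integers(-32768, 32769, size=(n, 3)),
            rotation=rng.integers(-32768, 32769, size=(n, 3)),
        )

    return InsoleRecording(
        participant_id="PX",
        sampling_rate_hz=100.0,
        left=block(n_left),
        right=block(n_right),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """4 participants, 1 min each, noisy swing pressure; shared across tests."""
    return simulate_cohort(4, duration_s=60.0, spur_rate=0.05, seed=11)


@pytest.fixture(scope="session")
def clean_cohort():
    """3 participants with no spurious swing pressure."""
    return simulate_cohort(3, duration_s=45.0, spur_rate=0.0, seed=5)
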