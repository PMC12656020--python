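import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_stream():
    """3-frame, 2-landmark stream for IO round trips."""
    from fixkit.io import LandmarkStream

    return LandmarkStream(
        fps=30.0,
        frame_index=np.array([0, 1, 2]),
        landmark_ids=np.array([33, 133]),
        coords=np.array(
            [
                [[1.0, 2.0], [3.0, 4.0]],
                [[1.5, 2.5], [3.5, 4.5]],
                [[0.1234567891234567, 2.0], [3.0, 4.0]],
            ]
        ),
    )


@pytest.fixture(scope="session")
def quiet_recording():
    """Short default-noise simulated recording shared across tests."""
    from fixkit.simulate import GazeSimConfig, simulate_recording

    return simulate_recording(GazeSimConfig(seed=7, duration_s=8.0))
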