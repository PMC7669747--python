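import numpy as np
import pytest

from ispt import SimConfig, Trajectory, simulate_trajectory


@pytest.fixture(scope="session")
def brownian_traj():
    """Free 2D Brownian motion at membrane-typical D, 30 kfps."""
    cfg = SimConfig(model="brownian", diffusion_coefficient=1e5,
                    framerate=30_000, n_frames=20_000, seed=11)
    return simulate_trajectory(cfg)


@pytest.fixture(scope="session")
def stepper_traj():
    """Noisy 8 nm stepper along +x (motor-like transport)."""
    cfg = SimConfig(model="stepper", step_size=8.0, dwell_rate=2.0,
                    framerate=1_000, n_frames=25_000, track_axis=[1.0, 0.0],
                    jitter_sigma=2.0, diffusion_coefficient=0.0, seed=5)
    return simulate_trajectory(cfg)


@pytest.fixture
def toy_1d_traj():
    """5-point 1D toy trajectory used for hand-enumerated MSD values."""
    x = np.array([0.0, 1.0, 3.0, 2.0, 4.0])
    return Trajectory(position=np.column_stack([x, np.zeros(5)]),
                      framerate=1.0)
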