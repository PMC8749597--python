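import numpy as np
import pytest

from camimu.motion import ReachParams, simulate_session


@pytest.fixture(scope="session")
def noiseless_params() -> ReachParams:
    """Short-cadence reaching cycle with tremor disabled."""
    return ReachParams(hold_start_s=1.0, jitter_sd=0.0)


@pytest.fixture(scope="session")
def tiny_session(noiseless_params):
    """Two noiseless cycles plus the exact kinematic IMU target."""
    return simulate_session(noiseless_params, 2, seed=7, imu_noise_sd=0.0)


@pytest.fixture(scope="session")
def toy_features(tiny_session):
    """Normalized 3D features straight from world-frame joints (no camera),
    windowed against the kinematic acceleration — a clean regression toy."""
    from camimu.features import NormStats, window_series

    traj, imu = tiny_session
    coords = traj.stacked()
    ls = coords[:, 1]
    rel = np.concatenate([coords[:, i] - ls for i in (0, 2, 3)], axis=1)
    d = np.stack([np.linalg.norm(coords[:, i] - ls, axis=1) for i in (0, 2, 3)], axis=1)
    vals = np.concatenate([rel, d], axis=1)
    stats = NormStats.fit(vals)
    return window_series(stats.apply(vals), imu.acc, window=25, stride=1)
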