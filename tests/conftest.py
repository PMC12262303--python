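import numpy as np
import pytest

from condyn.io import Trajectory


def make_traj(points, dt=2.0, track_id=0, frames=None):
    """Trajectory from an (N, 2) position list in um."""
    pts = np.asarray(points, dtype=float)
    if frames is None:
        frames = np.arange(len(pts))
    return Trajectory(track_id=track_id, frames=frames, x=pts[:, 0], y=pts[:, 1], dt=dt)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
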