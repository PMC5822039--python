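import numpy as np
import pytest

from emtmosaic.geometry import Intrinsics, Plane
from emtmosaic.synthetic import EMTNoiseConfig, SceneConfig, make_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def intrinsics():
    return Intrinsics(fx=300.0, fy=300.0, cx=183.5, cy=188.5)


@pytest.fixture(scope="session")
def plane50():
    return Plane.from_normal_distance([0, 0, 1], 50.0)


@pytest.fixture(scope="session")
def noisefree_seq():
    """30 circular frames, exact measurements and correspondences."""
    cfg = SceneConfig(n_frames=30, laps=0.6, seed=1)
    return make_sequence(cfg, EMTNoiseConfig(nu=0.0, seed=1),
                         sigma_v=0.0, n_points=30)


@pytest.fixture(scope="session")
def noisy_seq20():
    """20 circular frames with sigma_v = 1 px and nu = 1 tracker noise."""
    cfg = SceneConfig(n_frames=20, laps=0.4, seed=3)
    return make_sequence(cfg, EMTNoiseConfig(nu=1.0, seed=3),
                         sigma_v=1.0, n_points=50)


@pytest.fixture(scope="session")
def noisy_seq30():
    """30 circular frames with sigma_v = 1 px and nu = 1 tracker noise."""
    cfg = SceneConfig(n_frames=30, laps=0.6, seed=0)
    return make_sequence(cfg, EMTNoiseConfig(nu=1.0, seed=0),
                         sigma_v=1.0, n_points=50)


def random_pose(rng, rot_scale=0.3, trans_scale=10.0):
    from emtmosaic.geometry import Pose

    r = rng.normal(0, rot_scale, 3)
    n = np.linalg.norm(r)
    if n >= np.pi:
        r *= (np.pi - 1e-3) / n
    return Pose(r, rng.normal(0, trans_scale, 3))
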