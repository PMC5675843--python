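import numpy as np
import pytest

from aecvision import gassom
from aecvision import scenes as sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bank():
    """20 subspaces over a 30-d patch space: fast to scan by brute force."""
    return gassom.init_bank(20, seed=7, dim=30)


@pytest.fixture
def desk_geometry():
    return sc.FixationGeometry(window_base=25, max_shift=40)


@pytest.fixture
def two_plane_scene():
    """Two textured planes at distinct disparities over a flat background."""
    cfg = sc.SceneConfig(
        n_planes=2, background_texture="flat", disparity_range=(-20, 20)
    )
    return sc.generate_scene(
        cfg, 42,
        plane_disparities=[-6, 10],
        plane_rects=[(60, 140, 100, 170), (120, 200, 180, 260)],
    )


def random_orthonormal_basis(rng, dim):
    """Independent oracle helper: a random (dim, 2) orthonormal basis via QR."""
    q, _ = np.linalg.qr(rng.standard_normal((dim, 2)))
    return q
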