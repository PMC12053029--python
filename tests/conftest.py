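import numpy as np
import pytest

from suspendkin.correction import SegmentLengths
from suspendkin.geometry import CameraDLT
from suspendkin.simulate import pinhole_dlt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bv1_lengths():
    """Segment lengths of one study individual (cm): arm 17, forearm 17.5,
    thigh 11.5, leg 11.5."""
    return SegmentLengths.from_cm("BV1", "left", 17.0, 17.5, 11.5, 11.5)


@pytest.fixture
def camera_pair():
    """Two exact synthetic pinhole cameras viewing the origin."""
    return {
        "cam1": pinhole_dlt("cam1", np.array([0.0, 2.0, 0.3]), np.zeros(3)),
        "cam2": pinhole_dlt("cam2", np.array([1.5, 1.5, -0.2]), np.zeros(3)),
    }


def random_rig(rng, n_cams=2):
    """A random non-degenerate camera rig around the working volume."""
    cams = {}
    for i in range(n_cams):
        azim = rng.uniform(0, 2 * np.pi)
        radius = rng.uniform(1.5, 3.0)
        pos = np.array(
            [radius * np.cos(azim), radius * np.sin(azim), rng.uniform(-0.5, 0.5)]
        )
        cams[f"cam{i + 1}"] = pinhole_dlt(
            f"cam{i + 1}", pos, rng.uniform(-0.05, 0.05, size=3),
            focal_px=rng.uniform(1000, 2000),
        )
    return cams


@pytest.fixture
def cube_points():
    """Corners of a 1 m cube centred on the origin (non-coplanar)."""
    return np.array(
        [(x, y, z) for x in (-0.5, 0.5) for y in (-0.5, 0.5) for z in (-0.5, 0.5)]
    )
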