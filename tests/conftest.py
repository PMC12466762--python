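import numpy as np
import pytest

from bovimetry.frames import LANDMARK_NAMES, CameraIntrinsics, Keypoint, KeypointSet
from bovimetry.phantom import PhantomSpec, render_phantom


@pytest.fixture(scope="session")
def printed_intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(fx=525.0, fy=525.0, cx=319.5, cy=239.5)


@pytest.fixture(scope="session")
def phantom_capture():
    """One noiseless default phantom render, shared across the session."""
    spec = PhantomSpec(seed=11)
    return spec, *render_phantom(spec)


def make_keypoint_set(coords, bbox_area=10000.0, visibility=None, confidence=None):
    """KeypointSet from a (6, 2) array of (u, v) coordinates."""
    coords = np.asarray(coords, dtype=float)
    visibility = visibility or [2] * len(LANDMARK_NAMES)
    confidence = confidence or [1.0] * len(LANDMARK_NAMES)
    kps = [
        Keypoint(name, float(coords[i, 0]), float(coords[i, 1]),
                 visibility=visibility[i], confidence=confidence[i])
        for i, name in enumerate(LANDMARK_NAMES)
    ]
    return KeypointSet(kps, bbox_area=bbox_area)


@pytest.fixture
def square_keypoints():
    """Six keypoints on a simple grid with a 100x100 box."""
    coords = [[10, 10], [110, 10], [10, 110], [110, 110], [60, 60], [70, 60]]
    return make_keypoint_set(coords, bbox_area=10000.0)
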