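"""Pinhole back-projection, rigid transforms, point-cloud filtering, ground plane.

The camera frame follows the usual computer-vision convention: +Z along the
optical axis into the scene, +X right, +Y down in the image.  Back-projection
of a pixel (u, v) with depth Z is

    X = (u - cx) * Z / fx,   Y = (v - cy) * Z / fy,   Z = Z.

World coordinates are obtained with a rigid transform p_world = R p_cam + T;
the world up axis is +Z (heights are world-Z differences).  The pass-through
filter keeps points whose camera-frame Z lies in the open interval (z1, z2),
removing e.g. background returns beyond 5 m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import CameraIntrinsics, Extrinsics, RGBDFrame

__all__ = [
    "PointCloud",
    "FilterRange",
    "GroundPlane",
    "MissingDepthError",
    "GroundEstimationError",
    "backproject",
    "project",
    "frame_to_cloud",
    "passthrough_filter",
    "to_world",
    "estimate_ground",
    "save_ply",
    "load_ply",
    "save_pcd",
    "load_pcd",
]

WORLD_UP = np.array([0.0, 0.0, 1.0])


class MissingDepthError(ValueError):
    """A pixel needed for back-projection has no valid depth."""


class GroundEstimationError(RuntimeError):
    """Too few points near the hoof hints to estimate the ground plane."""


@dataclass
class PointCloud:
    """Metric 3-D points with an explicit frame tag ('camera' or 'world')."""

    points: np.ndarray
    frame: str = "camera"

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if p.size and not np.all(np.isfinite(p)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.frame not in ("camera", "world"):
            raise ValueError(f"frame must be 'camera' or 'world', got {self.frame!r}")
        self.points = p

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class FilterRange:
    """Open interval (z1, z2) in meters for the pass-through filter."""

    z1: float
    z2: float

    def __post_init__(self) -> None:
        if not self.z1 < self.z2:
            raise ValueError(f"need z1 < z2, got ({self.z1}, {self.z2})")


@dataclass(frozen=True)
class GroundPlane:
    """Ground elevation z0 along the world up axis with its supporting points."""

    z0: float
    normal: np.ndarray
    support_count: int

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-9):
            raise ValueError("ground normal must be a unit vector")
        object.__setattr__(self, "normal", n)


def backproject(u, v, Z, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Map pixel(s) + depth(s) to camera-frame 3-D point(s) (inverse pinhole).

    Scalar inputs yield a (3,) point; array inputs broadcast to (N, 3).
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    if np.any(Z <= 0):
        bad = np.argwhere(np.atleast_1d(Z) <= 0).ravel()
        raise MissingDepthError(
            f"non-positive depth at pixel index {bad[0]} "
            f"(u={np.atleast_1d(u)[min(bad[0], u.size - 1)] if u.size else u}, "
            f"v={np.atleast_1d(v)[min(bad[0], v.size - 1)] if v.size else v})"
        )
    X = (u - intrinsics.cx) * Z / intrinsics.fx
    Y = (v - intrinsics.cy) * Z / intrinsics.fy
    pts = np.stack(np.broadcast_arrays(X, Y, Z), axis=-1)
    return pts if pts.ndim > 1 else pts.reshape(3)


def project(point, intrinsics: CameraIntrinsics) -> tuple[np.ndarray, np.ndarray]:
    """Forward pinhole model: camera-frame point(s) -> subpixel (u, v)."""
    p = np.asarray(point, dtype=np.float64)
    X, Y, Z = p[..., 0], p[..., 1], p[..., 2]
    if np.any(Z <= 0):
        raise ValueError("cannot project points at or behind the camera plane")
    return intrinsics.fx * X / Z + intrinsics.cx, intrinsics.fy * Y / Z + intrinsics.cy


def frame_to_cloud(frame: RGBDFrame, stride: int = 1) -> PointCloud:
    """Back-project every valid-depth pixel (sampled at ``stride``) to a cloud."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    d = frame.depth.values[::stride, ::stride]
    vv, uu = np.mgrid[0: frame.shape[0]: stride, 0: frame.shape[1]: stride]
    valid = d > 0
    pts = backproject(uu[valid], vv[valid], d[valid], frame.intrinsics)
    return PointCloud(pts.reshape(-1, 3), frame="camera")


def passthrough_filter(cloud: PointCloud, range_: FilterRange) -> tuple[PointCloud, PointCloud]:
    """Split a camera-frame cloud into (kept, removed) by Z in the open (z1, z2).

    The boundary is excluded on both sides.  kept + removed partitions the
    input exactly.
    """
    if cloud.frame != "camera":
        raise ValueError("pass-through filtering operates on camera-frame Z")
    z = cloud.points[:, 2] if len(cloud) else np.empty(0)
    keep = (z > range_.z1) & (z < range_.z2)
    return (
        PointCloud(cloud.points[keep], frame="camera"),
        PointCloud(cloud.points[~keep], frame="camera"),
    )


def to_world(obj, extrinsics: Extrinsics):
    """Apply p_world = R p + T to a PointCloud or a single (3,) point."""
    if isinstance(obj, PointCloud):
        if obj.frame != "camera":
            raise ValueError("to_world expects a camera-frame cloud")
        return PointCloud(obj.points @ extrinsics.R.T + extrinsics.T, frame="world")
    p = np.asarray(obj, dtype=np.float64).reshape(3)
    return extrinsics.R @ p + extrinsics.T


def estimate_ground(cloud: PointCloud, hoof_hints, radius: float = 0.15,
                    min_support: int = 50) -> GroundPlane:
    """Estimate the floor elevation from points near the hooves.

    Candidates are all world-frame points within ``radius`` (3-D Euclidean) of
    any hoof hint.  The upper half of the candidates (by height) is discarded
    to reject points on the limbs, and z0 is the median height of the rest.
    The normal is the world up axis; this assumes a level floor, which is how
    heights are defined (world-Z differences).
    """
    if cloud.frame != "world":
        raise ValueError("ground estimation expects a world-frame cloud")
    hints = np.asarray(hoof_hints, dtype=np.float64).reshape(-1, 3)
    if len(cloud) == 0 or hints.shape[0] == 0:
        raise GroundEstimationError("need a non-empty cloud and at least one hoof hint")
    near = np.zeros(len(cloud), dtype=bool)
    for h in hints:
        near |= np.einsum("ij,ij->i", cloud.points - h, cloud.points - h) <= radius**2
    candidates = cloud.points[near]
    if candidates.shape[0] < min_support:
        raise GroundEstimationError(
            f"only {candidates.shape[0]} points within {radius} m of the hoof hints "
            f"(minimum {min_support}); try a larger radius"
        )
    heights = np.sort(candidates[:, 2])
    lower = heights[: max(1, heights.size // 2)]  # reject limb points
    return GroundPlane(z0=float(np.median(lower)), normal=WORLD_UP,
                       support_count=int(candidates.shape[0]))


# ---------------------------------------------------------------------------
# Point-cloud file formats


def save_ply(cloud: PointCloud, path, binary: bool = True) -> None:
    """Write a point cloud as PLY (binary little-endian by default)."""
    n = len(cloud)
    header = (
        "ply\n"
        f"format {'binary_little_endian' if binary else 'ascii'} 1.0\n"
        f"comment frame {cloud.frame}\n"
        f"element vertex {n}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(cloud.points.astype("<f4").tobytes())
        else:
            for x, y, z in cloud.points:
                fh.write(f"{x} {y} {z}\n".encode("ascii"))


def load_ply(path) -> PointCloud:
    with open(path, "rb") as fh:
        data = fh.read()
    head, _, body = data.partition(b"end_header\n")
    lines = head.decode("ascii").splitlines()
    fmt = next(line.split()[1] for line in lines if line.startswith("format"))
    n = int(next(line.split()[2] for line in lines if line.startswith("element vertex")))
    frame = "camera"
    for line in lines:
        if line.startswith("comment frame"):
            frame = line.split()[2]
    if fmt == "binary_little_endian":
        pts = np.frombuffer(body[: 12 * n], dtype="<f4").reshape(n, 3)
    else:
        pts = np.loadtxt(body.decode("ascii").splitlines(), dtype=np.float64).reshape(n, 3)
    return PointCloud(pts.astype(np.float64), frame=frame)


def save_pcd(cloud: PointCloud, path) -> None:
    """Write a point cloud in the ASCII PCD format."""
    n = len(cloud)
    with open(path, "w") as fh:
        fh.write(
            "# .PCD v0.7 - Point Cloud Data file format\n"
            f"# frame {cloud.frame}\n"
            "VERSION 0.7\nFIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
            f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
        )
        for x, y, z in cloud.points:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


def load_pcd(path) -> PointCloud:
    frame = "camera"
    pts: list[list[float]] = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("# frame"):
                frame = line.split()[2]
            elif line.startswith("DATA"):
                if line.split()[1] != "ascii":
                    raise ValueError("only ASCII PCD files are supported")
                in_data = True
            elif in_data and line.strip():
                pts.append([float(t) for t in line.split()])
    return PointCloud(np.array(pts, dtype=np.float64).reshape(-1, 3), frame=frame)
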