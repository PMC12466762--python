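"""Body-trait computation from six 3-D landmarks and the ground plane.

The four traits are defined on the lateral view of a standing animal:

* withers height — world-Z difference between the withers landmark and the
  ground reference plane, in cm;
* hip height — the same vertical convention applied to the hip landmark;
* body length — 3-D Euclidean distance between the point of shoulder and the
  posterior edge of the pin bone, in cm;
* cannon circumference — pi times the 3-D Euclidean distance between the
  bilateral surface points at the narrowest forelimb section, treating that
  distance as the diameter of a circular cross-section.

``measure_animal`` runs the full chain on one frame: depth completion, depth
lookup per landmark, back-projection, camera-to-world transform, ground-plane
estimation, and the four trait computations, recording a quality flag for
every fallback taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .completion import complete_depth
from .frames import Extrinsics, KeypointSet, RGBDFrame
from .geometry import (
    FilterRange,
    GroundEstimationError,
    GroundPlane,
    PointCloud,
    backproject,
    estimate_ground,
    frame_to_cloud,
    passthrough_filter,
    to_world,
)

__all__ = [
    "BodyMeasurements",
    "GroundConfig",
    "OrientationError",
    "NoMeasurementError",
    "withers_height",
    "hip_height",
    "body_length",
    "cannon_circumference",
    "lookup_depth",
    "measure_animal",
    "relative_error",
]


class OrientationError(ValueError):
    """A height came out non-positive: the up-axis convention is misconfigured."""


class NoMeasurementError(RuntimeError):
    """No landmark is visible; nothing can be measured."""


@dataclass
class BodyMeasurements:
    """The four trait values in centimeters; ``None`` marks an unmeasurable trait.

    ``flags`` maps a trait name to the quality flags accumulated while
    computing it (e.g. ``depth-interpolated:withers_top`` or
    ``missing-landmark:cannon_medial``).  A trait with a missing landmark is
    absent (None), never 0.
    """

    withers_height_cm: float | None = None
    hip_height_cm: float | None = None
    body_length_cm: float | None = None
    cannon_circumference_cm: float | None = None
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("withers_height_cm", "hip_height_cm", "body_length_cm",
                     "cannon_circumference_cm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present, got {v}")


@dataclass
class GroundConfig:
    """How the ground reference plane is found.

    ``hints`` may give explicit hoof-adjacent world points; when None they are
    derived from the landmarks by dropping each available horizontal position
    onto the lowest nearby cloud points.  ``stride`` subsamples the depth map
    when building the cloud used for ground estimation.
    """

    radius: float = 0.15
    min_support: int = 50
    stride: int = 1
    hints: list | None = None


def withers_height(withers_point, ground: GroundPlane) -> float:
    """Vertical (world-Z) distance from the withers landmark to the floor, cm."""
    h = (np.asarray(withers_point, dtype=np.float64)[2] - ground.z0) * 100.0
    if h <= 0:
        raise OrientationError(
            f"withers height {h:.2f} cm is not positive; check the up-axis convention"
        )
    return float(h)


def hip_height(hip_point, ground: GroundPlane) -> float:
    """Vertical (world-Z) distance from the hip landmark to the floor, cm."""
    h = (np.asarray(hip_point, dtype=np.float64)[2] - ground.z0) * 100.0
    if h <= 0:
        raise OrientationError(
            f"hip height {h:.2f} cm is not positive; check the up-axis convention"
        )
    return float(h)


def body_length(p1, p2) -> float:
    """3-D Euclidean distance between shoulder point and pin bone, cm."""
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    return float(np.linalg.norm(p1 - p2) * 100.0)


def cannon_circumference(p_medial, p_lateral) -> float:
    """pi x the bilateral-point distance (taken as diameter), cm."""
    d = np.linalg.norm(np.asarray(p_medial, dtype=np.float64)
                       - np.asarray(p_lateral, dtype=np.float64))
    if d == 0:
        raise ValueError("cannon landmarks coincide; circumference is degenerate")
    return float(math.pi * d * 100.0)


def relative_error(gt: float, pred: float) -> float:
    """|pred - gt| / gt x 100, in percent, reported to two decimals."""
    if gt <= 0:
        raise ValueError(f"ground truth must be positive, got {gt}")
    return round(abs(pred - gt) / gt * 100.0, 2)


# ---------------------------------------------------------------------------
# Depth lookup and the end-to-end pipeline


def lookup_depth(depth_values: np.ndarray, u: float, v: float,
                 mode: str = "median") -> tuple[float | None, list[str]]:
    """Depth in meters at a subpixel landmark, with quality flags.

    The landmark is rounded to the nearest pixel for indexing.  In ``median``
    mode the value is the median of the valid depths in the 5x5 window around
    that pixel (robust to per-pixel sensor noise); in ``nearest`` mode the
    center pixel is used directly with the window median as fallback.  In
    both modes an invalid center pixel earns a ``depth-interpolated`` flag,
    and an all-invalid window yields (None, ['missing-depth']).
    """
    H, W = depth_values.shape
    ui = int(np.clip(round(u), 0, W - 1))
    vi = int(np.clip(round(v), 0, H - 1))
    center = depth_values[vi, ui]
    window = depth_values[max(0, vi - 2): vi + 3, max(0, ui - 2): ui + 3]
    valid = window[window > 0]
    flags: list[str] = []
    if center <= 0:
        if valid.size == 0:
            return None, ["missing-depth"]
        flags.append("depth-interpolated")
        return float(np.median(valid)), flags
    if mode == "nearest":
        return float(center), flags
    if mode == "median":
        return float(np.median(valid)), flags
    raise ValueError(f"unknown depth lookup mode {mode!r}")


_TRAIT_LANDMARKS = {
    "withers_height_cm": ("withers_top",),
    "hip_height_cm": ("hip_top",),
    "body_length_cm": ("shoulder_point", "pin_bone"),
    "cannon_circumference_cm": ("cannon_medial", "cannon_lateral"),
}


def _derive_hoof_hints(cloud: PointCloud, landmark_world: dict, radius: float) -> list:
    """Drop landmark horizontal positions onto the lowest nearby cloud points.

    The cannon pair sits on the forelimb just above the hoof, so its midpoint
    is the preferred anchor; other landmarks are fallbacks when the cannon is
    not visible.  The hint height is the 1st percentile of heights within a
    horizontal ``radius`` of the anchor, i.e. approximately the floor.
    """
    anchors = []
    cm, cl = landmark_world.get("cannon_medial"), landmark_world.get("cannon_lateral")
    if cm is not None and cl is not None:
        anchors.append((np.asarray(cm) + np.asarray(cl)) / 2.0)
    elif cm is not None or cl is not None:
        anchors.append(np.asarray(cm if cm is not None else cl))
    else:
        anchors.extend(np.asarray(p) for p in landmark_world.values() if p is not None)
    hints = []
    xy = cloud.points[:, :2]
    for a in anchors:
        d2 = np.einsum("ij,ij->i", xy - a[:2], xy - a[:2])
        near_z = cloud.points[d2 <= radius**2, 2]
        if near_z.size:
            hints.append(np.array([a[0], a[1], np.percentile(near_z, 1)]))
    return hints


def measure_animal(frame: RGBDFrame, keypoints: KeypointSet, extrinsics: Extrinsics,
                   ground_config: GroundConfig | None = None, *,
                   complete: bool = True, max_passes: int = 5,
                   filter_range: FilterRange | None = None,
                   depth_lookup: str = "median") -> BodyMeasurements:
    """Measure the four body traits for one animal.

    Pipeline: depth completion -> per-landmark depth lookup -> pinhole
    back-projection -> camera-to-world transform -> ground-plane estimation
    -> trait computation.  A missing or depth-less landmark degrades only the
    traits that use it; every fallback is recorded in ``flags``.
    """
    if keypoints.visible_count() == 0:
        raise NoMeasurementError("all six landmarks are invisible")
    ground_config = ground_config or GroundConfig()
    filter_range = filter_range or FilterRange(0.1, 5.0)

    depth = complete_depth(frame.depth, max_passes=max_passes) if complete else frame.depth
    flags: dict[str, list[str]] = {}

    # Per-landmark world coordinates (None where unavailable).
    kp_flags: dict[str, list[str]] = {}
    landmark_world: dict[str, np.ndarray | None] = {}
    for kp in keypoints.keypoints:
        if not kp.visible:
            landmark_world[kp.name] = None
            kp_flags[kp.name] = ["missing-landmark"]
            continue
        Z, lflags = lookup_depth(depth.values, kp.u, kp.v, mode=depth_lookup)
        kp_flags[kp.name] = lflags
        if Z is None:
            landmark_world[kp.name] = None
            continue
        landmark_world[kp.name] = to_world(backproject(kp.u, kp.v, Z, frame.intrinsics),
                                           extrinsics)

    # Scene cloud for the ground reference: complete -> filter -> world.
    cloud_cam = frame_to_cloud(RGBDFrame(frame.color, depth, frame.intrinsics),
                               stride=ground_config.stride)
    kept, _removed = passthrough_filter(cloud_cam, filter_range)
    cloud_world = to_world(kept, extrinsics)

    ground: GroundPlane | None = None
    ground_error: str | None = None
    hints = ground_config.hints
    if hints is None:
        hints = _derive_hoof_hints(cloud_world, landmark_world, ground_config.radius)
    try:
        if not hints:
            raise GroundEstimationError("no hoof hints could be derived from the landmarks")
        ground = estimate_ground(cloud_world, hints, radius=ground_config.radius,
                                 min_support=ground_config.min_support)
    except GroundEstimationError as exc:
        ground_error = str(exc)

    def trait_flags(trait: str) -> list[str]:
        out = []
        for lm in _TRAIT_LANDMARKS[trait]:
            out.extend(f"{f}:{lm}" for f in kp_flags.get(lm, []))
        return out

    values: dict[str, float | None] = {}
    for trait, landmarks in _TRAIT_LANDMARKS.items():
        flags[trait] = trait_flags(trait)
        pts = [landmark_world[lm] for lm in landmarks]
        if any(p is None for p in pts):
            values[trait] = None
            continue
        if trait in ("withers_height_cm", "hip_height_cm"):
            if ground is None:
                values[trait] = None
                flags[trait].append(f"no-ground-plane:{ground_error}")
                continue
            fn = withers_height if trait == "withers_height_cm" else hip_height
            values[trait] = fn(pts[0], ground)
        elif trait == "body_length_cm":
            values[trait] = body_length(*pts)
        else:
            values[trait] = cannon_circumference(*pts)

    return BodyMeasurements(flags=flags, **values)
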