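"""Aligned RGB-D frames, camera parameters, and keypoint annotations.

This module defines the canonical in-memory containers for the measurement
pipeline and the readers/writers for the standard on-disk formats: 8-bit PNG
color images, 16-bit PNG depth maps (millimeters by default), Labelme point
annotations, COCO-style keypoint triplets, and CSV measurement reports.

Coordinate conventions: pixel coordinates are (u, v) = (column, row) with the
origin at the top-left corner, 0-based.  Subpixel keypoint coordinates are
preserved; rounding to integer pixels happens only when indexing a depth map.
Depth values are stored in meters with 0 marking "no measurement".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image

__all__ = [
    "LANDMARK_NAMES",
    "CameraIntrinsics",
    "DepthMap",
    "RGBDFrame",
    "Keypoint",
    "KeypointSet",
    "Extrinsics",
    "AlignmentError",
    "SchemaError",
    "read_frame",
    "write_depth_png",
    "read_depth_png",
    "read_keypoints",
    "write_keypoints",
    "write_report",
]

#: Canonical order of the six lateral-view anatomical landmarks.
LANDMARK_NAMES = (
    "withers_top",
    "hip_top",
    "shoulder_point",
    "pin_bone",
    "cannon_medial",
    "cannon_lateral",
)

#: Default aliases accepted when reading annotation files; extendable via the
#: ``aliases`` argument of :func:`read_keypoints` or the YAML config.
DEFAULT_ALIASES = {
    "withers": "withers_top",
    "hip": "hip_top",
    "shoulder": "shoulder_point",
    "ischium": "pin_bone",
    "pin": "pin_bone",
    "cannon_inner": "cannon_medial",
    "cannon_outer": "cannon_lateral",
}


class AlignmentError(ValueError):
    """Color and depth images are not pixel-aligned."""


class SchemaError(ValueError):
    """An annotation file does not follow the declared landmark schema."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixels: focal lengths and principal point."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")

    def validate_for_image(self, width: int, height: int) -> None:
        if not (0 <= self.cx < width and 0 <= self.cy < height):
            raise ValueError(
                f"principal point ({self.cx}, {self.cy}) outside {width}x{height} image"
            )


@dataclass
class DepthMap:
    """H x W grid of range values in meters; 0 marks a missing measurement.

    NaNs are coerced to the missing marker on construction so that downstream
    arithmetic never propagates them.
    """

    values: np.ndarray
    missing_marker: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError(f"depth map must be a non-empty 2-D grid, got shape {v.shape}")
        v = np.where(np.isnan(v), self.missing_marker, v)
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("depth values must be finite and >= 0")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def valid_mask(self) -> np.ndarray:
        return self.values > self.missing_marker

    def missing_count(self) -> int:
        return int(np.count_nonzero(~self.valid_mask()))


@dataclass
class RGBDFrame:
    """Pixel-aligned color image + depth map + intrinsics."""

    color: np.ndarray
    depth: DepthMap
    intrinsics: CameraIntrinsics

    def __post_init__(self) -> None:
        c = np.asarray(self.color)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError(f"color image must be H x W x 3, got shape {c.shape}")
        if c.shape[:2] != self.depth.shape:
            raise AlignmentError(
                f"color {c.shape[:2]} and depth {self.depth.shape} are not pixel-aligned"
            )
        self.color = c
        self.intrinsics.validate_for_image(c.shape[1], c.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass(frozen=True)
class Keypoint:
    """A named landmark at subpixel (u, v) with COCO visibility semantics.

    visibility: 0 = absent/unlabeled, 1 = labeled but occluded, 2 = visible.
    The OKS indicator treats 1 and 2 identically.
    """

    name: str
    u: float
    v: float
    visibility: int = 2
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.visibility not in (0, 1, 2):
            raise ValueError(f"visibility must be 0, 1 or 2, got {self.visibility}")

    @property
    def visible(self) -> bool:
        return self.visibility > 0


@dataclass
class KeypointSet:
    """Exactly six landmarks in canonical order plus a bounding-box area (px^2)."""

    keypoints: list[Keypoint]
    bbox_area: float = 0.0

    def __post_init__(self) -> None:
        if len(self.keypoints) != len(LANDMARK_NAMES):
            raise ValueError(f"expected {len(LANDMARK_NAMES)} keypoints, got {len(self.keypoints)}")
        names = tuple(k.name for k in self.keypoints)
        if names != LANDMARK_NAMES:
            raise ValueError(f"keypoints must be in canonical order {LANDMARK_NAMES}, got {names}")
        if any(k.visible for k in self.keypoints) and self.bbox_area <= 0:
            raise ValueError("bbox_area must be > 0 when any keypoint is visible")

    def __getitem__(self, name: str) -> Keypoint:
        return self.keypoints[LANDMARK_NAMES.index(name)]

    def visible_count(self) -> int:
        return sum(k.visible for k in self.keypoints)

    def as_array(self) -> np.ndarray:
        """(6, 2) array of (u, v) pixel coordinates."""
        return np.array([[k.u, k.v] for k in self.keypoints], dtype=np.float64)

    def translated(self, du: float, dv: float) -> "KeypointSet":
        kps = [replace(k, u=k.u + du, v=k.v + dv) for k in self.keypoints]
        return KeypointSet(kps, bbox_area=self.bbox_area)


@dataclass(frozen=True)
class Extrinsics:
    """Rigid camera-to-world transform: p_world = R @ p_cam + T."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=np.float64)
        T = np.asarray(self.T, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"R must be 3x3, got {R.shape}")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-9
        ):
            raise ValueError("R must be orthonormal with determinant +1")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "T", T)

    @classmethod
    def identity(cls) -> "Extrinsics":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "Extrinsics":
        return Extrinsics(self.R.T, -self.R.T @ self.T)


# ---------------------------------------------------------------------------
# Frame I/O


def read_depth_png(path, depth_scale: float = 0.001) -> DepthMap:
    """Read a single-channel PNG depth map, converting stored units to meters."""
    try:
        img = Image.open(path)
        arr = np.asarray(img)
    except OSError as exc:
        raise OSError(f"cannot read depth image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(f"depth image {path} must be single-channel, got shape {arr.shape}")
    return DepthMap(arr.astype(np.float64) * depth_scale)


def write_depth_png(depth: DepthMap, path, depth_scale: float = 0.001) -> None:
    """Write a depth map as 16-bit PNG in stored units (millimeters by default)."""
    stored = np.round(depth.values / depth_scale)
    if np.any(stored > np.iinfo(np.uint16).max):
        raise ValueError("depth values exceed the 16-bit stored range at this depth_scale")
    Image.fromarray(stored.astype(np.uint16)).save(path)


def read_frame(color_path, depth_path, intrinsics: CameraIntrinsics,
               depth_scale: float = 0.001) -> RGBDFrame:
    """Read an aligned RGB-D pair; depth is stored in meters after scaling.

    Raises :class:`AlignmentError` when the two images disagree in size and
    ``OSError`` when either file cannot be decoded.
    """
    try:
        color = np.asarray(Image.open(color_path).convert("RGB"))
    except OSError as exc:
        raise OSError(f"cannot read color image {color_path}: {exc}") from exc
    depth = read_depth_png(depth_path, depth_scale=depth_scale)
    if color.shape[:2] != depth.shape:
        raise AlignmentError(
            f"color {color.shape[:2]} and depth {depth.shape} are not pixel-aligned"
        )
    return RGBDFrame(color=color, depth=depth, intrinsics=intrinsics)


# ---------------------------------------------------------------------------
# Keypoint annotation I/O


def _canonicalize(named: dict[str, Keypoint], bbox_area: float | None,
                  aliases: dict[str, str] | None) -> KeypointSet:
    """Map arbitrarily named/ordered landmarks onto the canonical schema."""
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update(aliases)
    resolved: dict[str, Keypoint] = {}
    for name, kp in named.items():
        canon = table.get(name, name)
        if canon not in LANDMARK_NAMES:
            raise SchemaError(
                f"unknown landmark name {name!r}; accepted names: {list(LANDMARK_NAMES)}"
                f" (or aliases {sorted(table)})"
            )
        resolved[canon] = replace(kp, name=canon)
    kps = []
    for canon in LANDMARK_NAMES:
        if canon in resolved:
            kps.append(resolved[canon])
        else:
            kps.append(Keypoint(canon, 0.0, 0.0, visibility=0, confidence=0.0))
    if bbox_area is None:
        vis = [k for k in kps if k.visible]
        if vis:
            us = [k.u for k in vis]
            vs = [k.v for k in vis]
            bbox_area = max(max(us) - min(us), 1.0) * max(max(vs) - min(vs), 1.0)
        else:
            bbox_area = 0.0
    return KeypointSet(kps, bbox_area=float(bbox_area))


def _parse_labelme(doc: dict, aliases) -> list[KeypointSet]:
    named: dict[str, Keypoint] = {}
    for shape in doc.get("shapes", []):
        if shape.get("shape_type", "point") != "point":
            continue
        (u, v), = shape["points"]
        named[shape["label"]] = Keypoint(shape["label"], float(u), float(v), visibility=2,
                                         confidence=float(shape.get("confidence", 1.0)))
    return [_canonicalize(named, None, aliases)]


def _parse_coco(doc: dict, aliases) -> list[KeypointSet]:
    sets = []
    for ann in doc.get("annotations", []):
        flat = ann["keypoints"]
        if len(flat) != 3 * len(LANDMARK_NAMES):
            raise SchemaError(
                f"COCO keypoints must have {3 * len(LANDMARK_NAMES)} values, got {len(flat)}"
            )
        named = {}
        confs = ann.get("keypoint_confidences", [1.0] * len(LANDMARK_NAMES))
        for i, name in enumerate(LANDMARK_NAMES):
            x, y, vis = flat[3 * i: 3 * i + 3]
            vis = int(vis)
            named[name] = Keypoint(name, float(x), float(y), visibility=vis,
                                   confidence=float(confs[i]) if vis else 0.0)
        bbox = ann.get("bbox")
        area = ann.get("area", bbox[2] * bbox[3] if bbox else None)
        sets.append(_canonicalize(named, area, aliases))
    return sets


def read_keypoints(path, dialect: str, aliases: dict[str, str] | None = None) -> list[KeypointSet]:
    """Read keypoint annotations in the ``labelme`` or ``coco`` dialect.

    Landmarks are mapped to canonical order by name; absent landmarks get
    visibility 0 and confidence 0.  A file with no visible landmarks yields a
    set that downstream code treats as empty (it is not an error here).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if dialect == "labelme":
        return _parse_labelme(doc, aliases)
    if dialect == "coco":
        return _parse_coco(doc, aliases)
    raise ValueError(f"unknown annotation dialect {dialect!r}; expected 'labelme' or 'coco'")


def write_keypoints(sets: list[KeypointSet], path, dialect: str,
                    image_size: tuple[int, int] | None = None) -> None:
    """Write keypoint sets in the requested dialect (exact round-trip)."""
    if dialect == "labelme":
        if len(sets) != 1:
            raise ValueError("labelme files hold a single annotated instance")
        shapes = [
            {"label": k.name, "points": [[k.u, k.v]], "shape_type": "point",
             "confidence": k.confidence}
            for k in sets[0].keypoints if k.visible
        ]
        doc = {"version": "5.5.0", "shapes": shapes}
        if image_size is not None:
            doc["imageWidth"], doc["imageHeight"] = image_size
    elif dialect == "coco":
        anns = []
        for i, ks in enumerate(sets):
            flat: list[float] = []
            confs: list[float] = []
            for k in ks.keypoints:
                flat.extend([k.u, k.v, k.visibility])
                confs.append(k.confidence)
            anns.append({"id": i, "keypoints": flat, "area": ks.bbox_area,
                         "keypoint_confidences": confs,
                         "num_keypoints": ks.visible_count()})
        doc = {
            "annotations": anns,
            "categories": [{"id": 1, "name": "cattle", "keypoints": list(LANDMARK_NAMES)}],
        }
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Measurement reports

TRAIT_COLUMNS = (
    "withers_height_cm",
    "hip_height_cm",
    "body_length_cm",
    "cannon_circumference_cm",
)


def write_report(measurements: list, path, ground_truth: list | None = None) -> None:
    """Write one CSV row per animal: id, four traits, and relative errors.

    ``measurements`` is a list of ``(animal_id, BodyMeasurements)`` pairs (or
    objects exposing ``animal_id``).  Traits that are absent (missing
    landmark) are written as empty cells, never as 0.  When ``ground_truth``
    (a parallel list of BodyMeasurements) is supplied, per-trait relative
    errors in percent are appended.
    """
    import pandas as pd

    from .measure import relative_error

    if not measurements:
        raise ValueError("cannot write a report for an empty measurement list")
    rows = []
    for idx, item in enumerate(measurements):
        animal_id, bm = item
        row: dict[str, object] = {"animal_id": animal_id}
        for col in TRAIT_COLUMNS:
            val = getattr(bm, col)
            row[col] = "" if val is None else f"{val:.2f}"
        if ground_truth is not None:
            gt = ground_truth[idx]
            for col in TRAIT_COLUMNS:
                val, gval = getattr(bm, col), getattr(gt, col)
                key = col.replace("_cm", "_re_pct")
                row[key] = "" if (val is None or gval is None) else f"{relative_error(gval, val):.2f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
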