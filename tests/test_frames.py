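"""RGB-D frame and annotation I/O: formats, canonical schema, round-trips."""

import json

import numpy as np
import pytest
from PIL import Image

from bovimetry.frames import (
    LANDMARK_NAMES,
    AlignmentError,
    CameraIntrinsics,
    DepthMap,
    Extrinsics,
    Keypoint,
    KeypointSet,
    SchemaError,
    read_frame,
    read_keypoints,
    write_depth_png,
    write_keypoints,
    write_report,
)
from bovimetry.measure import BodyMeasurements

from .conftest import make_keypoint_set


def _write_pair(tmp_path, w=64, h=48, depth_mm=1500):
    color = np.full((h, w, 3), 90, dtype=np.uint8)
    Image.fromarray(color).save(tmp_path / "c.png")
    depth = np.full((h, w), depth_mm, dtype=np.uint16)
    Image.fromarray(depth).save(tmp_path / "d.png")
    return tmp_path / "c.png", tmp_path / "d.png"


class TestFrameIO:
    def test_depth_scale_converts_stored_millimeters_to_meters(self, tmp_path):
        cpath, dpath = _write_pair(tmp_path, depth_mm=1500)
        frame = read_frame(cpath, dpath, CameraIntrinsics(525, 525, 31.5, 23.5),
                           depth_scale=0.001)
        assert frame.depth.values[0, 0] == pytest.approx(1.5)
        assert frame.shape == (48, 64)

    def test_mismatched_color_and_depth_sizes_raise_alignment_error(self, tmp_path):
        cpath, _ = _write_pair(tmp_path)
        Image.fromarray(np.zeros((30, 64), dtype=np.uint16)).save(tmp_path / "d2.png")
        with pytest.raises(AlignmentError):
            read_frame(cpath, tmp_path / "d2.png", CameraIntrinsics(525, 525, 31.5, 23.5))

    def test_depth_png_round_trip_preserves_millimeter_values(self, tmp_path):
        d = DepthMap(np.array([[0.0, 1.234], [4.999, 0.001]]))
        write_depth_png(d, tmp_path / "d.png")
        back = np.asarray(Image.open(tmp_path / "d.png"))
        assert back.tolist() == [[0, 1234], [4999, 1]]

    def test_nan_depth_is_coerced_to_missing(self):
        d = DepthMap(np.array([[np.nan, 2.0]]))
        assert d.values[0, 0] == 0.0 and d.missing_count() == 1


class TestIntrinsicsExtrinsics:
    def test_nonpositive_focal_length_rejected(self):
        with pytest.raises(ValueError):
            CameraIntrinsics(fx=-1, fy=525, cx=10, cy=10)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValueError):
            Extrinsics(np.eye(3) * 2.0, np.zeros(3))

    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            Extrinsics(R, np.zeros(3))


class TestKeypointSchema:
    def test_labelme_round_trip_is_exact(self, tmp_path, square_keypoints):
        write_keypoints([square_keypoints], tmp_path / "a.json", dialect="labelme")
        back = read_keypoints(tmp_path / "a.json", dialect="labelme")[0]
        assert back.as_array().tolist() == square_keypoints.as_array().tolist()
        assert [k.visibility for k in back.keypoints] == \
            [k.visibility for k in square_keypoints.keypoints]

    def test_coco_round_trip_is_exact(self, tmp_path, square_keypoints):
        vis = [2, 2, 1, 2, 0, 2]
        ks = make_keypoint_set(square_keypoints.as_array(), visibility=vis)
        write_keypoints([ks], tmp_path / "a.json", dialect="coco")
        back = read_keypoints(tmp_path / "a.json", dialect="coco")[0]
        assert [k.visibility for k in back.keypoints] == vis
        assert back.as_array().tolist() == ks.as_array().tolist()
        assert back.bbox_area == ks.bbox_area

    def test_shuffled_labelme_records_yield_identical_canonical_order(self, tmp_path):
        shapes = [{"label": name, "points": [[float(i), float(2 * i)]],
                   "shape_type": "point"} for i, name in enumerate(LANDMARK_NAMES)]
        for order in (shapes, shapes[::-1]):
            with open(tmp_path / "a.json", "w") as fh:
                json.dump({"shapes": order}, fh)
            ks = read_keypoints(tmp_path / "a.json", dialect="labelme")[0]
            assert [k.name for k in ks.keypoints] == list(LANDMARK_NAMES)
            assert ks["hip_top"].u == 1.0

    def test_absent_landmarks_get_visibility_zero(self, tmp_path):
        shapes = [{"label": n, "points": [[5.0, 5.0]], "shape_type": "point"}
                  for n in LANDMARK_NAMES[:4]]
        with open(tmp_path / "a.json", "w") as fh:
            json.dump({"shapes": shapes}, fh)
        ks = read_keypoints(tmp_path / "a.json", dialect="labelme")[0]
        assert ks.visible_count() == 4
        assert ks["cannon_medial"].visibility == 0
        assert ks["cannon_medial"].confidence == 0.0

    def test_unknown_landmark_name_raises_schema_error_listing_names(self, tmp_path):
        with open(tmp_path / "a.json", "w") as fh:
            json.dump({"shapes": [{"label": "nose", "points": [[1, 1]],
                                   "shape_type": "point"}]}, fh)
        with pytest.raises(SchemaError, match="withers_top"):
            read_keypoints(tmp_path / "a.json", dialect="labelme")

    def test_alias_mapping_resolves_to_canonical_name(self, tmp_path):
        with open(tmp_path / "a.json", "w") as fh:
            json.dump({"shapes": [{"label": "ischium", "points": [[7, 9]],
                                   "shape_type": "point"}]}, fh)
        ks = read_keypoints(tmp_path / "a.json", dialect="labelme")[0]
        assert ks["pin_bone"].visible and ks["pin_bone"].u == 7

    def test_keypoint_set_requires_exactly_six_in_order(self):
        with pytest.raises(ValueError):
            KeypointSet([Keypoint("withers_top", 0, 0)], bbox_area=1)


class TestReports:
    def test_report_row_shape_with_ground_truth(self, tmp_path):
        bm = BodyMeasurements(withers_height_cm=130.0, hip_height_cm=134.0,
                              body_length_cm=160.0, cannon_circumference_cm=22.0)
        gt = BodyMeasurements(withers_height_cm=131.0, hip_height_cm=134.0,
                              body_length_cm=161.0, cannon_circumference_cm=21.0)
        write_report([("a1", bm)], tmp_path / "r.csv", ground_truth=[gt])
        lines = (tmp_path / "r.csv").read_text().strip().splitlines()
        assert len(lines) == 2
        assert len(lines[1].split(",")) == 9  # id + 4 traits + 4 REs

    def test_missing_trait_is_empty_cell_not_zero(self, tmp_path):
        bm = BodyMeasurements(withers_height_cm=130.0, hip_height_cm=134.0,
                              body_length_cm=160.0, cannon_circumference_cm=None)
        write_report([("a1", bm)], tmp_path / "r.csv")
        row = (tmp_path / "r.csv").read_text().strip().splitlines()[1]
        assert row.endswith(",") and "0.00" not in row.split(",")[-1]

    def test_empty_measurement_list_is_an_error(self, tmp_path):
        with pytest.raises(ValueError):
            write_report([], tmp_path / "r.csv")
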