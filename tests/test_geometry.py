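"""Back-projection, rigid transforms, pass-through filtering, ground plane."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bovimetry.frames import CameraIntrinsics, DepthMap, Extrinsics, RGBDFrame
from bovimetry.geometry import (
    FilterRange,
    GroundEstimationError,
    MissingDepthError,
    PointCloud,
    backproject,
    estimate_ground,
    frame_to_cloud,
    load_pcd,
    load_ply,
    passthrough_filter,
    project,
    save_pcd,
    save_ply,
    to_world,
)


class TestBackprojection:
    def test_principal_point_maps_to_the_optical_axis(self, printed_intrinsics):
        p = backproject(319.5, 239.5, 2.0, printed_intrinsics)
        np.testing.assert_allclose(p, [0.0, 0.0, 2.0])

    def test_one_focal_length_off_axis_gives_unit_lateral_offset(self, printed_intrinsics):
        p = backproject(844.5, 239.5, 1.0, printed_intrinsics)
        np.testing.assert_allclose(p, [1.0, 0.0, 1.0])

    def test_zero_depth_raises_missing_depth_error(self, printed_intrinsics):
        with pytest.raises(MissingDepthError):
            backproject(100, 100, 0.0, printed_intrinsics)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(u=st.floats(0, 847), v=st.floats(0, 479), Z=st.floats(0.05, 10.0))
    def test_project_inverts_backproject_within_1e9_px(self, u, v, Z):
        intr = CameraIntrinsics(525.0, 525.0, 319.5, 239.5)
        u2, v2 = project(backproject(u, v, Z, intr), intr)
        assert abs(u2 - u) < 1e-9 and abs(v2 - v) < 1e-9


class TestFrameToCloud:
    def _frame(self, depth):
        color = np.zeros((*depth.shape, 3), dtype=np.uint8)
        return RGBDFrame(color, DepthMap(depth), CameraIntrinsics(100, 100, 1.5, 1.5))

    def test_constant_map_yields_one_point_per_pixel(self):
        cloud = frame_to_cloud(self._frame(np.ones((4, 4))), stride=1)
        assert len(cloud) == 16 and np.all(cloud.points[:, 2] == 1.0)

    def test_invalid_pixels_are_skipped(self):
        d = np.ones((4, 4))
        d[0, 0] = d[1, 2] = d[3, 3] = 0.0
        assert len(frame_to_cloud(self._frame(d))) == 13

    def test_stride_subsamples_the_grid(self):
        assert len(frame_to_cloud(self._frame(np.ones((4, 4))), stride=2)) == 4


class TestPassthrough:
    def test_open_interval_membership(self):
        z = [0.5, 2.0, 4.9, 5.1, 6.0]
        cloud = PointCloud(np.column_stack([np.zeros(5), np.zeros(5), z]))
        kept, removed = passthrough_filter(cloud, FilterRange(0.1, 5.0))
        assert len(kept) == 3 and len(removed) == 2

    def test_boundary_value_is_removed(self):
        cloud = PointCloud([[0, 0, 5.0]])
        kept, removed = passthrough_filter(cloud, FilterRange(0.1, 5.0))
        assert len(kept) == 0 and len(removed) == 1

    def test_empty_cloud_passes_through_empty(self):
        kept, removed = passthrough_filter(PointCloud(np.empty((0, 3))), FilterRange(0.1, 5.0))
        assert len(kept) == len(removed) == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 8.0), min_size=0, max_size=40))
    def test_kept_plus_removed_partitions_the_input(self, zs):
        cloud = PointCloud(np.column_stack([np.zeros(len(zs)), np.zeros(len(zs)), zs]))
        kept, removed = passthrough_filter(cloud, FilterRange(0.1, 5.0))
        assert len(kept) + len(removed) == len(cloud)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            FilterRange(5.0, 5.0)


class TestRigidTransform:
    def test_identity_transform_changes_only_the_frame_tag(self):
        cloud = PointCloud([[1, 2, 3]])
        out = to_world(cloud, Extrinsics.identity())
        assert out.frame == "world"
        np.testing.assert_array_equal(out.points, cloud.points)

    def test_pure_translation(self):
        out = to_world(np.array([0.0, 0.0, 2.0]), Extrinsics(np.eye(3), [0, 0, 1]))
        np.testing.assert_allclose(out, [0, 0, 3])

    def test_round_trip_through_inverse_recovers_coordinates(self):
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        ext = Extrinsics(R, [0.3, -1.2, 2.0])
        p = np.array([0.4, 1.1, -0.6])
        back = ext.inverse().R @ (to_world(p, ext)) + ext.inverse().T
        np.testing.assert_allclose(back, p, atol=1e-9)

    def test_rigid_transform_preserves_pairwise_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(20, 3))
        th = 1.1
        R = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]])
        out = to_world(PointCloud(pts), Extrinsics(R, [1, 2, 3]))
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d_out = np.linalg.norm(out.points[:, None] - out.points[None], axis=-1)
        np.testing.assert_allclose(d_out, d_in, atol=1e-9)


class TestGroundPlane:
    def _floor_cloud(self, z0=0.0, n=200, with_limb=False, rng=None):
        rng = rng or np.random.default_rng(7)
        xy = rng.uniform(-0.1, 0.1, size=(n, 2))
        pts = np.column_stack([xy, np.full(n, z0)])
        if with_limb:
            limb = np.column_stack([rng.uniform(-0.02, 0.02, size=(n // 2, 2)),
                                    np.full(n // 2, z0 + 0.25)])
            pts = np.vstack([pts, limb])
        return PointCloud(pts, frame="world")

    def test_flat_floor_recovered_exactly(self):
        cloud = self._floor_cloud(z0=0.0)
        gp = estimate_ground(cloud, [[0, 0, 0]], radius=0.15, min_support=50)
        assert gp.z0 == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(gp.normal, [0, 0, 1])

    def test_limb_points_rejected_by_lower_half_median(self):
        cloud = self._floor_cloud(z0=0.05, with_limb=True)
        gp = estimate_ground(cloud, [[0, 0, 0.05]], radius=0.3, min_support=50)
        assert abs(gp.z0 - 0.05) < 0.01

    def test_duplicating_floor_points_does_not_move_the_median(self):
        cloud = self._floor_cloud(z0=0.02)
        dup = PointCloud(np.vstack([cloud.points, cloud.points[:50]]), frame="world")
        gp1 = estimate_ground(cloud, [[0, 0, 0]], radius=0.2, min_support=10)
        gp2 = estimate_ground(dup, [[0, 0, 0]], radius=0.2, min_support=10)
        assert gp1.z0 == pytest.approx(gp2.z0, abs=1e-12)

    def test_insufficient_support_raises_with_advice(self):
        cloud = self._floor_cloud(n=60)
        with pytest.raises(GroundEstimationError, match="radius"):
            estimate_ground(cloud, [[5.0, 5.0, 0.0]], radius=0.1, min_support=50)


class TestCloudFiles:
    def test_ply_binary_round_trip(self, tmp_path):
        cloud = PointCloud(np.random.default_rng(0).normal(size=(17, 3)), frame="world")
        save_ply(cloud, tmp_path / "c.ply")
        back = load_ply(tmp_path / "c.ply")
        assert back.frame == "world"
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-6)

    def test_pcd_ascii_round_trip(self, tmp_path):
        cloud = PointCloud([[1.0, -2.5, 3.25], [0.0, 0.5, 4.0]])
        save_pcd(cloud, tmp_path / "c.pcd")
        back = load_pcd(tmp_path / "c.pcd")
        assert back.frame == "camera"
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-7)
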