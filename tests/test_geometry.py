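"""Pinhole/stereo geometry: examples, inverses, and a triangulation oracle."""

import numpy as np
import pytest

from bananavision.geometry import (
    BehindCameraError,
    CameraIntrinsics,
    DepthFrame,
    InvalidDepthError,
    InvalidDisparityError,
    InvalidTransformError,
    PixelCoord,
    Point3D,
    RigidTransform,
    StereoRig,
    align_depth_pixel,
    deproject,
    depth_from_disparity,
    project,
    transform_point,
)


def triangulate_two_view(rig: StereoRig, x_left: float, x_right: float, cx: float) -> float:
    """Brute-force two-view triangulation oracle for a rectified rig.

    Left camera at the origin, right camera translated by the baseline along
    X, both with focal f and principal column cx.  Intersect the two viewing
    rays in the X-Z plane by linear least squares and return the Z of the
    midpoint of closest approach.
    """
    # ray directions in each camera frame (y suppressed: rectified rows align)
    dl = np.array([(x_left - cx) / rig.f, 1.0])   # (X/Z, 1) direction, left
    dr = np.array([(x_right - cx) / rig.f, 1.0])  # right
    # solve o_l + t*dl = o_r + s*dr with o_l=(0,0), o_r=(B,0)
    A = np.column_stack([dl, -dr])
    b = np.array([rig.B, 0.0])
    t, s = np.linalg.lstsq(A, b, rcond=None)[0]
    p_left = t * dl
    p_right = np.array([rig.B, 0.0]) + s * dr
    return float((p_left[1] + p_right[1]) / 2)


class TestDepthFromDisparity:
    @pytest.mark.parametrize(
        "f,B,d,expected",
        [(1.0, 1.0, 1.0, 1.0), (380.0, 0.05, 19.0, 1.0)],
    )
    def test_examples(self, f, B, d, expected):
        assert depth_from_disparity(StereoRig(f=f, B=B), d) == pytest.approx(expected)

    def test_halving_disparity_doubles_depth(self):
        rig = StereoRig(f=400.0, B=0.06)
        for d in (0.5, 2.0, 17.3):
            assert depth_from_disparity(rig, d / 2) == pytest.approx(
                2 * depth_from_disparity(rig, d)
            )

    def test_invalid_disparity_raises(self):
        rig = StereoRig(f=380.0, B=0.05)
        with pytest.raises(InvalidDisparityError):
            depth_from_disparity(rig, 0.0)
        with pytest.raises(InvalidDisparityError):
            depth_from_disparity(rig, -1.0)

    def test_monotonicity(self):
        # strictly decreasing in d, increasing in B and f
        assert depth_from_disparity(StereoRig(380, 0.05), 10) > depth_from_disparity(
            StereoRig(380, 0.05), 11
        )
        assert depth_from_disparity(StereoRig(380, 0.06), 10) > depth_from_disparity(
            StereoRig(380, 0.05), 10
        )
        assert depth_from_disparity(StereoRig(400, 0.05), 10) > depth_from_disparity(
            StereoRig(380, 0.05), 10
        )

    def test_agrees_with_triangulation_oracle(self, rng):
        """Z = f*B/d equals a brute-force two-view ray intersection."""
        rig = StereoRig(f=380.0, B=0.095)
        cx = 320.0
        for _ in range(100):
            X = rng.uniform(-1, 1)
            Z = rng.uniform(0.3, 8.0)
            x_left = rig.f * X / Z + cx
            x_right = rig.f * (X - rig.B) / Z + cx
            d = x_left - x_right
            assert depth_from_disparity(rig, d) == pytest.approx(
                triangulate_two_view(rig, x_left, x_right, cx), abs=1e-9
            )


class TestDeprojectProject:
    def test_principal_point_maps_to_axis(self, vga_intrinsics):
        q = deproject(PixelCoord(320.0, 240.0), 2.0, vga_intrinsics)
        assert q == pytest.approx((0.0, 0.0, 2.0))

    def test_deproject_example(self, vga_intrinsics):
        q = deproject(PixelCoord(420.0, 240.0), 2.0, vga_intrinsics)
        assert q == pytest.approx((0.4, 0.0, 2.0))

    def test_project_examples(self, vga_intrinsics):
        assert project(Point3D(0, 0, 1), vga_intrinsics) == pytest.approx((320.0, 240.0))
        assert project(Point3D(0.4, 0, 2.0), vga_intrinsics) == pytest.approx((420.0, 240.0))

    def test_projection_scale_invariant(self, vga_intrinsics, rng):
        q = Point3D(0.3, -0.2, 1.7)
        p0 = project(q, vga_intrinsics)
        for s in (0.5, 2.0, 13.7):
            p = project(Point3D(q.X * s, q.Y * s, q.Z * s), vga_intrinsics)
            assert p == pytest.approx(p0)

    def test_errors(self, vga_intrinsics):
        with pytest.raises(InvalidDepthError):
            deproject(PixelCoord(10, 10), 0.0, vga_intrinsics)
        with pytest.raises(BehindCameraError):
            project(Point3D(0, 0, -1.0), vga_intrinsics)

    def test_round_trip_1000_points(self, vga_intrinsics, rng):
        """project(deproject(p, Z)) returns p to < 1e-6 px over random depths."""
        for _ in range(1000):
            p = PixelCoord(rng.uniform(0, 640), rng.uniform(0, 480))
            Z = rng.uniform(0.2, 10.0)
            p2 = project(deproject(p, Z, vga_intrinsics), vga_intrinsics)
            assert abs(p2.x - p.x) < 1e-6 and abs(p2.y - p.y) < 1e-6


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


class TestRigidTransform:
    def test_identity_and_translation(self):
        q = Point3D(0, 0, 1)
        assert transform_point(q, RigidTransform.identity()) == pytest.approx(q)
        E = RigidTransform(np.eye(3), np.array([0.05, 0, 0]))
        assert transform_point(q, E) == pytest.approx((0.05, 0, 1))

    def test_rotation_action(self):
        E = RigidTransform(_rot_z(90), np.zeros(3))
        assert transform_point(Point3D(1, 0, 0), E) == pytest.approx((0, 1, 0), abs=1e-12)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(InvalidTransformError):
            RigidTransform(np.eye(3) * 1.01, np.zeros(3))
        with pytest.raises(InvalidTransformError):
            RigidTransform(np.diag([1, 1, -1]), np.zeros(3))  # det -1

    def test_inverse_round_trip(self, rng):
        for _ in range(50):
            E = RigidTransform(_rot_z(rng.uniform(-180, 180)), rng.uniform(-1, 1, 3))
            q = Point3D(*rng.uniform(-2, 2, 3))
            back = transform_point(transform_point(q, E), E.inverse())
            assert np.allclose(back, q, atol=1e-9)


class TestAlignment:
    def test_self_alignment_is_identity(self, vga_intrinsics):
        p = PixelCoord(123.4, 56.7)
        out = align_depth_pixel(p, 1.5, vga_intrinsics, RigidTransform.identity(), vga_intrinsics)
        assert out == pytest.approx(p)

    def test_pure_translation_example(self, vga_intrinsics):
        E = RigidTransform(np.eye(3), np.array([0.05, 0, 0]))
        out = align_depth_pixel(PixelCoord(320, 240), 1.0, vga_intrinsics, E, vga_intrinsics)
        assert out == pytest.approx((345.0, 240.0))

    def test_equals_explicit_chain(self, vga_intrinsics, rng):
        K2 = CameraIntrinsics(fx=610, fy=605, cx=321.5, cy=238.2, width=640, height=480)
        E = RigidTransform(_rot_z(2.0), np.array([0.015, -0.001, 0.002]))
        for _ in range(50):
            p = PixelCoord(rng.uniform(0, 640), rng.uniform(0, 480))
            depth = rng.uniform(0.3, 5.0)
            composed = align_depth_pixel(p, depth, vga_intrinsics, E, K2)
            explicit = project(transform_point(deproject(p, depth, vga_intrinsics), E), K2)
            assert abs(composed.x - explicit.x) < 1e-9
            assert abs(composed.y - explicit.y) < 1e-9


class TestDepthFrame:
    def test_lookup_and_units(self):
        values = np.zeros((4, 6), dtype=np.uint16)
        values[2, 3] = 800
        f = DepthFrame(values=values, depth_scale=0.001)
        assert f.depth_at(PixelCoord(3.2, 1.8)) == pytest.approx(0.8)  # nearest neighbor
        assert f.depth_at(PixelCoord(0, 0)) == 0.0  # dropout reads zero

    def test_rejects_bad_frames(self):
        with pytest.raises(ValueError):
            DepthFrame(values=np.zeros((2, 2)), depth_scale=0.001)  # float grid
        with pytest.raises(ValueError):
            DepthFrame(values=np.zeros((2, 2), dtype=np.uint16), depth_scale=0.0)
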