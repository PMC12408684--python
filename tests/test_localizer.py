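"""Robust depth extraction: region scaling, sampling, clustering, gating."""

import numpy as np
import pytest

from bananavision.geometry import DepthFrame, Point3D
from bananavision.localizer import (
    BoundingBox,
    EmptyInputError,
    EmptyRegionError,
    LocalizationStatus,
    LocalizerConfig,
    NoValidDepthError,
    axis_errors,
    axis_errors_mm,
    drop_invalid,
    error_summary,
    kmeans_1d,
    localize,
    majority_cluster_median,
    sample_depths,
    sampling_region,
)


def kmeans2_threshold_oracle(values: np.ndarray) -> float:
    """Exhaustive 1-D optimum for k=2: the best partition is a threshold on
    the sorted values; enumerate all n-1 splits and return the minimal
    within-group sum of squares."""
    v = np.sort(np.asarray(values, dtype=float))
    best = np.inf
    for i in range(1, len(v)):
        lo, hi = v[:i], v[i:]
        wgss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        best = min(best, wgss)
    return best


def make_frame(depth_mm: np.ndarray) -> DepthFrame:
    return DepthFrame(values=depth_mm.astype(np.uint16), depth_scale=0.001)


class TestSamplingRegion:
    def test_half_scale_example(self):
        box = BoundingBox(cx=320, cy=240, w=200, h=100)
        r = sampling_region(box, 0.5, (640, 480))
        assert (r.cx, r.cy, r.w, r.h) == (320, 240, 100, 50)

    def test_unit_scale_equals_box(self):
        box = BoundingBox(cx=100, cy=80, w=40, h=20)
        r = sampling_region(box, 1.0, (640, 480))
        assert (r.x0, r.x1, r.y0, r.y1) == (80, 120, 70, 90)

    def test_clipping_recomputes_center(self):
        box = BoundingBox(cx=5, cy=240, w=100, h=40)
        r = sampling_region(box, 1.0, (640, 480))
        assert r.x0 == 0 and r.x1 == 55
        assert r.cx == pytest.approx(27.5)  # center of the clipped rectangle

    def test_fully_outside_raises(self):
        box = BoundingBox(cx=-200, cy=240, w=50, h=50)
        with pytest.raises(EmptyRegionError):
            sampling_region(box, 0.5, (640, 480))

    def test_minimum_one_pixel(self):
        box = BoundingBox(cx=10.5, cy=10.5, w=1, h=1)
        r = sampling_region(box, 0.5, (640, 480))
        assert r.w >= 1 and r.h >= 1


class TestSampleDepths:
    def test_constant_region(self):
        frame = make_frame(np.full((480, 640), 800))
        r = sampling_region(BoundingBox(320, 240, 100, 100), 0.5, (640, 480))
        s = sample_depths(frame, r, 100, seed=7)
        assert len(s) == 100
        assert np.all(s.values == pytest.approx(0.8))

    def test_determinism(self):
        frame = make_frame(np.arange(480 * 640).reshape(480, 640) % 1000)
        r = sampling_region(BoundingBox(320, 240, 100, 100), 0.5, (640, 480))
        a = sample_depths(frame, r, 100, seed=3)
        b = sample_depths(frame, r, 100, seed=3)
        assert np.array_equal(a.values, b.values) and np.array_equal(a.pixels, b.pixels)
        c = sample_depths(frame, r, 100, seed=4)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_support_containment_tiny_region(self):
        frame = make_frame(np.full((480, 640), 500))
        box = BoundingBox(cx=10, cy=10, w=4, h=4)
        r = sampling_region(box, 0.5, (640, 480))
        s = sample_depths(frame, r, 100, seed=0)
        assert len(s) == 100  # with replacement keeps n fixed
        assert {tuple(p) for p in s.pixels} <= {
            (x, y) for x in range(r.x0, r.x1) for y in range(r.y0, r.y1)
        }


class TestDropInvalid:
    def test_zero_removal(self):
        from bananavision.localizer import DepthSampleSet

        s = DepthSampleSet(values=np.array([0.0, 0.0, 0.5, 0.6]), pixels=np.zeros((4, 2)))
        out = drop_invalid(s)
        assert list(out.values) == [0.5, 0.6]

    @pytest.mark.parametrize("values,expected", [([0.0, 0.0], []), ([0.4, 0.7], [0.4, 0.7])])
    def test_all_or_none(self, values, expected):
        from bananavision.localizer import DepthSampleSet

        s = DepthSampleSet(values=np.array(values), pixels=np.zeros((len(values), 2)))
        assert list(drop_invalid(s).values) == expected


class TestKMeans1D:
    def test_two_well_separated_groups(self):
        p = kmeans_1d([1, 1, 1, 9, 9], k=2, seed=0)
        centers = sorted(p.centers)
        assert centers == pytest.approx([1.0, 9.0])
        assert sorted(p.counts) == [2, 3]

    def test_identical_values_degenerate(self):
        p = kmeans_1d([0.7] * 10, k=2, seed=0)
        assert p.k == 1 and p.counts[0] == 10

    def test_center_equals_member_mean(self, rng):
        v = rng.uniform(0.3, 3.0, size=50)
        p = kmeans_1d(v, k=2, seed=1)
        for i in range(p.k):
            assert p.centers[i] == pytest.approx(p.members(i).mean(), abs=1e-9)
        assert p.counts.sum() == 50

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            kmeans_1d([], k=2)

    def test_bimodal_recovery_matches_oracle(self, rng):
        """70 near 0.7 m + 30 near 2.5 m: recovered groups are the modes and
        the converged WGSS equals the exhaustive-threshold optimum."""
        v = np.concatenate(
            [rng.normal(0.7, 0.01, 70), rng.normal(2.5, 0.01, 30)]
        )
        p = kmeans_1d(v, k=2, seed=5)
        assert sorted(p.counts) == [30, 70]
        assert p.within_group_ss() == pytest.approx(kmeans2_threshold_oracle(v), rel=1e-9)

    def test_wgss_never_beats_oracle_500_random_inputs(self, rng):
        """Lloyd's WGSS is lower-bounded by the exhaustive 1-D optimum."""
        for i in range(500):
            n = int(rng.integers(2, 200))
            v = rng.uniform(0.2, 5.0, size=n)
            p = kmeans_1d(v, k=2, seed=i)
            assert p.within_group_ss() >= kmeans2_threshold_oracle(v) - 1e-9


class TestMajorityClusterMedian:
    def test_majority_rule(self, rng):
        v = np.concatenate([rng.normal(0.8, 0.005, 70), rng.normal(2.5, 0.005, 30)])
        p = kmeans_1d(v, k=2, seed=0)
        maj = p.members(int(np.argmax(p.counts)))
        assert majority_cluster_median(p) == pytest.approx(np.median(maj))
        assert majority_cluster_median(p) == pytest.approx(0.8, abs=0.01)

    def test_single_group(self):
        p = kmeans_1d([0.5, 0.6, 0.7], k=1)
        assert majority_cluster_median(p) == pytest.approx(0.6)

    def test_even_count_median_is_mean_of_middles(self):
        p = kmeans_1d([0.4, 0.5, 0.6, 0.7], k=1)
        assert majority_cluster_median(p) == pytest.approx(0.55)

    def test_tie_goes_to_nearer_cluster(self):
        # exact 50/50 split: the smaller-center (nearer) cluster wins
        v = np.array([0.5] * 50 + [2.0] * 50)
        p = kmeans_1d(v, k=2, seed=0)
        assert sorted(p.counts) == [50, 50]
        assert majority_cluster_median(p) == pytest.approx(0.5)


class TestLocalize:
    def frame_with_plane(self, z_mm: int) -> DepthFrame:
        return make_frame(np.full((480, 640), z_mm))

    def test_constant_plane_exact(self, vga_intrinsics):
        box = BoundingBox(cx=320, cy=240, w=120, h=120)
        res = localize(box, self.frame_with_plane(800), vga_intrinsics, LocalizerConfig())
        assert res.status is LocalizationStatus.OK
        assert res.depth_m == pytest.approx(0.8)
        assert res.point == pytest.approx((0.0, 0.0, 0.8))
        assert res.n_valid_samples == 100

    def test_blind_zone(self, vga_intrinsics):
        box = BoundingBox(cx=320, cy=240, w=120, h=120)
        res = localize(box, self.frame_with_plane(250), vga_intrinsics, LocalizerConfig())
        assert res.status is LocalizationStatus.BLIND_ZONE
        assert res.point is None

    def test_beyond_accurate_range_keeps_flagged_point(self, vga_intrinsics):
        box = BoundingBox(cx=320, cy=240, w=120, h=120)
        res = localize(box, self.frame_with_plane(1500), vga_intrinsics, LocalizerConfig())
        assert res.status is LocalizationStatus.BEYOND_ACCURATE_RANGE
        assert res.point is not None and res.point.Z == pytest.approx(1.5)

    def test_full_dropout(self, vga_intrinsics):
        box = BoundingBox(cx=320, cy=240, w=120, h=120)
        res = localize(box, self.frame_with_plane(0), vga_intrinsics, LocalizerConfig())
        assert res.status is LocalizationStatus.NO_VALID_DEPTH
        assert res.point is None and res.n_valid_samples == 0

    def test_determinism_bit_for_bit(self, vga_intrinsics, rng):
        depth = (rng.uniform(600, 900, (480, 640))).astype(np.uint16)
        frame = DepthFrame(values=depth)
        box = BoundingBox(cx=300, cy=200, w=150, h=100)
        cfg = LocalizerConfig(rng_seed=11)
        a = localize(box, frame, vga_intrinsics, cfg)
        b = localize(box, frame, vga_intrinsics, cfg)
        assert a.depth_m == b.depth_m and a.status == b.status and a.point == b.point

    def test_contamination_robustness(self, vga_intrinsics, rng):
        """Up to 49% far outliers move the extracted depth by at most sigma."""
        sigma = 0.005
        t = 0.8
        for trial in range(200):
            n_out = int(rng.integers(1, 50))
            v = np.concatenate(
                [
                    rng.normal(t, sigma, 100 - n_out),
                    rng.normal(t + 10 * sigma + rng.uniform(0, 1.0), sigma, n_out),
                ]
            )
            p = kmeans_1d(v, k=2, seed=trial)
            assert abs(majority_cluster_median(p) - t) <= sigma


class TestAxisErrors:
    @pytest.mark.parametrize(
        "real,detected,expected",
        [
            ((-0.097, 0.055, 0.325), (-0.102, 0.042, 0.331), (5, 13, 6)),
            ((-0.044, 0.080, 0.459), (-0.058, 0.071, 0.463), (14, 9, 4)),
            ((0.1, 0.2, 0.3), (0.1, 0.2, 0.3), (0, 0, 0)),
        ],
    )
    def test_examples(self, real, detected, expected):
        assert axis_errors(Point3D(*real), Point3D(*detected)) == expected

    def test_unrounded_retained(self):
        ex, ey, ez = axis_errors_mm((0.0, 0.0, 0.0), (0.0014, 0.0, 0.0))
        assert ex == pytest.approx(1.4)

    def test_summary_single_pair(self):
        s = error_summary([((0, 0, 0), (0.005, 0.010, 0.015))])
        for axis, v in (("x", 5.0), ("y", 10.0), ("z", 15.0)):
            assert s[axis]["mean"] == s[axis]["max"] == s[axis]["min"] == v

    def test_summary_excludes_absent_detections(self):
        s = error_summary([((0, 0, 0), None), ((0, 0, 0), (0.001, 0.001, 0.001))])
        assert s["counts"] == {"n_included": 1, "n_excluded": 1}

    def test_summary_no_valid_pairs_raises(self):
        with pytest.raises(NoValidDepthError):
            error_summary([((0, 0, 0), None)])
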