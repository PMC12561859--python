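"""Unit and property tests for the mask-to-landmark geometry."""

import numpy as np
import pytest

from periomet.exceptions import EmptyMaskError, GeometryError, InputError
from periomet.geometry import (
    CalibratedScale,
    Circle,
    boundary_points,
    brow_height_at,
    calibrate_scale,
    landmark_columns,
    largest_component,
    measure_all,
    measure_mrd,
    min_enclosing_circle,
    min_enclosing_circle_bruteforce,
)


def disk_mask(shape, cx, cy, r):
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r


# ---------------------------------------------------------------------------
# largest_component
# ---------------------------------------------------------------------------

class TestLargestComponent:
    def test_single_blob_is_identity(self):
        mask = np.zeros((12, 12), bool)
        mask[3:7, 3:8] = True
        assert np.array_equal(largest_component(mask), mask)

    def test_speckle_removed(self):
        mask = np.zeros((20, 20), bool)
        mask[2:12, 2:7] = True       # 50 px blob
        mask[15:16, 15:18] = True    # 3 px speckle
        out = largest_component(mask)
        assert out.sum() == 50
        assert not out[15, 15]

    def test_equal_blobs_tie_break_topleft(self):
        # exhaustive over all placements of two disjoint 2x2 blobs in 10x10
        base = np.zeros((10, 10), bool)
        placements = [(0, 0), (0, 6), (6, 0), (6, 6), (3, 3)]
        for a in placements:
            for b in placements:
                if a == b:
                    continue
                mask = base.copy()
                mask[a[0]:a[0] + 2, a[1]:a[1] + 2] = True
                mask[b[0]:b[0] + 2, b[1]:b[1] + 2] = True
                out = largest_component(mask)
                first = min(a, b)  # row-major order = lexicographic (row, col)
                assert out[first[0], first[1]]
                assert out.sum() == 4

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            largest_component(np.zeros((5, 5), bool))

    def test_diagonal_pixels_are_8connected(self):
        mask = np.zeros((6, 6), bool)
        mask[1, 1] = mask[2, 2] = mask[3, 3] = True
        assert largest_component(mask).sum() == 3


# ---------------------------------------------------------------------------
# boundary_points
# ---------------------------------------------------------------------------

class TestBoundaryPoints:
    def test_solid_square_excludes_interior(self):
        mask = np.zeros((7, 7), bool)
        mask[2:5, 2:5] = True
        pts = boundary_points(mask)
        assert len(pts) == 8
        assert not any((p == [3, 3]).all() for p in pts)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        pts = boundary_points(mask)
        assert pts.tolist() == [[3.0, 2.0]]  # (x, y)

    def test_border_pixels_count_frame_as_background(self):
        mask = np.ones((3, 3), bool)
        assert len(boundary_points(mask)) == 8  # center is interior

    @pytest.mark.parametrize("seed", range(10))
    def test_circle_of_boundary_equals_circle_of_foreground(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((40, 40), bool)
        for _ in range(rng.integers(1, 4)):
            cx, cy = rng.uniform(8, 32, 2)
            r = rng.uniform(2, 7)
            mask |= disk_mask(mask.shape, cx, cy, r)
        rows, cols = np.nonzero(mask)
        full = min_enclosing_circle(np.column_stack((cols, rows)).astype(float))
        bdry = min_enclosing_circle(boundary_points(mask))
        assert full.radius == pytest.approx(bdry.radius, abs=1e-9)
        assert full.center == pytest.approx(bdry.center, abs=1e-9)


# ---------------------------------------------------------------------------
# minimum enclosing circle
# ---------------------------------------------------------------------------

class TestMinEnclosingCircle:
    def test_single_point(self):
        c = min_enclosing_circle([(3.0, 4.0)])
        assert c.center == (3.0, 4.0)
        assert c.radius == 0.0

    def test_two_point_diameter(self):
        c = min_enclosing_circle([(0, 0), (2, 0)])
        assert c.center == pytest.approx((1.0, 0.0))
        assert c.radius == pytest.approx(1.0)

    def test_acute_triangle_circumcircle(self):
        # circumcircle of (0,0), (4,0), (2,3): center (2, 5/6), radius 13/6
        c = min_enclosing_circle([(0, 0), (4, 0), (2, 3)])
        assert c.center == pytest.approx((2.0, 5.0 / 6.0), abs=1e-9)
        assert c.radius == pytest.approx(13.0 / 6.0, abs=1e-9)

    def test_collinear_points_use_extreme_pair(self):
        c = min_enclosing_circle([(0, 0), (1, 1), (2, 2), (5, 5)])
        b = min_enclosing_circle_bruteforce([(0, 0), (1, 1), (2, 2), (5, 5)])
        assert c.radius == pytest.approx(np.hypot(2.5, 2.5), abs=1e-9)
        assert b.radius == pytest.approx(c.radius, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(InputError):
            min_enclosing_circle([])

    def test_matches_bruteforce_on_200_random_sets(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n = int(rng.integers(1, 26))
            pts = rng.uniform(0, 100, size=(n, 2))
            fast = min_enclosing_circle(pts)
            slow = min_enclosing_circle_bruteforce(pts)
            assert fast.radius == pytest.approx(slow.radius, abs=1e-7)
            assert fast.center[0] == pytest.approx(slow.center[0], abs=1e-7)
            assert fast.center[1] == pytest.approx(slow.center[1], abs=1e-7)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 50, size=(40, 2))
        a = min_enclosing_circle(pts)
        for seed in range(5):
            b = min_enclosing_circle(rng.permutation(pts))
            assert a.radius == pytest.approx(b.radius, abs=1e-9)
            assert a.center == pytest.approx(b.center, abs=1e-9)

    def test_all_points_contained(self):
        rng = np.random.default_rng(99)
        pts = rng.normal(0, 10, size=(300, 2))
        c = min_enclosing_circle(pts)
        d = np.hypot(pts[:, 0] - c.center[0], pts[:, 1] - c.center[1])
        assert (d <= c.radius + 1e-7).all()

    def test_bruteforce_rejects_large_input(self):
        with pytest.raises(InputError):
            min_enclosing_circle_bruteforce(np.zeros((51, 2)))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

class TestCalibration:
    def test_radius_5p5_gives_unit_scale(self):
        assert calibrate_scale(Circle((0, 0), 5.5)).mm_per_px == pytest.approx(1.0)

    def test_radius_10_gives_0p55(self):
        assert calibrate_scale(Circle((0, 0), 10.0)).mm_per_px == pytest.approx(0.55)

    def test_reference_diameter_is_11mm(self):
        assert calibrate_scale(Circle((0, 0), 8)).reference_diameter_mm == 11.0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(GeometryError):
            calibrate_scale(Circle((0, 0), 0.0))


# ---------------------------------------------------------------------------
# landmark columns and brow heights
# ---------------------------------------------------------------------------

class TestLandmarkColumns:
    def brow(self, lo=5, hi=50, shape=(64, 64)):
        mask = np.zeros(shape, bool)
        mask[5:9, lo:hi + 1] = True
        return mask

    def test_limbus_columns_medial_left(self):
        cols = landmark_columns(Circle((32, 40), 10), self.brow())
        assert (cols["ML"], cols["PC"], cols["LL"]) == (22, 32, 42)

    def test_brow_extremes(self):
        cols = landmark_columns(Circle((32, 40), 10), self.brow(5, 50))
        assert cols["MBE"] == 5 and cols["LBE"] == 50

    def test_medial_right_swaps_sides(self):
        left = landmark_columns(Circle((32, 40), 10), self.brow(), "left")
        right = landmark_columns(Circle((32, 40), 10), self.brow(), "right")
        assert right["ML"] == left["LL"] and right["LL"] == left["ML"]
        assert right["MBE"] == left["LBE"] and right["LBE"] == left["MBE"]

    def test_unknown_side_rejected(self):
        with pytest.raises(InputError):
            landmark_columns(Circle((32, 40), 10), self.brow(), "up")


class TestBrowHeight:
    def test_brow_at_pupil_row_is_zero(self):
        mask = np.zeros((64, 64), bool)
        mask[40:44, 10:50] = True
        h = brow_height_at(mask, 30, (32.0, 40.0), CalibratedScale(0.55))
        assert h == pytest.approx(0.0)

    def test_20px_above_with_scale_0p55_is_11mm(self):
        mask = np.zeros((64, 64), bool)
        mask[20:24, 10:50] = True
        h = brow_height_at(mask, 30, (32.0, 40.0), CalibratedScale(0.55))
        assert h == pytest.approx(11.0)

    def test_out_of_band_column_gives_nan(self):
        mask = np.zeros((64, 64), bool)
        mask[20:24, 10:20] = True
        assert np.isnan(brow_height_at(mask, 40, (32.0, 40.0),
                                       CalibratedScale(0.55)))


# ---------------------------------------------------------------------------
# MRD measurement
# ---------------------------------------------------------------------------

class TestMeasureMRD:
    def test_fully_visible_disk(self):
        mask = disk_mask((64, 64), 32, 32, 10)
        mrd1, mrd2, top, bottom = measure_mrd(
            mask, Circle((32.0, 32.0), 10.0), CalibratedScale(0.55))
        assert mrd1 == pytest.approx(5.5, abs=0.55)
        assert mrd2 == pytest.approx(5.5, abs=0.55)
        assert not top and not bottom

    def test_upper_lid_4px_above_center(self):
        mask = disk_mask((64, 64), 32, 32, 10)
        mask[: 32 - 4] = False  # lid clips everything above row 28
        mrd1, _, top, _ = measure_mrd(
            mask, Circle((32.0, 32.0), 10.0), CalibratedScale(0.55))
        assert mrd1 == pytest.approx(4 * 0.55)
        assert top

    def test_lid_at_center_row_gives_zero(self):
        mask = disk_mask((64, 64), 32, 32, 10)
        mask[:32] = False
        mrd1, _, top, _ = measure_mrd(
            mask, Circle((32.0, 32.0), 10.0), CalibratedScale(0.55))
        assert mrd1 == pytest.approx(0.0)
        assert top

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            measure_mrd(np.zeros((8, 8), bool), Circle((4, 4), 2),
                        CalibratedScale(1.0))


# ---------------------------------------------------------------------------
# measure_all: end-to-end invariances
# ---------------------------------------------------------------------------

class TestMeasureAll:
    def test_mirror_symmetry(self, scene_small):
        _, _, truth = scene_small
        lm = measure_all(truth.iris_mask, truth.brow_mask, medial="left")
        mirrored = measure_all(truth.iris_mask[:, ::-1],
                               truth.brow_mask[:, ::-1], medial="right")
        for name, value in lm.values().items():
            assert mirrored.values()[name] == pytest.approx(value, abs=1e-9)

    def test_translation_invariance(self, scene_small):
        _, _, truth = scene_small
        lm = measure_all(truth.iris_mask, truth.brow_mask)
        shifted = measure_all(np.roll(truth.iris_mask, (5, -7), (0, 1)),
                              np.roll(truth.brow_mask, (5, -7), (0, 1)))
        for name, value in lm.values().items():
            assert shifted.values()[name] == pytest.approx(value, abs=1e-9)

    def test_scale_covariance(self, scene_small):
        # upscaling masks by k leaves mm values nearly unchanged
        _, _, truth = scene_small
        lm = measure_all(truth.iris_mask, truth.brow_mask)
        k = 2
        big_iris = np.kron(truth.iris_mask, np.ones((k, k), bool))
        big_brow = np.kron(truth.brow_mask, np.ones((k, k), bool))
        big = measure_all(big_iris, big_brow)
        assert big.mm_per_px == pytest.approx(lm.mm_per_px / k, rel=0.05)
        for name, value in lm.values().items():
            assert big.values()[name] == pytest.approx(
                value, abs=2.5 * lm.mm_per_px)

    def test_mrd_sum_within_corneal_diameter(self, scene_batch20):
        for _, _, truth in zip(*scene_batch20):
            lm = measure_all(truth.iris_mask, truth.brow_mask)
            assert lm.mrd1_mm + lm.mrd2_mm <= 11.0 + 2 * lm.mm_per_px

    def test_landmark_recovery_within_3px(self, scene_batch20):
        """Mask-based measurement tracks analytic truth within the method's
        demonstrated bound of 3 px x mm_per_px on every landmark."""
        for _, _, truth in zip(*scene_batch20):
            lm = measure_all(truth.iris_mask, truth.brow_mask)
            tol = 3.0 * truth.mm_per_px
            for name, value in truth.landmarks.values().items():
                assert lm.values()[name] == pytest.approx(value, abs=tol), name

    def test_error_names_failing_stage(self):
        with pytest.raises(EmptyMaskError, match=r"largest_component\(iris\)"):
            measure_all(np.zeros((8, 8), bool), np.ones((8, 8), bool))
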