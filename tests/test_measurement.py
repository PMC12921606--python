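"""Mask smoothing, perimeters, boundary distances, shape descriptors,
summary rows."""

import math

import numpy as np
import pytest

from conftest import distance_bruteforce, random_blob
from spheroidquant.mask_generation import SpheroidMask
from spheroidquant.measurement import (
    distance_to_boundary,
    mask_perimeter,
    measure_objects,
    shape_descriptors,
    smooth_mask,
    summarize,
)
from spheroidquant.object_detection import DetectedObject


def disk_mask(radius, size=None, px=1.0, center=None):
    size = size or 2 * radius + 20
    center = center or (size // 2, size // 2)
    rr, cc = np.mgrid[0:size, 0:size]
    grid = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return SpheroidMask(grid, px, "compact")


def obj_at(*coords):
    return DetectedObject(label=1, pixels=list(coords))


class TestSmoothMask:
    def test_empty_mask_passes_through(self):
        m = SpheroidMask(np.zeros((10, 10), bool), 1.0, "compact")
        assert smooth_mask(m).area_px == 0

    def test_large_disk_barely_changes(self):
        m = disk_mask(100)
        out = smooth_mask(m, detail_um=15.0)
        assert abs(out.area_px - m.area_px) < 0.01 * m.area_px

    def test_thin_spike_removed_and_perimeter_restored(self):
        plain = disk_mask(40, size=140)
        spiked = SpheroidMask(plain.grid.copy(), 1.0, "compact")
        spiked.grid[69:71, 110:140] = True  # 2 px wide, 30 px long spike
        out = smooth_mask(spiked, detail_um=15.0)
        assert not out.grid[69:71, 135:140].any()
        p_plain = mask_perimeter(smooth_mask(plain, 15.0))
        p_out = mask_perimeter(out)
        assert abs(p_out - p_plain) <= 0.02 * p_plain

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        m = SpheroidMask(random_blob(rng, 48), 1.0, "compact")
        once = smooth_mask(m, 8.0)
        twice = smooth_mask(once, 8.0)
        np.testing.assert_array_equal(once.grid, twice.grid)


class TestMaskPerimeter:
    def test_square_follows_tracing_convention(self):
        grid = np.zeros((60, 60), bool)
        grid[5:55, 5:55] = True
        assert mask_perimeter(SpheroidMask(grid, 1.0, "compact")) == 4 * 49

    def test_disk_close_to_analytic_circumference(self):
        p = mask_perimeter(disk_mask(50, size=120))
        assert abs(p - 2 * math.pi * 50) <= 0.05 * 2 * math.pi * 50

    def test_single_pixel_and_empty_are_zero(self):
        grid = np.zeros((5, 5), bool)
        assert mask_perimeter(SpheroidMask(grid, 1.0, "compact")) == 0
        grid[2, 2] = True
        assert mask_perimeter(SpheroidMask(grid, 1.0, "compact")) == 0

    def test_scales_linearly_with_pixel_size(self):
        m1 = disk_mask(30, px=1.0)
        m2 = disk_mask(30, px=2.0)
        assert mask_perimeter(m2) == pytest.approx(2 * mask_perimeter(m1))


class TestDistanceToBoundary:
    def test_straight_edge_geometry(self):
        grid = np.zeros((80, 80), bool)
        grid[:, :51] = True  # boundary column 50
        mask = SpheroidMask(grid, 1.0, "compact")
        obj = obj_at((40, 60))
        assert distance_to_boundary(obj, mask) == pytest.approx(10.0)

    def test_zero_for_centroid_on_boundary(self):
        grid = np.zeros((20, 20), bool)
        grid[5:15, 5:15] = True
        mask = SpheroidMask(grid, 1.0, "compact")
        assert distance_to_boundary(obj_at((5, 7)), mask) == 0.0

    def test_matches_bruteforce_on_random_blobs(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            grid = random_blob(rng, 24)
            mask = SpheroidMask(grid, 1.0, "compact")
            free = np.column_stack(np.nonzero(~grid))
            pt = tuple(free[rng.integers(len(free))])
            got = distance_to_boundary(obj_at(pt), mask)
            assert got == pytest.approx(distance_bruteforce(pt, grid), abs=1e-9)

    def test_edge_reference_uses_nearest_object_pixel(self):
        grid = np.zeros((40, 40), bool)
        grid[:, :11] = True
        mask = SpheroidMask(grid, 1.0, "compact")
        obj = obj_at((20, 15), (20, 25))  # centroid at col 20, nearest pixel col 15
        assert distance_to_boundary(obj, mask, reference="centroid") == pytest.approx(10.0)
        assert distance_to_boundary(obj, mask, reference="edge") == pytest.approx(5.0)

    def test_empty_mask_raises(self):
        mask = SpheroidMask(np.zeros((5, 5), bool), 1.0, "compact")
        with pytest.raises(ValueError, match="no boundary"):
            distance_to_boundary(obj_at((1, 1)), mask)


class TestShapeDescriptors:
    def test_disk_is_round_and_solid(self):
        rr, cc = np.mgrid[0:70, 0:70]
        disk = (rr - 35) ** 2 + (cc - 35) ** 2 <= 30**2
        obj = DetectedObject(label=1, pixels=np.column_stack(np.nonzero(disk)))
        circ, roundness, solidity = shape_descriptors(obj)
        assert circ >= 0.9
        assert solidity >= 0.98
        assert roundness >= 0.9

    def test_square_circularity_near_pi_over_4(self):
        grid = np.zeros((50, 50), bool)
        grid[5:45, 5:45] = True
        obj = DetectedObject(label=1, pixels=np.column_stack(np.nonzero(grid)))
        circ, _, solidity = shape_descriptors(obj)
        assert circ == pytest.approx(math.pi / 4, abs=0.05)
        assert solidity == pytest.approx(1.0, abs=0.02)

    def test_single_pixel_conventions(self):
        circ, roundness, solidity = shape_descriptors(obj_at((3, 3)))
        assert (circ, roundness, solidity) == (1.0, 1.0, 1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(19)
        blob = random_blob(rng, 20)
        coords = np.column_stack(np.nonzero(blob))
        a = shape_descriptors(DetectedObject(label=1, pixels=coords))
        b = shape_descriptors(DetectedObject(label=1, pixels=coords + [7, 13]))
        assert a == b

    def test_descriptors_bounded(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            coords = np.column_stack(np.nonzero(random_blob(rng, 24)))
            circ, roundness, solidity = shape_descriptors(
                DetectedObject(label=1, pixels=coords)
            )
            assert 0 < circ <= 1 and 0 < roundness <= 1 and 0 < solidity <= 1


class TestSummarize:
    def test_no_objects_row(self):
        mask = disk_mask(20)
        rec = summarize(mask, [], 1.0, timepoint_label="START")
        assert rec.n_objects == 0
        assert rec.total_object_area_um2 == 0
        assert rec.mean_distance_um is None and rec.median_distance_um is None
        assert rec.n_objects_per_mm == 0

    def test_mean_and_median_distances(self):
        mask = disk_mask(20, size=200)
        objs = [obj_at((5, 5 + i)) for i in range(4)]
        for o, d in zip(objs, (10.0, 20.0, 30.0, 100.0)):
            o.distance_um = d
        rec = summarize(mask, objs, 1.0, timepoint_label="24h")
        assert rec.mean_distance_um == 40.0
        assert rec.median_distance_um == 25.0
        assert rec.n_objects == 4

    def test_artifacts_excluded_from_all_figures_but_counted(self):
        mask = disk_mask(20, size=200)
        keepme = obj_at((5, 5))
        keepme.distance_um = 12.0
        bubble = obj_at((150, 150))
        bubble.distance_um = 99.0
        bubble.excluded_as_artifact = True
        rec = summarize(mask, [keepme, bubble], 1.0)
        assert rec.n_objects == 1
        assert rec.n_excluded_artifacts == 1
        assert rec.mean_distance_um == 12.0
        assert rec.total_object_area_um2 == 1.0

    def test_scale_consistency_doubling_pixel_size(self, disintegrating_run):
        dataset, _, masks = disintegrating_run
        from spheroidquant.object_detection import EMaxParams, detect

        img, mask = dataset.followups[0], masks[1]
        objs = detect(img, mask, EMaxParams(dynamic=0.001))
        # detail_um scales with the calibration so the smoothing element
        # stays the same on the fixed pixel grid
        measure_objects(objs, mask, 2.0)
        rec2 = summarize(mask, objs, 2.0, detail_um=8.0)
        measure_objects(objs, mask, 4.0)
        rec4 = summarize(mask, objs, 4.0, detail_um=16.0)
        assert rec4.mask_area_um2 == pytest.approx(4 * rec2.mask_area_um2)
        assert rec4.mask_perimeter_um == pytest.approx(2 * rec2.mask_perimeter_um)
        assert rec4.mean_distance_um == pytest.approx(2 * rec2.mean_distance_um)
        assert rec4.total_object_area_um2 == pytest.approx(4 * rec2.total_object_area_um2)
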