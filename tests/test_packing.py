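"""Watershed/Voronoi packing pipeline against geometric oracles."""

import numpy as np
import pytest
from skimage.draw import disk

from crystalgate.packing import (cell_metrics, distance_map, edge_overlay,
                                 hexagonal_ideal, mean_free_path,
                                 packing_summary, preprocess, segment_spheres,
                                 tessellate, CellMetrics)
from crystalgate.synthetic import SphereImageParams, gen_microsphere_image


def _disk_image(centers, radius, shape=(128, 128)):
    img = np.full(shape, 30, dtype=np.uint8)
    for c in centers:
        rr, cc = disk(c, radius, shape=shape)
        img[rr, cc] = 200
    return img


class TestPreprocess:
    def test_bimodal_separation(self):
        img = _disk_image([(64, 64)], 20)
        mask = preprocess(img)
        assert np.array_equal(mask, img == 200)

    def test_inverted_polarity(self):
        img = _disk_image([(64, 64)], 20)
        mask = preprocess(img, invert=True)
        assert np.array_equal(mask, img == 30)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.full((32, 32), 7, dtype=np.uint8))

    def test_noisy_mask_jaccard(self):
        p = SphereImageParams(intensity_noise_sd=5.0, seed=6)
        img, centers = gen_microsphere_image(p)
        truth = _disk_image(centers, p.radius_px, p.image_size) == 200
        mask = preprocess(img)
        jac = (mask & truth).sum() / (mask | truth).sum()
        assert jac >= 0.95


class TestDistanceMap:
    def test_single_pixel(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        d = distance_map(mask)
        assert d[4, 4] == 1.0
        assert (d[~mask] == 0).all()

    def test_disk_maximum_at_center(self):
        r = 25
        mask = _disk_image([(64, 64)], r) == 200
        d = distance_map(mask)
        assert abs(d.max() - r) <= 1.0
        peak = np.unravel_index(d.argmax(), d.shape)
        assert abs(peak[0] - 64) <= 1 and abs(peak[1] - 64) <= 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            distance_map(np.zeros((8, 8), dtype=bool))


class TestTessellate:
    def test_two_disk_boundary_is_bisector(self):
        # equal disks: the watershed line must sit on the perpendicular
        # bisector of the two centers, within 1 px
        centers = [(64, 40), (64, 90)]
        img = _disk_image(centers, 12)
        d = distance_map(preprocess(img))
        seg = tessellate(d, seeds=np.array(centers))
        assert seg.n_cells == 2
        boundary = np.argwhere(seg.label_image == 0)
        # exclude nothing: frame-touching watershed lines only exist
        # between the two regions here
        bisector_col = (40 + 90) / 2.0
        assert np.all(np.abs(boundary[:, 1] - bisector_col) <= 1.0)

    def test_single_disk_single_region(self):
        img = _disk_image([(64, 64)], 15)
        d = distance_map(preprocess(img))
        seg = tessellate(d, seeds=np.array([[64, 64]]))
        assert seg.n_cells == 1
        assert np.all(seg.label_image == 1)

    def test_hex_lattice_region_count(self):
        img, centers = gen_microsphere_image(SphereImageParams())
        seg = segment_spheres(img, min_distance=5)
        assert seg.n_cells == 25

    def test_region_count_equals_seed_count(self):
        p = SphereImageParams(lattice="random_sequential", n_spheres=14,
                              radius_px=9, seed=5)
        img, centers = gen_microsphere_image(p)
        seg = segment_spheres(img, seeds=centers)
        assert seg.n_cells == 14

    def test_pixel_conservation(self):
        img, centers = gen_microsphere_image(SphereImageParams())
        seg = segment_spheres(img, seeds=centers)
        lab = seg.label_image
        cell_px = sum((lab == k).sum() for k in range(1, seg.n_cells + 1))
        assert cell_px + (lab == 0).sum() == lab.size

    def test_zero_seeds_rejected(self):
        d = distance_map(_disk_image([(64, 64)], 10) == 200)
        with pytest.raises(ValueError):
            tessellate(d, seeds=np.empty((0, 2)))


class TestCellMetrics:
    def test_square_region_area(self):
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[5:15, 5:15] = 1
        from crystalgate.packing import SegmentationResult
        seg = SegmentationResult(lab, 1, 1.0, np.array([[10.0, 10.0]]))
        (cell,) = cell_metrics(seg)
        assert cell.area_nm2 == 100.0
        assert cell.interior

    def test_disk_perimeter_within_5pct(self):
        r = 50
        lab = np.zeros((128, 128), dtype=np.int32)
        rr, cc = disk((64, 64), r)
        lab[rr, cc] = 1
        from crystalgate.packing import SegmentationResult
        seg = SegmentationResult(lab, 1, 1.0, np.array([[64.0, 64.0]]))
        (cell,) = cell_metrics(seg)
        assert cell.perimeter_nm == pytest.approx(2 * np.pi * r, rel=0.05)

    def test_area_scales_with_px_size(self):
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[5:15, 5:15] = 1
        from crystalgate.packing import SegmentationResult
        a1 = cell_metrics(SegmentationResult(
            lab, 1, 1.0, np.array([[10.0, 10.0]])))[0].area_nm2
        a2 = cell_metrics(SegmentationResult(
            lab, 1, 2.5, np.array([[10.0, 10.0]])))[0].area_nm2
        assert a2 == pytest.approx(a1 * 2.5 ** 2)

    def test_isoperimetric_inequality(self):
        img, centers = gen_microsphere_image(SphereImageParams())
        seg = segment_spheres(img, seeds=centers, px_size_nm=1.0)
        for cell in cell_metrics(seg):
            assert cell.perimeter_nm ** 2 >= 4 * np.pi * cell.area_nm2 * 0.95


class TestPackingSummary:
    def _square_cells(self, n=4, area=100.0, perim=40.0):
        return [CellMetrics(label=i + 1, area_nm2=area, perimeter_nm=perim,
                            interior=True) for i in range(n)]

    def test_identical_cells_zero_se(self):
        summary = packing_summary(self._square_cells(), 10.0, 3e-3)
        assert summary.se_area_nm2 == 0.0
        assert summary.mean_area_nm2 == 100.0

    def test_hex_ideal_closed_form(self):
        # regular hexagon of side s: area (3√3/2)s², perimeter 6s;
        # inscribed-circle diameter d = s√3
        s = 10.0
        d = s * np.sqrt(3.0)
        area, perim = hexagonal_ideal(d)
        assert area == pytest.approx(259.81, abs=0.01)
        assert perim == pytest.approx(60.0)

    def test_hex_lattice_area_matches_ideal(self):
        # large spacing keeps the 1 px watershed-line bias below 2%
        p = SphereImageParams(n_spheres=25, radius_px=12,
                              spacing_px=120.0, image_size=(704, 704))
        img, centers = gen_microsphere_image(p)
        seg = segment_spheres(img, seeds=centers, px_size_nm=1.0)
        cells = cell_metrics(seg)
        # lattice-cell ideal: hexagon inscribed-circle diameter = spacing
        summary = packing_summary(cells, sphere_diameter_nm=120.0,
                                  concentration_m=3e-3)
        assert (summary.hex_area_deviation_nm2
                <= 0.02 * summary.mean_area_nm2)

    def test_needs_two_interior_cells(self):
        cells = [CellMetrics(1, 10.0, 15.0, interior=False),
                 CellMetrics(2, 10.0, 15.0, interior=True)]
        with pytest.raises(ValueError):
            packing_summary(cells, 10.0, 3e-3)


class TestMeanFreePath:
    def test_arithmetic_oracle(self):
        assert mean_free_path(3e-3, 1000.0) == pytest.approx(
            1.246e-4, rel=1e-3)

    def test_inverse_density(self):
        assert mean_free_path(2e-3, 500.0) == pytest.approx(
            mean_free_path(1e-3, 500.0) / 2.0)

    def test_inverse_square_diameter(self):
        assert mean_free_path(1e-3, 1000.0) == pytest.approx(
            mean_free_path(1e-3, 500.0) / 4.0)

    def test_configurable_kinetic_factor(self):
        assert mean_free_path(1e-3, 500.0, kinetic_factor=1.0) == (
            pytest.approx(np.sqrt(2.0) * mean_free_path(1e-3, 500.0)))


class TestEdgeOverlay:
    def test_shapes_and_red_edges(self):
        img, centers = gen_microsphere_image(SphereImageParams())
        seg = segment_spheres(img, seeds=centers)
        rgb = edge_overlay(img, seg)
        assert rgb.shape == img.shape + (3,)
        edges = seg.label_image == 0
        assert np.all(rgb[edges] == (255, 0, 0))

    def test_single_region_no_interior_red(self):
        img = _disk_image([(64, 64)], 15)
        d = distance_map(preprocess(img))
        seg = tessellate(d, seeds=np.array([[64, 64]]))
        rgb = edge_overlay(img, seg)
        red = (rgb[..., 0] == 255) & (rgb[..., 1] == 0) & (rgb[..., 2] == 0)
        assert not red.any()

    def test_shape_mismatch_rejected(self):
        img = _disk_image([(64, 64)], 15)
        d = distance_map(preprocess(img))
        seg = tessellate(d, seeds=np.array([[64, 64]]))
        with pytest.raises(ValueError):
            edge_overlay(img[:-1], seg)
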