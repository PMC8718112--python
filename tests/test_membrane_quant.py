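"""Contour tracing, membrane means, F-memb pooling and percent-of-control."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk

from receptorquant.errors import ContourError
from receptorquant.membrane_quant import (
    MembraneProfiler,
    mask_to_contour,
    membrane_mean,
    percent_of_control,
    pooled_f_memb,
)
from receptorquant.segmentation import CellMask, CellSegmenter
from receptorquant.stack_model import AnalysisConfig, TwoChannelStack
from receptorquant.synthetic import CellPhantomParams, make_cell_stack


def _disk_mask(radius, pad=4):
    d = disk(radius).astype(bool)
    return np.pad(d, pad)


class TestMaskToContour:
    def test_single_pixel_gives_length_one_path(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        contour = mask_to_contour(mask)
        assert contour.length_px == 1
        np.testing.assert_array_equal(contour.path, [[1, 1]])

    def test_filled_3x3_square_visits_all_8_perimeter_pixels_once(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        contour = mask_to_contour(mask)
        expected = {(r, c) for r in range(1, 4) for c in range(1, 4)} - {(2, 2)}
        visited = [tuple(p) for p in contour.path]
        assert set(visited) == expected
        assert len(visited) == len(set(visited)) == 8
        # consecutive pixels (and the wrap-around closure) are 8-neighbors
        closed = np.vstack([contour.path, contour.path[:1]])
        steps = np.abs(np.diff(closed, axis=0)).max(axis=1)
        assert (steps <= 1).all()

    @pytest.mark.parametrize("radius", [10, 30])
    def test_disk_path_length_near_digital_perimeter(self, radius):
        mask = _disk_mask(radius)
        contour = mask_to_contour(mask)
        boundary = mask & ~ndimage.binary_erosion(mask, np.ones((3, 3)))
        # oracle: exact count of boundary pixels
        assert contour.length_px == boundary.sum()
        assert set(map(tuple, contour.path)) == set(zip(*np.nonzero(boundary)))

    def test_break_position_is_seeded_and_inconsequential(self):
        mask = _disk_mask(12)
        rng = np.random.default_rng(0)
        img = rng.random(mask.shape)
        c1 = mask_to_contour(mask, rng_seed=1)
        c2 = mask_to_contour(mask, rng_seed=2)
        c1_again = mask_to_contour(mask, rng_seed=1)
        assert c1.break_index == c1_again.break_index
        assert membrane_mean(c1, img) == pytest.approx(membrane_mean(c2, img))

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:3, 1:3] = True
        mask[6:9, 6:9] = True
        with pytest.raises(ContourError, match="components"):
            mask_to_contour(mask)

    def test_hollow_mask_rejected(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[1:8, 1:8] = True
        mask[4, 4] = False
        with pytest.raises(ContourError, match="holes"):
            mask_to_contour(mask)

    def test_inner_side_lies_one_pixel_inward(self):
        mask = _disk_mask(10)
        outer = mask_to_contour(mask, side="outer")
        inner = mask_to_contour(mask, side="inner")
        boundary = mask & ~ndimage.binary_erosion(mask, np.ones((3, 3)))
        inner_set = set(map(tuple, inner.path))
        assert inner_set.isdisjoint(set(zip(*np.nonzero(boundary))))
        assert all(mask[r, c] for r, c in inner_set)


class TestMembraneMean:
    def test_constant_plane_returns_value(self):
        mask = _disk_mask(8)
        contour = mask_to_contour(mask)
        assert membrane_mean(contour, np.full(mask.shape, 37.5)) == 37.5

    def test_ring_cell_with_exact_contour_reads_rim_value(self):
        params = CellPhantomParams(
            image_size=96,
            radius_px=30,
            membrane_intensity=200.0,
            cytoplasm_a594_intensity=20.0 - 10.0,
            background=20.0,
            noise_sd=0.0,
            psf_sigma_px=0.0,
            puncta_count=0,
            rng_seed=0,
        )
        stack, truth = make_cell_stack(params)
        contour = mask_to_contour(truth.true_masks[0])
        assert membrane_mean(contour, stack.a594[0]) == pytest.approx(200.0)

    def test_out_of_bounds_contour_rejected(self):
        mask = _disk_mask(5)
        contour = mask_to_contour(mask)
        with pytest.raises(ValueError, match="outside"):
            membrane_mean(contour, np.zeros((4, 4)))


class TestPooledFMemb:
    def test_identical_slices_pool_to_common_value(self):
        params = CellPhantomParams(
            image_size=96,
            radius_px=30,
            membrane_intensity=120.0,
            noise_sd=0.0,
            psf_sigma_px=0.0,
            puncta_count=0,
            n_slices=10,
            rng_seed=0,
        )
        stack, truth = make_cell_stack(params)
        mask = CellMask(
            masks=truth.true_masks, thresholds=np.zeros(10), source="gfp"
        )
        m = pooled_f_memb(stack, mask, AnalysisConfig())
        assert m.f_memb == pytest.approx(120.0)
        assert m.n_slices == 10

    def test_pooling_is_mean_of_slice_means(self):
        means = np.array([100.0, 110.0, 120.0])
        from receptorquant.membrane_quant import MembraneMeasurement

        mm = MembraneMeasurement(per_slice_means=means, f_memb=means.mean(), n_slices=3)
        assert mm.f_memb == 110.0

    def test_recovers_generator_mean_within_2pct_with_slice_variation(self):
        params = CellPhantomParams(
            image_size=128,
            radius_px=40,
            membrane_intensity=150.0,
            membrane_intensity_sd_per_slice=5.0,
            noise_sd=0.0,
            psf_sigma_px=0.0,
            puncta_count=0,
            rng_seed=4,
        )
        stack, truth = make_cell_stack(params)
        seg = CellSegmenter().transform(stack)
        m = pooled_f_memb(stack, seg, AnalysisConfig())
        generated = truth.per_slice_rim_intensity.mean()
        assert m.f_memb == pytest.approx(generated, rel=0.02)

    def test_linearity_under_channel_scaling(self, small_phantom_params):
        params = CellPhantomParams(**small_phantom_params, rng_seed=9)
        stack, truth = make_cell_stack(params)
        mask = CellMask(
            masks=truth.true_masks,
            thresholds=np.zeros(params.n_slices),
            source="gfp",
        )
        cfg = AnalysisConfig()
        base = pooled_f_memb(stack, mask, cfg).f_memb
        scaled = TwoChannelStack(
            gfp=stack.gfp, a594=3.0 * stack.a594, pixel_size_um=0.08
        )
        assert pooled_f_memb(scaled, mask, cfg).f_memb == pytest.approx(3.0 * base)

    def test_excluding_all_slices_raises(self, small_phantom_params):
        params = CellPhantomParams(**small_phantom_params, n_slices=2, rng_seed=1)
        stack, truth = make_cell_stack(params)
        mask = CellMask(masks=truth.true_masks, thresholds=np.zeros(2), source="gfp")
        cfg = AnalysisConfig(excluded_slices=(0, 1))
        with pytest.raises(ValueError, match="exclusion"):
            pooled_f_memb(stack, mask, cfg)

    def test_traversal_direction_irrelevant_to_mean(self):
        mask = _disk_mask(10)
        img = np.random.default_rng(5).random(mask.shape)
        contour = mask_to_contour(mask)
        reversed_path = contour.path[::-1]
        assert img[reversed_path[:, 0], reversed_path[:, 1]].mean() == pytest.approx(
            membrane_mean(contour, img)
        )


class TestPercentOfControl:
    @pytest.mark.parametrize(
        "group,control,expected",
        [
            (115.5, 170.7, 68),  # DOR, dorsal striatum
            (85.8, 140.9, 61),   # DOR, ventral striatum
            (63.9, 170.7, 37),   # MOR, dorsal striatum
            (65.7, 140.9, 47),   # MOR, ventral striatum
        ],
    )
    def test_published_group_means_reproduce_reported_percentages(
        self, group, control, expected
    ):
        assert percent_of_control(group, control) == expected

    def test_identity_is_100(self):
        assert percent_of_control(3.7, 3.7) == 100

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            percent_of_control(10.0, 0.0)
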