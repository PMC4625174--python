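"""Segmentation: filters, masking, domain measurement, per-cell counts."""

import numpy as np
import pytest
from scipy import ndimage

from raftrack import SegmentationParams, SimConfig
from raftrack.segment import (
    domains_per_cell,
    make_mask,
    measure_domains,
    segment_movie,
    subtract_background,
    unsharp_mask,
)
from raftrack.synthetic import simulate_movie
from raftrack.types import Domain


def gaussian_spot(shape, center, sigma, amplitude, offset=0.0):
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return offset + amplitude * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


class TestSubtractBackground:
    def test_flat_field_maps_to_zero(self):
        out = subtract_background(np.full((64, 64), 37.0), radius_px=8)
        assert np.allclose(out, 0.0)

    def test_matches_independent_grey_opening(self):
        # independent oracle: scipy grey opening with the same disk
        rng = np.random.default_rng(0)
        img = gaussian_spot((64, 64), (32, 32), 2.0, 120.0, offset=100.0)
        img += rng.normal(0, 1, img.shape)
        radius = 8
        out = subtract_background(img, radius)
        yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
        disk = (yy**2 + xx**2) <= radius**2
        oracle = np.clip(img - ndimage.grey_opening(img, footprint=disk), 0, None)
        assert np.allclose(out, oracle)

    def test_spot_preserved_and_far_field_flat(self):
        img = gaussian_spot((80, 80), (40, 40), 2.0, 150.0, offset=100.0)
        out = subtract_background(img, radius_px=10)
        assert out[40, 40] == pytest.approx(150.0, rel=0.05)
        assert abs(out[5, 5]) < 2.0

    def test_output_nonnegative_on_random_input(self):
        rng = np.random.default_rng(1)
        out = subtract_background(rng.uniform(0, 255, (50, 50)), radius_px=5)
        assert out.min() >= 0.0

    def test_radius_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((20, 20)), radius_px=20)


class TestUnsharpMask:
    def test_zero_amount_is_identity(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 100, (40, 40))
        assert np.allclose(unsharp_mask(img, 5.0, 0.0), img)

    def test_constant_image_unchanged(self):
        img = np.full((40, 40), 12.0)
        assert np.allclose(unsharp_mask(img, 8.0, 1.0), img)

    def test_mean_approximately_preserved(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 100, (64, 64))
        out = unsharp_mask(img, 10.0, 0.9)
        assert out.mean() == pytest.approx(img.mean(), rel=0.01)

    def test_contrast_strictly_increases_for_spot(self):
        # oracle: closed-form enhancement at the peak vs a 5σ ring
        sigma = 2.0
        img = gaussian_spot((101, 101), (50, 50), sigma, 100.0, offset=10.0)
        out = unsharp_mask(img, radius_px=20.0, amount=0.9)
        ring = int(round(5 * sigma))
        contrast_in = img[50, 50] - img[50, 50 + ring]
        contrast_out = out[50, 50] - out[50, 50 + ring]
        assert contrast_out > contrast_in


class TestMakeMask:
    def test_step_image_thresholds_exactly(self):
        img = np.where(np.arange(100).reshape(10, 10) % 2 == 0, 10.0, 200.0)
        mask = make_mask(img, 100.0)
        assert np.array_equal(mask, img == 200.0)

    def test_out_of_range_thresholds_warn(self):
        img = np.random.default_rng(4).uniform(0, 1, (20, 20))
        with pytest.warns(UserWarning):
            assert not make_mask(img, 5.0).any()
        with pytest.warns(UserWarning):
            assert make_mask(img, -1.0).all()

    def test_otsu_separates_bimodal_image(self):
        img = np.concatenate([np.full(200, 10.0), np.full(200, 200.0)])
        rng = np.random.default_rng(5)
        img += rng.normal(0, 1, img.size)
        mask = make_mask(img.reshape(20, 20), "otsu")
        # the threshold lands in the gap between the modes
        assert 195 <= mask.sum() <= 205


class TestMeasureDomains:
    def test_constructed_square(self):
        mask = np.zeros((20, 20), bool)
        mask[5:8, 5:8] = True
        img = np.where(mask, 50.0, 0.0)
        doms = measure_domains(mask, img, SegmentationParams(min_area_px=4),
                               frame=3, pixel_size_um=0.5)
        assert len(doms) == 1
        d = doms[0]
        assert (d.area_px, d.mean_intensity, d.frame) == (9, 50.0, 3)
        assert d.area_um2 == pytest.approx(9 * 0.25)
        assert (d.centroid_row_px, d.centroid_col_px) == (6.0, 6.0)

    def test_min_area_filters_small_components(self):
        mask = np.zeros((20, 20), bool)
        mask[2:5, 2:5] = True      # area 9
        mask[10, 10:12] = True     # area 2
        doms = measure_domains(mask, mask.astype(float),
                               SegmentationParams(min_area_px=4))
        assert len(doms) == 1

    def test_areas_match_flood_fill_oracle(self):
        # independent oracle: scipy 8-connected labelling + bincount
        rng = np.random.default_rng(6)
        mask = ndimage.binary_dilation(rng.random((80, 80)) > 0.97,
                                       iterations=2)
        img = rng.uniform(1, 10, mask.shape)
        params = SegmentationParams(min_area_px=1)
        doms = measure_domains(mask, img, params)
        lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
        oracle_areas = sorted(np.bincount(lab.ravel())[1:])
        assert sorted(d.area_px for d in doms) == oracle_areas
        oracle_means = sorted(ndimage.mean(img, lab, np.arange(1, n + 1)))
        assert np.allclose(sorted(d.mean_intensity for d in doms), oracle_means)

    def test_labels_follow_raster_order_of_first_pixels(self):
        mask = np.zeros((20, 20), bool)
        mask[15:18, 2:5] = True
        mask[2:5, 10:13] = True
        doms = measure_domains(mask, mask.astype(float), SegmentationParams())
        assert doms[0].centroid_row_px < doms[1].centroid_row_px
        assert [d.label for d in doms] == [1, 2]


class TestDomainsPerCell:
    @staticmethod
    def _domain(r, c):
        return Domain(1, 0, 9, 1.0, 1.0, r, c)

    def test_all_in_one_cell(self):
        cells = np.ones((30, 30), np.int32)
        doms = [self._domain(5, 5), self._domain(20, 20)]
        assert domains_per_cell(doms, cells) == {1: 2}

    def test_empty_domain_list(self):
        assert domains_per_cell([], np.zeros((10, 10), np.int32)) == {}

    def test_manual_centroid_assignment(self):
        cells = np.zeros((30, 30), np.int32)
        cells[:, :15] = 1
        cells[:, 15:] = 2
        doms = [self._domain(3, 4), self._domain(10, 14.4), self._domain(8, 22)]
        assert domains_per_cell(doms, cells) == {1: 2, 2: 1}

    def test_label_zero_domains_dropped(self):
        cells = np.zeros((30, 30), np.int32)
        cells[0:10] = 1
        doms = [self._domain(5, 5), self._domain(25, 25)]
        assert domains_per_cell(doms, cells) == {1: 1}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            domains_per_cell([self._domain(50, 5)], np.ones((10, 10, 2), np.int32))


class TestOnSimulatedMovies:
    def test_recall_on_noiseless_movie(self, default_sim, seg_params):
        # every true domain of sufficient area overlaps a detection (IoU>=0.5)
        import dataclasses

        from raftrack.synthetic import render_movie, simulate_brownian_tracks
        from skimage.measure import label as sk_label

        cfg = dataclasses.replace(default_sim, n_frames=2, n_spots=12,
                                  background_level=50.0)
        tracks = simulate_brownian_tracks(cfg)
        movie, truth = render_movie(tracks, cfg, noise=False)
        frame = movie.data[0].astype(float)
        from raftrack.segment import segment_frame
        # threshold ≈ the 50%-of-peak truth convention on the enhanced scale
        doms, mask, _ = segment_frame(frame, SegmentationParams(threshold=70.0))
        det_lab = sk_label(mask, connectivity=2)
        true_lab = truth.domain_label_stack[0]
        for lbl in np.unique(true_lab)[1:]:
            region = true_lab == lbl
            if region.sum() < seg_params.min_area_px:
                continue
            overlapping = np.unique(det_lab[region])
            overlapping = overlapping[overlapping > 0]
            assert len(overlapping) >= 1
            best = max(
                (np.logical_and(det_lab == o, region).sum()
                 / np.logical_or(det_lab == o, region).sum())
                for o in overlapping
            )
            assert best >= 0.5

    def test_clustered_movie_has_fewer_larger_brighter_domains(self, seg_params):
        hits = 0
        for seed in range(10):
            mB, _ = simulate_movie(SimConfig(seed=seed), "brownian")
            mC, _ = simulate_movie(SimConfig(seed=seed + 1000), "clustered")
            dB = segment_movie(mB, seg_params, frames=[0])
            dC = segment_movie(mC, seg_params, frames=[0])
            hits += (
                dC.area_um2.median() > dB.area_um2.median()
                and dC.mean_intensity.mean() > dB.mean_intensity.mean()
                and len(dC) < len(dB)
            )
        assert hits >= 9
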