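import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nmjquant as nq
from nmjquant import (
    AccumulationConfig,
    RegionStats,
    ValidationError,
    accumulation_study,
    classify_accumulation,
    extract_nmj_rois,
    fiber_region_for,
    generate_geometry,
    median_filter,
    region_stats,
    render_volume,
    section_params,
)

from conftest import match_objects_to_truth


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((9, 9), 77, dtype=np.uint8)
        np.testing.assert_array_equal(median_filter(img, 1), img)

    def test_isolated_speck_removed(self):
        img = np.zeros((7, 7), dtype=np.uint8)
        img[3, 3] = 255
        assert median_filter(img, 1)[3, 3] == 0

    def test_center_of_1_to_9_is_5(self):
        img = np.arange(1, 10, dtype=np.uint8).reshape(3, 3)
        assert median_filter(img, 1)[1, 1] == 5

    def test_radius_zero_is_identity(self):
        img = np.random.default_rng(0).integers(0, 255, (5, 5), dtype=np.uint8)
        np.testing.assert_array_equal(median_filter(img, 0), img)


class TestRoiExtraction:
    def test_all_zero_image_yields_no_rois(self):
        assert extract_nmj_rois(np.zeros((32, 32), dtype=np.uint8)) == []

    def test_single_block_is_one_roi(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[10:16, 10:16] = 200
        rois = extract_nmj_rois(img)
        assert len(rois) == 1 and rois[0].sum() == 36

    def test_blocks_below_area_cutoff_are_dropped(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[2:4, 2:7] = 200  # area 10
        img[20:22, 20:25] = 200  # area 10
        assert extract_nmj_rois(img, AccumulationConfig(min_roi_area_px=20)) == []

    def test_threshold_bounds_inclusive(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[2:8, 2:8] = 30  # exactly at the lower bound
        assert len(extract_nmj_rois(img)) == 1
        img[2:8, 2:8] = 29
        assert extract_nmj_rois(img) == []

    def test_rois_sorted_by_centroid(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[40:46, 5:11] = 200
        img[5:11, 40:46] = 200
        rois = extract_nmj_rois(img)
        ys = [np.nonzero(r)[0].mean() for r in rois]
        assert ys == sorted(ys)


class TestFiberRegion:
    def test_square_dilation_ring_area(self):
        roi = np.zeros((32, 32), dtype=bool)
        roi[10:16, 10:16] = True
        ring = fiber_region_for(roi, AccumulationConfig(fiber_ring_radius_px=2))
        assert ring.sum() == 10 * 10 - 6 * 6
        assert not (ring & roi).any()

    def test_rings_exclude_other_rois(self):
        img = np.zeros((48, 48), dtype=np.uint8)
        img[10:16, 10:16] = 200
        img[10:16, 20:26] = 200
        rois = extract_nmj_rois(img)
        assert len(rois) == 2
        ring0 = fiber_region_for(rois[0], all_rois=rois)
        for other in rois[1:]:
            assert not (ring0 & other).any()

    def test_roi_filling_whole_image_has_no_fiber_region(self):
        roi = np.ones((8, 8), dtype=bool)
        assert fiber_region_for(roi) is None


class TestClassifier:
    @pytest.mark.parametrize(
        "nmj_mean, fiber_mean, fiber_sd, expected",
        [
            (100.0, 50.0, 20.0, True),
            (70.0, 50.0, 20.0, False),  # exact boundary: strict inequality
            (70.0001, 50.0, 20.0, True),
            (50.0, 50.0, 0.0, False),  # equal means, zero SD
        ],
    )
    def test_decision_rule(self, nmj_mean, fiber_mean, fiber_sd, expected):
        nmj = RegionStats(nmj_mean, 0.0, 10)
        fiber = RegionStats(fiber_mean, fiber_sd, 100)
        assert classify_accumulation(nmj, fiber) is expected

    def test_empty_region_is_validation_error(self):
        with pytest.raises(ValidationError):
            region_stats(np.zeros((4, 4)), np.zeros((4, 4), dtype=bool))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        gain=st.floats(0.1, 20.0, allow_nan=False),
        offset=st.floats(-50.0, 50.0, allow_nan=False),
    )
    def test_invariant_under_positive_affine_transform(self, seed, gain, offset):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 255, size=(24, 24))
        roi = np.zeros((24, 24), dtype=bool)
        roi[8:14, 8:14] = True
        ring = fiber_region_for(roi, AccumulationConfig(fiber_ring_radius_px=3))
        call = classify_accumulation(region_stats(img, roi), region_stats(img, ring))
        scaled = gain * img + offset
        call_scaled = classify_accumulation(
            region_stats(scaled, roi), region_stats(scaled, ring)
        )
        assert call == call_scaled


class TestStudy:
    def _run(self, fraction, seed=0, **overrides):
        params = section_params(
            marker_name="TH",
            positivity_fraction=fraction,
            n_nmjs=20,
            image_shape=(1, 256, 256),
            seed=seed,
            **overrides,
        )
        truth = generate_geometry(params)
        volume = render_volume(truth, params)
        return truth, volume, accumulation_study(volume, "TH")

    def test_uniform_marker_image_all_negative(self):
        truth, volume, _ = self._run(0.0, psf_sigma_um=0.0, noise=(0.0, 0.0))
        result = accumulation_study(volume, "TH")
        assert result.percent_positive == 0.0

    def test_high_contrast_noise_free_is_fully_recovered(self):
        _, _, result = self._run(1.0, psf_sigma_um=0.0, noise=(0.0, 0.0))
        assert result.percent_positive == 100.0

    def test_calls_match_truth_labels_exactly_without_noise(self):
        truth, volume, result = self._run(0.5, seed=3, psf_sigma_um=0.0, noise=(0.0, 0.0))
        bgt = volume.channel("BGT")[0]
        rois = extract_nmj_rois(bgt)
        assert len(rois) == truth.n_nmjs
        calls = list(result.table.records["positive"])
        voxel = np.asarray(volume.voxel_size[1:])
        for roi, call in zip(rois, calls):
            centroid = np.array(np.nonzero(roi)).mean(axis=1) * voxel
            idx = int(
                np.argmin(
                    np.linalg.norm(truth.nmj_centers[:, 1:] - centroid, axis=1)
                )
            )
            assert bool(call) == bool(truth.positive[idx])

    def test_recovery_under_default_noise(self):
        _, _, result = self._run(0.40, seed=5)
        assert abs(result.percent_positive - 40.0) <= 10.0

    def test_missing_channel_is_configuration_error(self):
        _, volume, _ = self._run(1.0)
        with pytest.raises(nq.ConfigurationError):
            accumulation_study(volume, "NPY")

    def test_3d_volume_rejected(self, noise_free_params):
        p = noise_free_params(n_nmjs=2)
        volume = render_volume(generate_geometry(p), p)
        with pytest.raises(ValidationError):
            accumulation_study(volume, p.marker_name)
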