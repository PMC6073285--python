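import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmjquant import (
    ValidationError,
    DistanceRecord,
    distance_distribution,
    edge_to_edge_distance,
    label_components,
    nearest_marker,
    proximity_fraction,
)

from conftest import bruteforce_min_distance

VOXEL = (1.0, 0.785, 0.785)


def _mask_at(*voxels, shape=(8, 8, 8)):
    mask = np.zeros(shape, dtype=bool)
    for v in voxels:
        mask[v] = True
    return mask


class TestEdgeToEdgeDistance:
    def test_identical_objects_are_at_zero(self):
        mask = _mask_at((2, 2, 2), (2, 2, 3))
        assert edge_to_edge_distance(mask, mask, VOXEL) == 0.0

    def test_overlapping_objects_are_at_zero(self):
        a = _mask_at((2, 2, 2), (2, 2, 3))
        b = _mask_at((2, 2, 3), (2, 2, 4))
        assert edge_to_edge_distance(a, b, VOXEL) == 0.0

    def test_three_xy_pitches(self):
        a = _mask_at((0, 0, 0))
        b = _mask_at((0, 0, 3))
        assert edge_to_edge_distance(a, b, VOXEL) == pytest.approx(2.355)

    def test_anisotropy_respected_along_z(self):
        a = _mask_at((0, 0, 0))
        b = _mask_at((2, 0, 0))
        assert edge_to_edge_distance(a, b, VOXEL) == pytest.approx(2.0)
        assert edge_to_edge_distance(a, b, (1.04, 0.785, 0.785)) == pytest.approx(2.08)

    def test_face_adjacent_voxels(self):
        a = _mask_at((0, 0, 0))
        b = _mask_at((0, 0, 1))
        assert edge_to_edge_distance(a, b, VOXEL) == pytest.approx(0.785)

    def test_only_border_voxels_matter(self):
        # solid 3x3x3 block: its interior voxel plays no role
        a = np.zeros((8, 8, 8), dtype=bool)
        a[1:4, 1:4, 1:4] = True
        b = _mask_at((2, 2, 6))
        expected = (6 - 3) * 0.785
        assert edge_to_edge_distance(a, b, VOXEL) == pytest.approx(expected)

    def test_empty_object_rejected(self):
        with pytest.raises(ValidationError):
            edge_to_edge_distance(_mask_at(), _mask_at((0, 0, 0)), VOXEL)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetric_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6, 6)) < 0.15
        b = rng.random((6, 6, 6)) < 0.15
        if not a.any() or not b.any():
            return
        d_ab = edge_to_edge_distance(a, b, VOXEL)
        d_ba = edge_to_edge_distance(b, a, VOXEL)
        assert d_ab == pytest.approx(d_ba)
        assert d_ab >= 0.0
        assert edge_to_edge_distance(a, a, VOXEL) == 0.0


class TestNearestMarker:
    def test_nearest_of_two_markers_wins(self):
        nmj = label_components(_mask_at((4, 4, 4), shape=(9, 9, 12)), 26)
        markers = _mask_at((4, 4, 6), (4, 4, 11), shape=(9, 9, 12))
        records = nearest_marker(nmj, label_components(markers, 26), VOXEL)
        assert len(records) == 1
        assert records[0].nearest_marker_id == 1
        assert records[0].distance_um == pytest.approx(2 * 0.785)

    def test_tie_broken_toward_lower_marker_id(self):
        nmj = label_components(_mask_at((4, 4, 5), shape=(9, 9, 11)), 26)
        markers = _mask_at((4, 4, 2), (4, 4, 8), shape=(9, 9, 11))
        records = nearest_marker(nmj, label_components(markers, 26), VOXEL)
        assert records[0].nearest_marker_id == 1

    def test_no_markers_gives_infinite_distances(self):
        nmj = label_components(_mask_at((2, 2, 2)), 26)
        empty = label_components(np.zeros((8, 8, 8), dtype=bool), 26)
        records = nearest_marker(nmj, empty, VOXEL)
        assert records[0].nearest_marker_id is None
        assert math.isinf(records[0].distance_um)

    def test_overlap_reports_zero_and_overlapping_marker(self):
        nmj = label_components(_mask_at((2, 2, 2), (2, 2, 3)), 26)
        markers = label_components(_mask_at((2, 2, 3)), 26)
        records = nearest_marker(nmj, markers, VOXEL)
        assert records[0].distance_um == 0.0
        assert records[0].nearest_marker_id == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        nmj_mask = rng.random((16, 16, 16)) < 0.04
        marker_mask = rng.random((16, 16, 16)) < 0.04
        nmj = label_components(nmj_mask, 26)
        markers = label_components(marker_mask, 26)
        if nmj.n_objects == 0 or markers.n_objects == 0:
            return
        records = nearest_marker(nmj, markers, VOXEL)
        for record in records:
            expected = min(
                bruteforce_min_distance(
                    nmj.mask(record.nmj_id), markers.mask(mid), VOXEL
                )
                for mid in markers.ids
            )
            assert record.distance_um == pytest.approx(expected)


class TestSummaries:
    def _records(self, distances):
        return [DistanceRecord(i + 1, 1, d) for i, d in enumerate(distances)]

    def test_all_zero_distances(self):
        assert proximity_fraction(self._records([0, 0, 0]), 2.0) == 1.0

    def test_half_below(self):
        assert proximity_fraction(self._records([1.0, 3.0]), 2.0) == 0.5

    def test_cutoff_is_strict(self):
        assert proximity_fraction(self._records([2.0]), 2.0) == 0.0

    def test_infinite_distance_counts_in_denominator(self):
        assert proximity_fraction(self._records([0.5, math.inf]), 2.0) == 0.5

    def test_monotone_in_threshold(self):
        records = self._records([0.3, 1.1, 1.9, 2.5, math.inf])
        fracs = [proximity_fraction(records, t) for t in (0.5, 1.0, 2.0, 3.0, 10.0)]
        assert fracs == sorted(fracs)

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            proximity_fraction([], 2.0)

    def test_histogram_bins_right_open(self):
        dist = distance_distribution(self._records([0.3]), 0.5)
        assert dist.counts[0] == 1 and dist.counts.sum() == 1
        dist = distance_distribution(self._records([0.5]), 0.5)
        assert dist.counts[0] == 0 and dist.counts[1] == 1

    def test_histogram_conserves_record_count(self):
        records = self._records([0.1, 0.4, 1.7, 2.0, 6.3, math.inf])
        dist = distance_distribution(records, 0.5)
        assert dist.n_records == len(records)
        assert dist.counts.sum() + dist.overflow == len(records)

    def test_cdf_at_cutoff_equals_proximity_fraction(self):
        records = self._records([0.1, 0.4, 1.7, 2.0, 6.3, math.inf])
        dist = distance_distribution(records, 0.5)
        assert dist.cdf(2.0) == pytest.approx(proximity_fraction(records, 2.0))
        # finite mass of the CDF excludes the overflow records
        assert dist.cdf(1e9) == pytest.approx((len(records) - 1) / len(records))
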