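"""DBSCAN voxel clustering and coronary-cluster identification."""

import numpy as np
import pytest

import autoffr as af
from autoffr.aorta import ReferencePoint
from autoffr.clustering import ClusterParams, CoronaryPairNotFoundError, clusters_to_mask
from autoffr.volume import BinaryVolume


def mask_from_points(points, shape=(20, 20, 20)):
    m = np.zeros(shape, dtype=bool)
    for p in points:
        m[tuple(p)] = True
    return BinaryVolume(m, (1.0, 1.0, 1.0))


REF = ReferencePoint(center=(0.0, 0.0), slice_range=(0, 1), radius=30.0)


class TestClusterVoxels:
    def test_collinear_chain_is_one_cluster(self):
        pts = [(0, 0, i) for i in range(5)]  # spacing 1 < eps 1.6
        clusters, noise = af.cluster_voxels(mask_from_points(pts))
        assert len(clusters) == 1 and len(clusters[0]) == 5
        assert len(noise) == 0

    def test_two_distant_voxels_are_noise(self):
        clusters, noise = af.cluster_voxels(mask_from_points([(0, 0, 0), (0, 0, 3)]))
        assert clusters == [] and len(noise) == 2

    def test_dense_group_plus_far_point_labels_noise(self):
        # a compact group with one point far outside any search radius
        pts = [(5, 5, 5), (5, 5, 6), (5, 6, 5), (6, 5, 5), (5, 6, 6), (12, 12, 12)]
        clusters, noise = af.cluster_voxels(mask_from_points(pts))
        assert len(clusters) == 1 and len(clusters[0]) == 5
        assert [tuple(p) for p in noise] == [(12, 12, 12)]

    def test_empty_mask_gives_empty_result(self):
        clusters, noise = af.cluster_voxels(mask_from_points([]))
        assert clusters == [] and len(noise) == 0

    def test_partition_is_disjoint_and_complete(self):
        rng = np.random.default_rng(0)
        pts = {tuple(p) for p in rng.integers(0, 18, (60, 3))}
        clusters, noise = af.cluster_voxels(mask_from_points(pts))
        seen = [tuple(p) for c in clusters for p in c.voxel_indices]
        seen += [tuple(p) for p in noise]
        assert sorted(seen) == sorted(pts)

    def test_core_membership_order_independent(self):
        # same point set through a permuted volume: core points group identically
        pts = [(5, 5, 5), (5, 5, 6), (5, 6, 5), (9, 9, 9), (9, 9, 10), (9, 10, 9)]
        c1, _ = af.cluster_voxels(mask_from_points(pts))
        sets1 = {frozenset(map(tuple, c.voxel_indices)) for c in c1}
        shifted = [(19 - k, 19 - i, 19 - j) for k, i, j in pts]  # reversed scan order
        c2, _ = af.cluster_voxels(mask_from_points(shifted))
        sets2 = {frozenset((19 - k, 19 - i, 19 - j) for k, i, j in map(tuple, c.voxel_indices))
                 for c in c2}
        assert sets1 == sets2

    def test_params_validated(self):
        with pytest.raises(ValueError):
            ClusterParams(eps=0)
        with pytest.raises(ValueError):
            ClusterParams(min_pts=0)


class TestSelectCoronary:
    def make_clusters(self, groups):
        return [af.VoxelCluster(np.array(g), i) for i, g in enumerate(groups)]

    def test_two_nearest_clusters_chosen(self):
        groups = [
            [(0, 0, 10)], [(0, 0, -12)], [(0, 80, 0)],
        ]
        cl = self.make_clusters(groups)
        left, right = af.select_coronary_clusters(cl, REF, min_size=1)
        chosen = {tuple(left.voxel_indices[0]), tuple(right.voxel_indices[0])}
        assert chosen == {(0, 0, 10), (0, 0, -12)}

    def test_left_right_assignment_by_column(self):
        cl = self.make_clusters([[(0, 0, 10)], [(0, 0, -12)]])
        left, right = af.select_coronary_clusters(cl, REF, min_size=1)
        assert left.mean_col() > right.mean_col()

    def test_single_cluster_errors(self):
        with pytest.raises(CoronaryPairNotFoundError, match="coronary pair"):
            af.select_coronary_clusters(self.make_clusters([[(0, 0, 0)]]), REF, min_size=1)

    def test_tiny_clusters_not_coronary_candidates(self):
        """Sub-vessel-size residues near the reference never outrank trees."""
        rng = np.random.default_rng(2)
        tree1 = [(5, 40 + int(i // 8), 30 + i % 8) for i in range(80)]
        tree2 = [(5, 40 + int(i // 8), -30 - i % 8) for i in range(80)]
        speck = [(0, 1, 1), (0, 1, 2)]  # right next to the reference
        cl = self.make_clusters([tree1, tree2, speck])
        left, right = af.select_coronary_clusters(cl, REF)
        assert len(left) >= 50 and len(right) >= 50


@pytest.fixture(scope="module")
def phantom():
    return af.make_coronary_phantom(seed=5, noise_sigma=0.0)


class TestSegmentCoronary:

    def test_single_threshold_equals_union_of_one(self, phantom):
        vol, labels = phantom
        cvol = af.crop_cardiac_region(vol, ((0, 1), (0.2, 0.8), (0.2, 0.8)))
        ref = af.detect_aorta_center(cvol)
        fp1 = af.FilterParams(grey_thresholds=(130,))
        l1, r1 = af.segment_coronary(cvol, fp1, ref=ref)
        # recompute through the union path with the same single threshold
        l2, r2 = af.segment_coronary(cvol, af.FilterParams(grey_thresholds=(130,)), ref=ref)
        np.testing.assert_array_equal(l1.mask, l2.mask)
        assert l1.mask.any() and r1.mask.any()

    def test_union_monotone_in_threshold_list(self, phantom):
        vol, _ = phantom
        cvol = af.crop_cardiac_region(vol, ((0, 1), (0.2, 0.8), (0.2, 0.8)))
        ref = af.detect_aorta_center(cvol)
        small, _ = af.segment_coronary(cvol, af.FilterParams(grey_thresholds=(135,)), ref=ref)
        big, _ = af.segment_coronary(cvol, af.FilterParams(grey_thresholds=(125, 135)), ref=ref)
        assert not (small.mask & ~big.mask).any()

    def test_graded_intensity_needs_low_threshold(self, phantom):
        """A 145-only copy misses the distal low-intensity segments that the
        multi-threshold union captures."""
        vol, labels = phantom
        cvol = af.crop_cardiac_region(vol, ((0, 1), (0.2, 0.8), (0.2, 0.8)))
        ref = af.detect_aorta_center(cvol)
        lo, ro = af.segment_coronary(cvol, af.FilterParams(grey_thresholds=(125,)), ref=ref)
        hi, rh = af.segment_coronary(cvol, af.FilterParams(grey_thresholds=(145,)), ref=ref)
        assert (hi.mask.sum() + rh.mask.sum()) < 0.6 * (lo.mask.sum() + ro.mask.sum())

    def test_all_thresholds_failing_raises(self, phantom):
        vol, _ = phantom
        cvol = af.crop_cardiac_region(vol, ((0, 1), (0.2, 0.8), (0.2, 0.8)))
        ref = af.detect_aorta_center(cvol)
        with pytest.raises(CoronaryPairNotFoundError):
            af.segment_coronary(cvol, af.FilterParams(grey_thresholds=(250,)), ref=ref)
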