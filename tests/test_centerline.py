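"""Cleaning, skeletonisation, branch splitting, surface and radii."""

import numpy as np
import pytest

import autoffr as af
from autoffr.centerline import VolumeDestroyedError
from autoffr.volume import BinaryVolume


def tube_mask(radius=3, length=60, shape=(70, 32, 32), spacing=(1.0, 1.0, 1.0)):
    k, i, j = np.mgrid[: shape[0], : shape[1], : shape[2]]
    cy, cx = shape[1] // 2, shape[2] // 2
    m = ((i - cy) ** 2 + (j - cx) ** 2 <= radius**2) & (k >= 5) & (k < 5 + length)
    return BinaryVolume(m, spacing)


def y_mask(shape=(60, 60, 24)):
    """Y-shaped tube: one trunk splitting into two arms, all radius 2."""
    m = np.zeros(shape, dtype=bool)
    k, i, j = np.mgrid[: shape[0], : shape[1], : shape[2]]
    for (k0, i0), (k1, i1) in [((5, 30), (30, 30)), ((30, 30), (52, 12)), ((30, 30), (52, 48))]:
        n = 80
        for t in np.linspace(0, 1, n):
            kk, ii = k0 + t * (k1 - k0), i0 + t * (i1 - i0)
            m[((k - kk) ** 2 + (i - ii) ** 2 + (j - 12) ** 2) <= 4] = True
    return BinaryVolume(m, (1.0, 1.0, 1.0))


class TestClean:
    def test_thin_tube_untouched_by_root_removal(self):
        mask = tube_mask(radius=3)
        out = af.clean_voxel_volume(mask)
        # a radius-3 tube holds far fewer than 700 voxels in any radius-7 ball
        np.testing.assert_array_equal(out.mask, mask.mask)

    def test_bulky_sphere_removed_tube_kept(self):
        mask = tube_mask(radius=3, shape=(70, 48, 48))
        k, i, j = np.mgrid[:70, :48, :48]
        sphere = (k - 10) ** 2 + (i - 24) ** 2 + (j - 24) ** 2 <= 15**2
        both = BinaryVolume(mask.mask | sphere, mask.spacing)
        out = af.clean_voxel_volume(both)
        assert not (out.mask & sphere & ~mask.mask).any()
        kept = out.mask & mask.mask & (k > 30)  # tube away from the sphere
        assert kept.sum() > 0.9 * (mask.mask & (k > 30)).sum()

    def test_scattered_voxels_removed(self):
        m = np.zeros((20, 20, 20), dtype=bool)
        m[2, 2, 2] = m[10, 15, 3] = m[17, 4, 18] = True
        with pytest.raises(VolumeDestroyedError, match="destroyed"):
            af.clean_voxel_volume(BinaryVolume(m, (1, 1, 1)))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            af.clean_voxel_volume(BinaryVolume(np.zeros((4, 4, 4), bool), (1, 1, 1)))


class TestSkeleton:
    def test_straight_tube_gives_axis_line(self):
        skel = af.extract_skeleton(tube_mask(radius=4, length=100, shape=(110, 32, 32)))
        pts = skel.indices()
        inner = pts[(pts[:, 0] > 10) & (pts[:, 0] < 100)]
        dev = np.hypot(inner[:, 1] - 16, inner[:, 2] - 16)
        assert dev.max() <= 1.0
        # one voxel per slice along the shaft
        ks, counts = np.unique(inner[:, 0], return_counts=True)
        assert counts.max() == 1

    def test_topology_preserved_two_components(self):
        m1 = tube_mask(radius=2, length=20, shape=(70, 40, 40))
        m2 = np.zeros_like(m1.mask)
        m2[40:60, 28:33, 28:33] = True  # odd-width bar: thinning keeps a line
        skel = af.extract_skeleton(BinaryVolume(m1.mask | m2, m1.spacing))
        from skimage.measure import label

        assert label(skel.mask, connectivity=3).max() == 2

    def test_single_voxel_is_its_own_skeleton(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        skel = af.extract_skeleton(BinaryVolume(m, (1, 1, 1)))
        assert skel.mask.sum() == 1 and skel.mask[2, 2, 2]


class TestSplitBranches:
    def test_y_phantom_three_branches_one_junction(self):
        skel = af.extract_skeleton(y_mask())
        tree = af.prune_spurs(af.split_branches(skel))
        assert len(tree.branches) == 3
        assert len(tree.junctions) == 1

    def test_unbranched_path_single_branch(self):
        skel = af.extract_skeleton(tube_mask(radius=3))
        tree = af.split_branches(skel)
        assert len(tree.branches) == 1
        n_skel = skel.mask.sum()
        assert len(tree.branches[0]) == n_skel

    def test_two_disjoint_paths_two_branches(self):
        m1 = tube_mask(radius=2, length=20, shape=(70, 40, 40))
        m2 = np.zeros_like(m1.mask)
        m2[40:65, 28:33, 28:33] = True
        skel = af.extract_skeleton(BinaryVolume(m1.mask | m2, m1.spacing))
        tree = af.split_branches(skel)
        assert len(tree.branches) == 2


class TestSurface:
    def test_sphere_area_tracks_analytic_value(self):
        # marching cubes on a binary mask is staircase-biased high: the
        # digital sphere surface measures a few percent above 4 pi r^2
        k, i, j = np.mgrid[:32, :32, :32]
        m = (k - 16) ** 2 + (i - 16) ** 2 + (j - 16) ** 2 <= 10**2
        verts, faces = af.extract_surface(BinaryVolume(m, (1, 1, 1)))
        tri = verts[faces]
        area = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        ).sum()
        analytic = 4 * np.pi * 10**2
        assert 1.0 <= area / analytic <= 1.25

    def test_tube_area_tracks_analytic_value(self):
        r, L = 4, 60
        verts, faces = af.extract_surface(tube_mask(radius=r, length=L, shape=(70, 32, 32)))
        tri = verts[faces]
        area = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        ).sum()
        analytic = 2 * np.pi * r * L + 2 * np.pi * r**2
        assert 1.0 <= area / analytic <= 1.25

    def test_single_voxel_closed_surface(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        verts, faces = af.extract_surface(BinaryVolume(m, (1, 1, 1)))
        assert len(verts) > 0 and len(faces) > 0
        # closed surface: every edge shared by exactly two triangles
        edges = {}
        for f in faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                e = (min(a, b), max(a, b))
                edges[e] = edges.get(e, 0) + 1
        assert set(edges.values()) == {2}


class TestRadii:
    def test_tube_radius_recovered_within_half_voxel(self):
        mask = tube_mask(radius=4, length=100, shape=(110, 32, 32))
        skel = af.extract_skeleton(mask)
        tree = af.split_branches(skel)
        verts, _ = af.extract_surface(mask)
        tree = af.estimate_radii(tree, verts)
        r = tree.branches[0].radii
        inner = r[5:-5]
        assert np.all(np.abs(inner - 4.0) <= 0.5)

    def test_stenosed_tube_minimum_recovered(self):
        spec = af.stenosed_tube_spec(severity=0.5, noise_sigma=0.0)
        _, truth, *_ = af.make_tube_phantom(spec)
        skel = af.extract_skeleton(truth)
        tree = af.estimate_radii(af.split_branches(skel), af.extract_surface(truth)[0])
        rmin = min(b.radii.min() for b in tree.branches)
        assert rmin == pytest.approx(2 * 0.458, abs=0.5 * 0.458)

    def test_empty_surface_rejected(self):
        tree = af.CenterlineTree([af.Branch(np.zeros((3, 3)))])
        with pytest.raises(ValueError, match="empty"):
            af.estimate_radii(tree, np.empty((0, 3)))

    def test_point_on_vertex_dropped(self):
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        tree = af.CenterlineTree([af.Branch(pts)])
        verts = np.array([[0.0, 0.0, 0.0], [5.0, 5.0, 5.0], [6.0, 5.0, 5.0]])
        out = af.estimate_radii(tree, verts, median_window=0)
        # the point coincident with a vertex has radius 0 and is dropped
        assert len(out.branches[0]) == 2
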