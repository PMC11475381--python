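"""Density clustering of candidate voxels and coronary-cluster identification.

Candidate voxel centres from each thresholded copy are grouped with DBSCAN
(voxel-index space, default eps 1.6 voxels, min_pts 2).  Among the resulting
clusters, the two with points nearest the aortic reference are taken as the
left and right coronary trees; masks from all grey-threshold copies are
merged by voxel-wise union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .aorta import ReferencePoint
from .filtering import FilterParams, candidate_mask, preprocess_volume
from .volume import BinaryVolume, ImageVolume


class CoronaryPairNotFoundError(RuntimeError):
    """Fewer than two clusters available for coronary identification."""


@dataclass
class ClusterParams:
    """DBSCAN settings: ``eps`` search radius (voxels) and minimum points.

    ``min_pts`` counts the point itself (classic DBSCAN MinPts).  The metric
    is Euclidean distance in voxel-index space; set ``metric_mm`` to cluster
    in physical mm instead.
    """

    eps: float = 1.6
    min_pts: int = 2
    metric_mm: bool = False
    min_coronary_size: int = 50

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if self.min_coronary_size < 1:
            raise ValueError("min_coronary_size must be >= 1")


@dataclass
class VoxelCluster:
    """A labelled set of voxel indices produced by density clustering."""

    voxel_indices: np.ndarray  # (n, 3) int array of (k, i, j)
    label: int
    core_mask: np.ndarray | None = None  # per-point: True = core, False = outer

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices)
        if len(self.voxel_indices) == 0:
            raise ValueError("cluster must be non-empty")

    def __len__(self) -> int:
        return len(self.voxel_indices)

    def min_distance_to(self, point: np.ndarray, scale: np.ndarray | None = None) -> float:
        """Minimum distance from any cluster voxel to ``point`` (k, i, j)."""
        d = self.voxel_indices.astype(float) - np.asarray(point, dtype=float)
        if scale is not None:
            d = d * scale
        return float(np.sqrt((d * d).sum(axis=1)).min())

    def mean_col(self) -> float:
        return float(self.voxel_indices[:, 2].mean())


def cluster_voxels(
    mask: BinaryVolume, params: ClusterParams | None = None
) -> tuple[list[VoxelCluster], np.ndarray]:
    """DBSCAN-cluster the set voxel centres of a binary volume.

    Returns ``(clusters, noise_points)``; every masked voxel lands in exactly
    one cluster or in the noise set.  Points are fed in lexicographic scan
    order of their indices so border-point assignment is deterministic.
    """
    params = params or ClusterParams()
    pts = mask.indices()  # argwhere => C order == lexicographic
    if len(pts) == 0:
        return [], np.empty((0, 3), dtype=int)
    coords = pts.astype(float)
    if params.metric_mm:
        dx, dy, dz = mask.spacing
        coords = coords * np.array([dz, dy, dx])
    db = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit(coords)
    labels = db.labels_
    core = np.zeros(len(pts), dtype=bool)
    core[db.core_sample_indices_] = True
    clusters = []
    for lab in range(labels.max() + 1):
        sel = labels == lab
        clusters.append(VoxelCluster(pts[sel], lab, core_mask=core[sel]))
    noise = pts[labels == -1]
    return clusters, noise


def select_coronary_clusters(
    clusters: list[VoxelCluster],
    ref: ReferencePoint,
    scale: np.ndarray | None = None,
    min_size: int = 50,
) -> tuple[VoxelCluster, VoxelCluster]:
    """Pick the two clusters nearest the aortic reference as the coronaries.

    Distance is the minimum over a cluster's points to the reference placed
    at its mean detection slice.  Clusters smaller than ``min_size`` voxels
    are not candidates: coronary trees span thousands of voxels, whereas
    tiny residues of the filtered aortic rim can sit arbitrarily close to
    the reference and would otherwise win the proximity ranking.  The pair
    is returned as (left, right) coronary: in radiological display the
    patient's left coronary lies on the image-right side of the aorta, so
    the cluster with the larger mean column is "left".
    """
    clusters = [c for c in clusters if len(c) >= min_size]
    if len(clusters) < 2:
        raise CoronaryPairNotFoundError(
            f"coronary pair not found: {len(clusters)} cluster(s) of >= "
            f"{min_size} voxels available"
        )
    ref_pt = ref.as_index_point()
    ranked = sorted(clusters, key=lambda c: c.min_distance_to(ref_pt, scale))
    a, b = ranked[0], ranked[1]
    if a.mean_col() >= b.mean_col():
        left, right = a, b
    else:
        left, right = b, a
    return left, right


def clusters_to_mask(
    clusters: list[VoxelCluster], shape: tuple[int, int, int]
) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for c in clusters:
        idx = c.voxel_indices
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return out


def segment_coronary(
    vol: ImageVolume,
    filters: FilterParams | None = None,
    cluster: ClusterParams | None = None,
    ref: ReferencePoint | None = None,
    precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[BinaryVolume, BinaryVolume]:
    """Multi-threshold coronary segmentation.

    For every grey threshold in ``filters.grey_thresholds`` the candidate
    mask is clustered individually and the two aorta-adjacent clusters kept;
    per-threshold coronary voxels are then merged by union.  Returns
    ``(left_mask, right_mask)``.  Raises only if *every* threshold fails to
    produce a coronary pair.
    """
    from .aorta import detect_aorta_center

    filters = filters or FilterParams()
    cluster = cluster or ClusterParams()
    if ref is None:
        ref = detect_aorta_center(vol)
    den, ves = precomputed if precomputed is not None else preprocess_volume(vol, filters)

    left_union = np.zeros(vol.shape, dtype=bool)
    right_union = np.zeros(vol.shape, dtype=bool)
    n_ok = 0
    last_err: Exception | None = None
    for t in filters.grey_thresholds:
        cand = candidate_mask(den, ves, t, filters, vol.spacing, vol.origin)
        clusters, _ = cluster_voxels(cand, cluster)
        try:
            lc, rc = select_coronary_clusters(clusters, ref,
                                              min_size=cluster.min_coronary_size)
        except CoronaryPairNotFoundError as err:
            last_err = err
            continue
        left_union |= clusters_to_mask([lc], vol.shape)
        right_union |= clusters_to_mask([rc], vol.shape)
        n_ok += 1
    if n_ok == 0:
        raise CoronaryPairNotFoundError(
            f"coronary pair not found at any grey threshold: {last_err}"
        )
    return (
        BinaryVolume(left_union, vol.spacing, vol.origin),
        BinaryVolume(right_union, vol.spacing, vol.origin),
    )
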