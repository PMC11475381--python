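"""Ascending-aorta landmark detection via circular Hough transform.

On superior axial slices the ascending aorta is the one large bright disc
near the heart.  A Canny edge map feeds a circular Hough transform with a
radius window chosen so that only the aorta matches; the mean centre over a
small slice range becomes the spatial reference point used to pick the two
coronary clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .volume import ImageVolume


class AortaNotDetectedError(RuntimeError):
    """No acceptable Hough circle was found in the configured slice range."""


@dataclass
class ReferencePoint:
    """Mean aortic centre used as the reference for cluster identification.

    ``center`` is (row, col) in pixel coordinates of the (cropped) volume;
    ``slice_range`` the slice indices that contributed; ``radius`` the mean
    detected radius in pixels.
    """

    center: tuple[float, float]
    slice_range: tuple[int, int]
    radius: float
    per_slice: list[tuple[int, float, float, float]] | None = None  # (k, row, col, r)

    @property
    def mean_slice(self) -> float:
        lo, hi = self.slice_range
        return 0.5 * (lo + hi - 1)

    def as_index_point(self) -> np.ndarray:
        """(k, i, j) location of the reference in voxel-index space."""
        return np.array([self.mean_slice, self.center[0], self.center[1]])


def detect_aorta_center(
    vol: ImageVolume,
    slice_range: tuple[int, int] = (4, 9),
    r_min: int = 25,
    r_max: int = 60,
    canny_low: float = 50.0,
    canny_high: float = 150.0,
) -> ReferencePoint:
    """Locate the ascending aorta on superior slices.

    ``slice_range`` is a half-open ``(start, stop)`` index range into the
    volume; the default (4, 9) covers the fifth through ninth slices.  In
    each slice, Canny edges feed a circular Hough transform restricted to
    radii ``[r_min, r_max]`` pixels and the highest-accumulator circle is
    accepted.  The arithmetic mean of accepted centres is returned.
    """
    lo, hi = slice_range
    if vol.n_slices < hi:
        raise ValueError(f"volume has {vol.n_slices} slices; need at least {hi}")
    if not (0 < r_min < r_max):
        raise ValueError("require 0 < r_min < r_max")

    radii = np.arange(r_min, r_max + 1)
    accepted: list[tuple[int, float, float, float]] = []
    for k in range(lo, hi):
        sl = np.asarray(vol.voxels[k], dtype=float)
        edges = canny(sl, sigma=1.0, low_threshold=canny_low, high_threshold=canny_high)
        if not edges.any():
            continue
        h = hough_circle(edges, radii)
        accums, cx, cy, rad = hough_circle_peaks(h, radii, total_num_peaks=1)
        if len(accums) == 0 or accums[0] <= 0.2:
            continue
        accepted.append((k, float(cy[0]), float(cx[0]), float(rad[0])))
    if not accepted:
        raise AortaNotDetectedError(
            f"aorta not detected: no circle with radius in [{r_min}, {r_max}] px "
            f"found in slices {lo}..{hi - 1}"
        )
    rows = np.mean([a[1] for a in accepted])
    cols = np.mean([a[2] for a in accepted])
    rmean = np.mean([a[3] for a in accepted])
    return ReferencePoint(
        center=(float(rows), float(cols)),
        slice_range=(lo, hi),
        radius=float(rmean),
        per_slice=accepted,
    )
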