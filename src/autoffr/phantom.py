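"""Synthetic CT-like vessel phantoms and parametric 1D meshes.

Ground truth is emitted alongside every phantom so each pipeline stage can
be checked against known geometry: bright tubes with prescribed axis and
radius profile embedded in noisy background, a large bright cylinder
standing in for the ascending aorta, a distant decoy vessel mimicking a
pulmonary branch, and cosine-tapered stenosed 1D meshes for the solver.

Scan characteristics emulated: ~0.458 mm in-plane pixel spacing, 0.625 mm
slice spacing, coronary grey intensities in the thresholdable 125-145
range, additive Gaussian noise clipped to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial import cKDTree

from .mesh import Mesh1D, Vessel1D
from .volume import BinaryVolume, ImageVolume

DEFAULT_SHAPE = (48, 256, 256)  # (slices, rows, cols)
DEFAULT_SPACING = (0.458, 0.458, 0.625)  # (dx, dy, dz) mm


@dataclass
class TubeSpec:
    """One tubular segment: axis control points in (k, i, j) voxel coords,
    per-point radius in mm, and grey intensity (scalar, or (start, end)
    graded linearly along the axis)."""

    axis: np.ndarray  # (n, 3) float voxel coords
    radius_mm: np.ndarray  # (n,) mm
    intensity: float | tuple[float, float] = 140.0
    label: str = "tube"

    def __post_init__(self) -> None:
        self.axis = np.atleast_2d(np.asarray(self.axis, dtype=float))
        self.radius_mm = np.atleast_1d(np.asarray(self.radius_mm, dtype=float))
        if len(self.axis) < 2:
            raise ValueError("tube axis needs at least 2 points (zero-length axis)")
        if len(self.radius_mm) != len(self.axis):
            raise ValueError("radius profile must match axis points")


@dataclass
class AortaSpec:
    center: tuple[float, float] = (128.0, 128.0)  # (row, col)
    radius_px: float = 40.0
    intensity: float = 200.0
    slice_range: tuple[int, int] = (0, 22)


@dataclass
class PhantomSpec:
    """Full phantom description; fixed seed gives byte-identical output."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    tubes: list[TubeSpec] = field(default_factory=list)
    aorta: AortaSpec | None = None
    background: float = 60.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [self.background]
        for t in self.tubes:
            vals.extend(np.atleast_1d(t.intensity).tolist())
        if self.aorta is not None:
            vals.append(self.aorta.intensity)
        if any(not (0 <= v <= 255) for v in vals):
            raise ValueError("intensities must lie in [0, 255]")


def _vox_to_mm(pts: np.ndarray, spacing) -> np.ndarray:
    dx, dy, dz = spacing
    pts = np.atleast_2d(pts)
    return np.column_stack([pts[:, 0] * dz, pts[:, 1] * dy, pts[:, 2] * dx])


def _rasterize_tube(
    shape, spacing, tube: TubeSpec, step_mm: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Voxelise one tube; returns (mask, intensity_of_masked, axis_mm, r_mm).

    Voxels whose centre lies within the local radius of the densely
    resampled axis are set.  Raises if the tube (incl. radius) leaves the
    volume.
    """
    dx, dy, dz = spacing
    axis_mm = _vox_to_mm(tube.axis, spacing)  # columns (z, y, x) mm
    seg = np.linalg.norm(np.diff(axis_mm, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("zero-length axis")
    n_dense = max(int(np.ceil(s[-1] / step_mm)) + 1, 2)
    sd = np.linspace(0.0, s[-1], n_dense)
    dense = np.column_stack([PchipInterpolator(s, axis_mm[:, d])(sd) for d in range(3)])
    r_dense = PchipInterpolator(s, tube.radius_mm)(sd)
    inten = np.atleast_1d(np.asarray(tube.intensity, dtype=float))
    if inten.size == 2:
        i_dense = inten[0] + (inten[1] - inten[0]) * sd / sd[-1]
    else:
        i_dense = np.full(n_dense, float(inten[0]))

    rmax = float(r_dense.max())
    lo_mm = dense.min(axis=0) - rmax
    hi_mm = dense.max(axis=0) + rmax
    lo = np.floor(lo_mm / np.array([dz, dy, dx])).astype(int) - 1
    hi = np.ceil(hi_mm / np.array([dz, dy, dx])).astype(int) + 2
    if np.any(lo < 0) or np.any(hi > np.asarray(shape)):
        raise ValueError(f"tube '{tube.label}' exits the volume (bbox {lo}..{hi})")

    kk, ii, jj = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    centres = np.column_stack([kk.ravel() * dz, ii.ravel() * dy, jj.ravel() * dx])
    dist, idx = cKDTree(dense).query(centres)
    # small tolerance: the axis is sampled discretely, so a voxel centre
    # exactly on the continuous boundary may query a slightly oblique sample
    inside = dist <= r_dense[idx] + 2e-3
    mask = np.zeros(shape, dtype=bool)
    vals = np.zeros(shape, dtype=float)
    kin = kk.ravel()[inside]
    iin = ii.ravel()[inside]
    jin = jj.ravel()[inside]
    mask[kin, iin, jin] = True
    vals[kin, iin, jin] = i_dense[idx[inside]]
    return mask, vals, dense, r_dense


def make_tube_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, BinaryVolume, list[np.ndarray], list[np.ndarray], dict[str, np.ndarray]]:
    """Render a phantom volume from its spec.

    Returns ``(volume, truth_mask, axes_mm, radii_mm, label_masks)`` where
    ``axes_mm``/``radii_mm`` hold the densely-sampled true axis (z, y, x mm)
    and radius profile per tube and ``label_masks`` maps tube labels (and
    ``"aorta"``) to their individual truth masks.
    """
    if not spec.tubes and spec.aorta is None:
        raise ValueError("phantom spec contains no structures")
    vox = np.full(spec.shape, spec.background, dtype=float)
    truth = np.zeros(spec.shape, dtype=bool)
    labels: dict[str, np.ndarray] = {}
    axes, radii = [], []
    for tube in spec.tubes:
        mask, vals, dense, r_dense = _rasterize_tube(spec.shape, spec.spacing, tube)
        vox[mask] = vals[mask]
        truth |= mask
        labels[tube.label] = labels.get(tube.label, np.zeros(spec.shape, bool)) | mask
        axes.append(dense)
        radii.append(r_dense)
    if spec.aorta is not None:
        a = spec.aorta
        ii, jj = np.meshgrid(np.arange(spec.shape[1]), np.arange(spec.shape[2]), indexing="ij")
        disc = (ii - a.center[0]) ** 2 + (jj - a.center[1]) ** 2 <= a.radius_px**2
        amask = np.zeros(spec.shape, dtype=bool)
        lo, hi = a.slice_range
        amask[lo:hi] = disc
        vox[amask] = a.intensity
        labels["aorta"] = amask
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vox = vox + rng.normal(0.0, spec.noise_sigma, size=vox.shape)
    vox = np.clip(vox, 0.0, 255.0)
    vol = ImageVolume(vox, spec.spacing)
    return vol, BinaryVolume(truth, spec.spacing), axes, radii, labels


# ---------------------------------------------------------------------------
# standard phantoms
# ---------------------------------------------------------------------------

def stenosed_tube_spec(
    severity: float = 0.5,
    base_radius_vox: float = 4.0,
    shape: tuple[int, int, int] = (140, 64, 64),
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    noise_sigma: float = 0.0,
    intensity: float = 140.0,
    seed: int = 0,
) -> PhantomSpec:
    """A straight z-aligned tube with a cosine-tapered mid-length stenosis.

    Radius is ``base_radius_vox`` in-plane voxels, narrowing to
    ``(1 - severity)`` of that at mid-length over a taper of a third of the
    tube length.
    """
    if not (0 <= severity < 1):
        raise ValueError("severity must lie in [0, 1)")
    nz, ny, nx = shape
    dx = spacing[0]
    r0 = base_radius_vox * dx
    ks = np.linspace(4, nz - 5, 41)
    centre = 0.5 * (ks[0] + ks[-1])
    width = 0.33 * (ks[-1] - ks[0])
    u = (ks - centre) / (width / 2.0)
    dip = np.where(np.abs(u) < 1, 0.5 * (1 + np.cos(np.pi * u)), 0.0)
    r = r0 * (1.0 - severity * dip)
    axis = np.column_stack([ks, np.full_like(ks, ny / 2.0), np.full_like(ks, nx / 2.0)])
    tube = TubeSpec(axis, r, intensity, label="tube")
    return PhantomSpec(shape, spacing, [tube], None, 60.0, noise_sigma, seed)


def coronary_phantom_spec(
    noise_sigma: float = 5.0,
    stenosis_severity: float = 0.5,
    seed: int = 0,
    mirrored: bool = False,
) -> PhantomSpec:
    """The standard coronary phantom: aorta cylinder on the superior slices,
    two coronary trees (each with one bifurcation) sprouting next to it,
    and a distant decoy vessel in the pulmonary region.

    The left main branch carries a cosine stenosis of the given diameter
    severity; tree intensities fade from ~150 proximally to ~132 distally
    so the multi-threshold (125-145) union is exercised.
    """

    def tree(side: int) -> list[TubeSpec]:
        # side=+1: patient-left (image right); -1: patient-right (image left)
        c = 128.0
        main_axis = np.array(
            [
                [10, 128, c + side * 49],
                [13, 127 + side * 2, c + side * 58],
                [18, 130 + side * 4, c + side * 66],
                [28, 138 + side * 9, c + side * 71],
                [40, 146 + side * 13, c + side * 73],
            ],
            dtype=float,
        )
        n = len(main_axis)
        r_main = np.linspace(1.8, 1.1, n)
        if side > 0 and stenosis_severity > 0:
            # stenosis around the third control point of the left main
            dip = np.array([0.0, 0.25, 1.0, 0.25, 0.0]) * stenosis_severity
            r_main = r_main * (1.0 - dip)
        daughter_axis = np.array(
            [
                [18, 130 + side * 4, c + side * 66],
                [24, 118, c + side * 71],
                [32, 109, c + side * 74],
                [40, 104, c + side * 72],
            ],
            dtype=float,
        )
        r_d = np.linspace(1.3, 0.9, len(daughter_axis))
        name = "left" if side > 0 else "right"
        return [
            TubeSpec(main_axis, r_main, (150.0, 132.0), label=name),
            TubeSpec(daughter_axis, r_d, (145.0, 132.0), label=name),
        ]

    tubes = tree(+1) + tree(-1)
    decoy = TubeSpec(
        np.array([[8, 58, 110], [16, 60, 128], [26, 62, 146], [34, 64, 160]], dtype=float),
        np.full(4, 1.5),
        140.0,
        label="decoy",
    )
    tubes.append(decoy)
    if mirrored:
        shape = DEFAULT_SHAPE
        for t in tubes:
            t.axis[:, 2] = (shape[2] - 1) - t.axis[:, 2]
    spec = PhantomSpec(
        tubes=tubes,
        aorta=AortaSpec(),
        noise_sigma=noise_sigma,
        seed=seed,
    )
    _check_tree_collision(spec)
    return spec


def _check_tree_collision(spec: PhantomSpec) -> None:
    """Left and right trees must not touch (distinct DBSCAN clusters)."""
    by_label: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for t in spec.tubes:
        axis_mm = _vox_to_mm(t.axis, spec.spacing)
        by_label.setdefault(t.label, []).append((axis_mm, t.radius_mm))
    if "left" not in by_label or "right" not in by_label:
        return
    for la, lr in by_label["left"]:
        for ra, rr in by_label["right"]:
            d = np.linalg.norm(la[:, None, :] - ra[None, :, :], axis=2)
            clearance = d - (lr[:, None] + rr[None, :])
            if clearance.min() < 2.0:  # mm safety margin
                raise ValueError("geometry collision between coronary trees")


def make_coronary_phantom(
    spec: PhantomSpec | None = None, **kwargs
) -> tuple[ImageVolume, dict[str, np.ndarray]]:
    """Render the standard coronary phantom; returns (volume, label truth)."""
    spec = spec or coronary_phantom_spec(**kwargs)
    vol, _, _, _, labels = make_tube_phantom(spec)
    return vol, labels


# ---------------------------------------------------------------------------
# parametric 1D meshes for the solver
# ---------------------------------------------------------------------------

def make_stenosed_mesh1d(
    r0: float = 0.15,
    severity: float = 0.5,
    length: float = 10.0,
    spacing: float = 0.01,
    stenosis_length: float = 2.0,
    stenosis_center: float | None = None,
) -> tuple[Mesh1D, float, float]:
    """Single-vessel 1D mesh with a smooth cosine-tapered stenosis.

    Returns ``(mesh, r_min_true, x_min_true)``; the throat radius is
    ``r0 * (1 - severity)`` so the area ratio there is ``(1-severity)^2``.
    All lengths in cm.
    """
    if not (0 <= severity < 1):
        raise ValueError("severity must lie in [0, 1)")
    if length <= 0 or spacing <= 0:
        raise ValueError("length and spacing must be > 0")
    c = length / 2.0 if stenosis_center is None else stenosis_center
    n = int(round(length / spacing)) + 1
    x = np.linspace(0.0, length, n)
    u = (x - c) / (stenosis_length / 2.0)
    dip = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
    r = r0 * (1.0 - severity * dip)
    mesh = Mesh1D([Vessel1D(0, x, r, None, name="stenosed")], spacing)
    return mesh, r0 * (1.0 - severity), c


def make_bifurcation_mesh1d(
    r_parent: float = 0.2,
    r_daughters: tuple[float, float] = (0.15, 0.15),
    lengths: tuple[float, float, float] = (3.0, 3.0, 3.0),
    spacing: float = 0.02,
) -> Mesh1D:
    """Parent vessel splitting into two daughters (symmetric by default)."""
    vs = []
    n0 = int(round(lengths[0] / spacing)) + 1
    vs.append(Vessel1D(0, np.linspace(0, lengths[0], n0), np.full(n0, r_parent), None, "parent"))
    for k, (rd, ld) in enumerate(zip(r_daughters, lengths[1:]), start=1):
        nd = int(round(ld / spacing)) + 1
        vs.append(Vessel1D(k, np.linspace(0, ld, nd), np.full(nd, rd), 0, f"daughter{k}"))
    return Mesh1D(vs, spacing)
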