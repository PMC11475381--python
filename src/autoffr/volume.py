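"""Voxel volume container and I/O.

A CT scan is held as a 3D scalar array indexed ``voxels[k, i, j]`` where
``k`` runs along the patient's longitudinal axis (slice index), ``i`` is the
in-plane row and ``j`` the in-plane column.  Grey intensities are
window/level-normalised to the 0-255 range before any filtering, because all
segmentation thresholds in this package are expressed in 8-bit grey units.

World coordinates (mm) of voxel (k, i, j):

    x = origin[0] + j * dx,   y = origin[1] + i * dy,   z = origin[2] + k * dz
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


class EmptyCropError(ValueError):
    """Raised when a crop specification produces an empty volume."""


@dataclass
class ImageVolume:
    """3D grey-intensity volume with anisotropic voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar grey intensities (0-255 after normalisation).
    spacing : tuple of float
        ``(dx, dy, dz)`` voxel spacing in mm.
    origin : tuple of float
        World coordinate (mm) of voxel (0, 0, 0), as ``(x, y, z)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (0.458, 0.458, 0.625)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxel array must be 3D, got ndim={self.voxels.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def index_to_world(self, kij: np.ndarray) -> np.ndarray:
        """Map (k, i, j) voxel indices to (x, y, z) world mm."""
        kij = np.atleast_2d(np.asarray(kij, dtype=float))
        dx, dy, dz = self.spacing
        ox, oy, oz = self.origin
        out = np.empty_like(kij)
        out[:, 0] = ox + kij[:, 2] * dx
        out[:, 1] = oy + kij[:, 1] * dy
        out[:, 2] = oz + kij[:, 0] * dz
        return out


@dataclass
class BinaryVolume:
    """Boolean candidate mask aligned with a source :class:`ImageVolume`."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def indices(self) -> np.ndarray:
        """(n, 3) array of (k, i, j) indices of set voxels, in C scan order."""
        return np.argwhere(self.mask)


def crop_cardiac_region(
    vol: ImageVolume,
    crop_spec: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] = (
        (0.0, 1.0),
        (0.2, 0.8),
        (0.2, 0.8),
    ),
) -> ImageVolume:
    """Crop a volume to a fractional bounding box (focus on the cardiac region).

    ``crop_spec`` gives (lo, hi) fractions per axis in (slice, row, col)
    order; the default keeps all slices and the central 60% in-plane.  The
    origin is updated so retained voxels keep their world coordinates.
    """
    axes = "slice", "row", "col"
    slices = []
    starts = []
    for ax, (lo, hi) in enumerate(crop_spec):
        if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
            raise ValueError(f"crop fractions must lie in [0,1] on axis {axes[ax]}")
        n = vol.voxels.shape[ax]
        i0, i1 = int(np.floor(lo * n)), int(np.ceil(hi * n))
        if i1 <= i0:
            raise EmptyCropError(f"crop produces an empty volume on axis '{axes[ax]}'")
        slices.append(slice(i0, i1))
        starts.append(i0)
    sub = vol.voxels[tuple(slices)]
    dx, dy, dz = vol.spacing
    ox, oy, oz = vol.origin
    new_origin = (ox + starts[2] * dx, oy + starts[1] * dy, oz + starts[0] * dz)
    return ImageVolume(sub.copy(), vol.spacing, new_origin)


def normalize_window(raw: np.ndarray, center: float | None = None, width: float | None = None) -> np.ndarray:
    """Window/level-normalise raw intensities (e.g. Hounsfield) to 0-255.

    With no window given, the full data range is mapped linearly onto 0-255.
    """
    raw = np.asarray(raw, dtype=float)
    if center is None or width is None:
        lo, hi = float(raw.min()), float(raw.max())
        if hi == lo:
            return np.zeros_like(raw)
    else:
        lo, hi = center - width / 2.0, center + width / 2.0
    out = (raw - lo) / (hi - lo) * 255.0
    return np.clip(out, 0.0, 255.0)


# ----------------------------------------------------------------------------
# NIfTI round-trip (phantom interchange) and DICOM series I/O
# ----------------------------------------------------------------------------

def save_nifti(vol: ImageVolume, path: str) -> None:
    """Write a volume as NIfTI; array is stored (x, y, z) per NIfTI convention."""
    import nibabel as nib

    dx, dy, dz = vol.spacing
    affine = np.diag([dx, dy, dz, 1.0]).astype(float)
    affine[:3, 3] = vol.origin
    data = np.ascontiguousarray(np.transpose(vol.voxels, (2, 1, 0)))
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), path)


def load_nifti(path: str) -> ImageVolume:
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(np.transpose(data, (2, 1, 0)).copy(), tuple(float(z) for z in zooms), origin)


def save_dicom_series(vol: ImageVolume, outdir: str, series_uid: str | None = None) -> list[str]:
    """Write each slice as a minimal secondary-capture DICOM file.

    Only the tags the reader needs (pixel spacing, slice positions, geometry)
    are populated; intensities are stored as uint16 with identity rescale.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    os.makedirs(outdir, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    dx, dy, dz = vol.spacing
    paths = []
    for k in range(vol.n_slices):
        sl = np.clip(vol.voxels[k], 0, 65535).astype(np.uint16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = sl.shape
        ds.PixelSpacing = [f"{dy:.6f}", f"{dx:.6f}"]  # row spacing, col spacing
        ds.SliceThickness = f"{dz:.6f}"
        ds.SpacingBetweenSlices = f"{dz:.6f}"
        ox, oy, oz = vol.origin
        ds.ImagePositionPatient = [f"{ox:.6f}", f"{oy:.6f}", f"{oz + k * dz:.6f}"]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleIntercept = "0"
        ds.RescaleSlope = "1"
        ds.PixelData = sl.tobytes()
        path = os.path.join(outdir, f"slice_{k:04d}.dcm")
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_dicom_series(
    dirpath: str,
    window_center: float | None = None,
    window_width: float | None = None,
) -> ImageVolume:
    """Read a DICOM series directory into a normalised :class:`ImageVolume`.

    Slices are sorted by their z position (falling back to instance number);
    spacing comes from the headers and intensities are window-normalised to
    0-255.  Inconsistent slice spacing (>5%) or missing spacing tags raise
    ``ValueError``.
    """
    import pydicom

    files = sorted(
        os.path.join(dirpath, f)
        for f in os.listdir(dirpath)
        if not f.startswith(".") and os.path.isfile(os.path.join(dirpath, f))
    )
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM slices in {dirpath!r}")

    def zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=zpos)
    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError("missing PixelSpacing tag")
    dy, dx = (float(v) for v in first.PixelSpacing)
    zs = np.array([zpos(ds) for ds in datasets])
    if len(datasets) > 1:
        dzs = np.diff(zs)
        dz = float(np.median(dzs))
        if dz <= 0:
            raise ValueError("non-increasing slice positions")
        if np.any(np.abs(dzs - dz) > 0.05 * dz):
            raise ValueError("inconsistent slice spacing beyond 5%")
    else:
        dz = float(getattr(first, "SpacingBetweenSlices", getattr(first, "SliceThickness", 0)) or 0)
        if dz <= 0:
            raise ValueError("missing slice spacing tags")
    slope = float(getattr(first, "RescaleSlope", 1) or 1)
    intercept = float(getattr(first, "RescaleIntercept", 0) or 0)
    stack = np.stack([ds.pixel_array.astype(float) * slope + intercept for ds in datasets])
    vox = normalize_window(stack, window_center, window_width)
    if hasattr(first, "ImagePositionPatient"):
        ox, oy = float(first.ImagePositionPatient[0]), float(first.ImagePositionPatient[1])
        oz = float(zs[0])
    else:
        ox = oy = oz = 0.0
    return ImageVolume(vox, (dx, dy, dz), (ox, oy, oz))
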