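"""Core grid containers and I/O.

A :class:`Volume` is a 3-D scalar grid in Hounsfield Units (or any scalar
field) indexed ``[k, j, i]`` = (slice, row, column), with per-axis voxel
spacing in mm and a world-space origin at the center of voxel ``(0, 0, 0)``.
World coordinates of voxel ``(k, j, i)`` are ``origin + index * spacing``.

Structure masks are simply boolean Volumes; :class:`DoseGrid` carries dose in
Gy on its own grid plus the reference prescription.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import GridMismatchError

__all__ = [
    "Volume",
    "DoseGrid",
    "StructureMask",
    "read_nifti",
    "write_nifti",
    "read_dicom_series",
    "read_rt_dose",
]


@dataclass
class Volume:
    """3-D scalar grid with spacing (mm) and origin (mm) metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GridMismatchError(f"expected 3-D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GridMismatchError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "Volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.shape}/{self.spacing} vs {other.shape}/{other.spacing}"
            )

    def world_coordinates(self):
        """Per-axis world coordinates (mm) of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=np.asarray(data))

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())


#: Boolean Volume used as a binary structure mask.
StructureMask = Volume


@dataclass
class DoseGrid:
    """3-D dose in Gy on its own grid, with the reference prescription."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    prescription_gy: float = 60.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GridMismatchError(f"expected 3-D dose, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("dose values must be nonnegative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GridMismatchError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def as_volume(self) -> Volume:
        return Volume(self.values, self.spacing, self.origin)

    def world_coordinates(self):
        return self.as_volume().world_coordinates()


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_nifti(vol: Volume, path: str | Path) -> Path:
    """Write a Volume to NIfTI.

    Data are stored in (x, y, z) = (column, row, slice) order with a diagonal
    affine built from the voxel spacing, so a round trip through
    :func:`read_nifti` is exact. Boolean masks are stored as uint8.
    """
    import nibabel as nib

    path = Path(path)
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    # internal (k, j, i) -> NIfTI (i, j, k)
    arr = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    sp = vol.spacing
    affine = np.diag([sp[2], sp[1], sp[0], 1.0])
    affine[:3, 3] = [vol.origin[2], vol.origin[1], vol.origin[0]]
    nib.save(nib.Nifti1Image(arr, affine), str(path))
    return path


def read_nifti(path: str | Path, as_mask: bool = False) -> Volume:
    """Read a NIfTI file written by :func:`write_nifti` (or any axis-aligned one)."""
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise GridMismatchError(f"expected 3-D NIfTI, got shape {arr.shape}")
    data = np.transpose(arr, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(x) for x in img.affine[:3, 3][::-1])
    if as_mask:
        data = data > 0.5
    return Volume(np.ascontiguousarray(data), spacing, origin)


# ---------------------------------------------------------------------------
# DICOM I/O (axis-aligned geometry; orientation matrices are not interpreted)
# ---------------------------------------------------------------------------

def read_dicom_series(directory: str | Path) -> Volume:
    """Read an axial CT series (one file per slice) into a Volume in HU."""
    import pydicom

    directory = Path(directory)
    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file()
    )
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    first = slices[0]
    rows = np.stack(
        [
            d.pixel_array * float(getattr(d, "RescaleSlope", 1.0))
            + float(getattr(d, "RescaleIntercept", 0.0))
            for d in slices
        ]
    )
    dy, dx = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1:
        dz = float(slices[1].ImagePositionPatient[2]) - float(first.ImagePositionPatient[2])
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    origin = (
        float(first.ImagePositionPatient[2]),
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[0]),
    )
    return Volume(rows.astype(np.float32), (abs(dz), dy, dx), origin)


def rasterize_contours(
    contours_mm: dict[str, list[np.ndarray]], grid: Volume
) -> dict[str, StructureMask]:
    """Rasterize planar contours into binary masks on ``grid``.

    ``contours_mm`` maps structure name to a list of closed polygons, each an
    (N, 3) array of world-space (z, y, x) points in mm; every polygon must lie
    in a single axial (constant-z) plane, as DICOM-RT contours do. Polygons
    are filled per slice; multiple polygons on one slice XOR, so holes and
    islands follow the even-odd rule.
    """
    from skimage.draw import polygon as draw_polygon

    nz, ny, nx = grid.shape
    out = {}
    for name, polys in contours_mm.items():
        mask = np.zeros(grid.shape, dtype=bool)
        for pts in polys:
            pts = np.asarray(pts, dtype=float)
            idx = (pts - np.asarray(grid.origin)) / np.asarray(grid.spacing)
            k = int(round(idx[0, 0]))
            if not 0 <= k < nz:
                continue
            rr, cc = draw_polygon(idx[:, 1], idx[:, 2], shape=(ny, nx))
            mask[k, rr, cc] ^= True
        out[name] = Volume(mask, grid.spacing, grid.origin)
    return out


def read_rt_struct(path: str | Path, grid: Volume) -> dict[str, StructureMask]:
    """Read a DICOM-RT Structure Set and rasterize its ROIs onto ``grid``.

    DICOM contour points are (x, y, z) in mm; they are reordered to this
    package's (z, y, x) convention before rasterization.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    contours: dict[str, list[np.ndarray]] = {}
    for roi in ds.ROIContourSequence:
        name = names.get(int(roi.ReferencedROINumber), str(roi.ReferencedROINumber))
        polys = []
        for contour in getattr(roi, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            polys.append(pts[:, ::-1])  # (x, y, z) -> (z, y, x)
        contours[name] = polys
    return rasterize_contours(contours, grid)


def read_rt_dose(path: str | Path, prescription_gy: float = 60.0) -> DoseGrid:
    """Read a DICOM-RT Dose file into a DoseGrid in Gy."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(float) * scaling
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = [float(v) for v in ds.GridFrameOffsetVector]
    dz = abs(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    origin = (
        float(ds.ImagePositionPatient[2]),
        float(ds.ImagePositionPatient[1]),
        float(ds.ImagePositionPatient[0]),
    )
    return DoseGrid(values, (dz, dy, dx), origin, prescription_gy=prescription_gy)
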