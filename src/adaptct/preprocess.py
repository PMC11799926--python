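"""Data preparation: HU clipping, invertible Z-score normalization, body-mask
delineation, rigid registration and 2.5-D slice stacking.

Normalization statistics are estimated once over a training cohort's clipped
body voxels and then frozen, so model outputs can always be mapped back to
the HU scale by the exact inverse affine transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .errors import DegenerateInputError, GridMismatchError, RegistrationError
from .volume import StructureMask, Volume

__all__ = [
    "NormStats",
    "RigidTransform",
    "SliceStack",
    "clip_hu",
    "zscore",
    "inverse_zscore",
    "estimate_norm_stats",
    "body_mask",
    "rigid_register",
    "resample_rigid",
    "stack_adjacent_slices",
]

HU_AIR = -1000.0

#: body delineation threshold (HU) and morphology radius (voxels)
BODY_THRESHOLD_HU = -300.0
BODY_CLOSING_RADIUS = 2


@dataclass
class NormStats:
    """Frozen affine normalization: clip to [clip_lo, clip_hi], then (v - mean)/sd."""

    mean: float
    sd: float
    clip_lo: float = -1000.0
    clip_hi: float = 3000.0

    def __post_init__(self):
        if self.sd <= 0:
            raise DegenerateInputError(f"sd must be > 0, got {self.sd}")
        if self.clip_lo >= self.clip_hi:
            raise DegenerateInputError("clip_lo must be < clip_hi")


def clip_hu(v: Volume, stats: NormStats) -> Volume:
    """Clamp intensities to the calibration range; in-range voxels unchanged."""
    return v.with_data(np.clip(v.data, stats.clip_lo, stats.clip_hi))


def zscore(v: Volume, stats: NormStats) -> Volume:
    """Clip, then map to zero-mean/unit-sd units under the frozen statistics.

    Computation is float64; the result keeps the input's float precision
    (at least float32), so a float64 round trip is exact to rounding.
    """
    dtype = np.float64 if v.data.dtype == np.float64 else np.float32
    clipped = np.clip(np.asarray(v.data, dtype=np.float64), stats.clip_lo, stats.clip_hi)
    return v.with_data(((clipped - stats.mean) / stats.sd).astype(dtype))


def inverse_zscore(v: Volume, stats: NormStats) -> Volume:
    """Exact inverse of :func:`zscore` (returns the clipped HU volume)."""
    dtype = np.float64 if v.data.dtype == np.float64 else np.float32
    return v.with_data(
        (np.asarray(v.data, dtype=np.float64) * stats.sd + stats.mean).astype(dtype)
    )


def estimate_norm_stats(
    volumes: list[Volume],
    masks: list[StructureMask] | None = None,
    clip_lo: float = -1000.0,
    clip_hi: float = 3000.0,
) -> NormStats:
    """Pool clipped (optionally body-masked) voxels over a cohort and freeze
    their mean/sd. A constant cohort has no usable scale and is rejected."""
    chunks = []
    for i, v in enumerate(volumes):
        data = np.clip(np.asarray(v.data, dtype=np.float64), clip_lo, clip_hi)
        if masks is not None:
            data = data[masks[i].data.astype(bool)]
        chunks.append(data.ravel())
    pooled = np.concatenate(chunks)
    if pooled.size == 0:
        raise DegenerateInputError("no voxels to estimate normalization statistics from")
    sd = float(pooled.std())
    if sd == 0.0:
        raise DegenerateInputError("constant volume: sd is zero, cannot normalize")
    return NormStats(mean=float(pooled.mean()), sd=sd, clip_lo=clip_lo, clip_hi=clip_hi)


# ---------------------------------------------------------------------------
# body delineation
# ---------------------------------------------------------------------------

def body_mask(v: Volume) -> StructureMask:
    """Delineate the patient outline: threshold above air, keep the largest
    connected component, close small gaps and fill interior holes (including
    the lungs, which belong to the body)."""
    fg = v.data > BODY_THRESHOLD_HU
    if not np.any(fg):
        raise DegenerateInputError("all-air volume: no body to delineate")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    struct = ndimage.generate_binary_structure(3, 1)
    struct = ndimage.iterate_structure(struct, BODY_CLOSING_RADIUS)
    # edge-pad before morphology: the patient extends beyond the scanned
    # z-range, and closing with a zero border would erode the end slices
    r = BODY_CLOSING_RADIUS
    fg = np.pad(fg, r, mode="edge")
    fg = ndimage.binary_closing(fg, structure=struct)
    fg = ndimage.binary_fill_holes(fg)
    fg = fg[r:-r, r:-r, r:-r]
    # per-slice fill handles tubular cavities open at the volume ends
    for k in range(fg.shape[0]):
        fg[k] = ndimage.binary_fill_holes(fg[k])
    if not np.any(fg):
        raise DegenerateInputError("body delineation produced an empty mask")
    return Volume(fg, v.spacing, v.origin)


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Rigid map from moving to fixed space: p_fixed = R (p - c) + c + t.

    Rotations are small Euler angles in degrees about the (z, y, x) axes
    applied in that order; ``center_mm`` is the rotation center.
    """

    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        az, ay, ax = np.deg2rad(self.rotation_deg)
        cz, sz = np.cos(az), np.sin(az)
        cy, sy = np.cos(ay), np.sin(ay)
        cx, sx = np.cos(ax), np.sin(ax)
        # rotations about the z (slice), y (row) and x (column) axes of (z,y,x) space
        rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
        ry = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
        rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center_mm, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        return (np.asarray(points_mm, dtype=float) - c) @ self._rot().T + c + t

    def inverse(self) -> "RigidTransform":
        r = self.matrix()
        c = np.asarray(self.center_mm, dtype=float)
        t = np.asarray(self.translation_mm, dtype=float)
        # inverse map: p -> R^T (p - c - t) + c ; expressed in the same form
        angles = -np.asarray(self.rotation_deg, dtype=float)[::-1]
        inv = RigidTransform(tuple((-r.T @ t).tolist()), (0.0, 0.0, 0.0), tuple(c.tolist()))
        # exact inverse rotation is R^T; for the Euler form we store the matrix directly
        inv._matrix_override = r.T
        return inv

    _matrix_override: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.translation_mm = tuple(float(x) for x in self.translation_mm)
        self.rotation_deg = tuple(float(x) for x in self.rotation_deg)
        self.center_mm = tuple(float(x) for x in self.center_mm)

    def _rot(self) -> np.ndarray:
        return self._matrix_override if self._matrix_override is not None else self.matrix()


def _world_to_index(vol: Volume, points_mm: np.ndarray) -> np.ndarray:
    return (points_mm - np.asarray(vol.origin)) / np.asarray(vol.spacing)


def resample_rigid(
    moving: Volume,
    transform: RigidTransform,
    target: Volume,
    fill_value: float = HU_AIR,
    order: int = 1,
) -> Volume:
    """Resample ``moving`` onto ``target``'s grid under ``transform`` (moving→fixed),
    with trilinear interpolation and ``fill_value`` outside the source FOV."""
    zz, yy, xx = np.meshgrid(*target.world_coordinates(), indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    c = np.asarray(transform.center_mm)
    t = np.asarray(transform.translation_mm)
    src_pts = (pts - c - t) @ transform._rot() + c
    idx = _world_to_index(moving, src_pts).T
    vals = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=np.float64),
        idx,
        order=order,
        mode="constant",
        cval=fill_value,
    )
    return Volume(
        vals.reshape(target.shape).astype(np.float32), target.spacing, target.origin
    )


def _mse_at(moving: Volume, fixed: Volume, params: np.ndarray, center) -> float:
    t = RigidTransform(tuple(params[:3]), tuple(params[3:6]), center)
    res = resample_rigid(moving, t, fixed)
    return float(np.mean((res.data - fixed.data) ** 2))


def rigid_register(
    moving: Volume,
    fixed: Volume,
    estimate_rotation: bool = False,
    upsample_factor: int = 20,
) -> tuple[RigidTransform, Volume]:
    """Rigidly align ``moving`` to ``fixed``.

    Translation is recovered by subvoxel phase correlation; when
    ``estimate_rotation`` is set, translation and small Euler angles are then
    refined jointly by local (Powell) minimization of the mean-squared
    intensity difference.
    """
    if moving.shape != fixed.shape:
        raise GridMismatchError("rigid_register expects volumes on a common grid shape")
    shift, err, _ = phase_cross_correlation(
        np.asarray(fixed.data, dtype=np.float64),
        np.asarray(moving.data, dtype=np.float64),
        upsample_factor=upsample_factor,
        normalization=None,
    )
    if not np.all(np.isfinite(shift)):
        raise RegistrationError("phase correlation failed (non-finite shift)")
    translation = tuple(float(s * sp) for s, sp in zip(shift, fixed.spacing))
    center = tuple(
        fixed.origin[a] + (fixed.shape[a] - 1) / 2.0 * fixed.spacing[a] for a in range(3)
    )
    transform = RigidTransform(translation, (0.0, 0.0, 0.0), center)
    if estimate_rotation:
        from scipy.optimize import minimize

        x0 = np.array(list(translation) + [0.0, 0.0, 0.0])
        res = minimize(
            lambda p: _mse_at(moving, fixed, p, center),
            x0,
            method="Powell",
            options={"maxiter": 40, "xtol": 1e-3},
        )
        transform = RigidTransform(tuple(res.x[:3]), tuple(res.x[3:6]), center)
    resampled = resample_rigid(moving, transform, fixed)
    return transform, resampled


# ---------------------------------------------------------------------------
# 2.5-D slice stacking
# ---------------------------------------------------------------------------

@dataclass
class SliceStack:
    """Three adjacent in-plane slices (k-1, k, k+1); edges replicate."""

    channels: np.ndarray  # (3, H, W)
    center_index: int


def stack_adjacent_slices(v: Volume, k: int) -> SliceStack:
    """Build the 3-channel 2.5-D input for slice ``k`` with edge replication."""
    n = v.shape[0]
    if not 0 <= k < n:
        raise IndexError(f"slice index {k} out of range [0, {n})")
    lo, hi = max(k - 1, 0), min(k + 1, n - 1)
    channels = np.stack([v.data[lo], v.data[k], v.data[hi]]).astype(np.float32)
    return SliceStack(channels=channels, center_index=k)
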