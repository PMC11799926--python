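"""3-D gamma-index dose comparison.

For every reference voxel whose dose is at or above the low-dose threshold
(default 10% of the reference maximum), the gamma index is

    γ(p) = min over displacements r, |r| <= R, of
           sqrt( (D_eval(p + r) - D_ref(p))² / ΔD²  +  |r|² / DTA² )

with ΔD = DT% of the global reference maximum (global normalization; a
local-normalization mode uses DT% of the local reference dose). The
evaluated dose is trilinearly interpolated on a displacement lattice of
step ``interp_step_mm``. Voxels below the threshold are excluded from both
the numerator and the denominator of the pass rate. The search is
restricted to a sphere of radius ``search_radius_mm`` (default 3·DTA):
any displacement beyond it contributes at least |r|/DTA = 3 to γ, which
cannot change pass/fail at γ <= 1 (and the γ value itself is only resolved
up to the lattice step far above 1).

``gamma_map`` is the production implementation (sorted displacements with
early termination); ``gamma_brute_force`` is an independent exhaustive
oracle with its own trilinear interpolation, used for validation on small
grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateInputError, GridMismatchError
from .volume import DoseGrid

__all__ = [
    "GammaParams",
    "GammaResult",
    "gamma_map",
    "gamma_brute_force",
    "resample_dose_grid",
    "pass_rate_report",
]


@dataclass
class GammaParams:
    """DT/DTA criteria and search controls; defaults are 3%/3 mm, 10% threshold."""

    dose_tolerance_pct: float = 3.0
    dta_mm: float = 3.0
    low_dose_threshold_pct: float = 10.0
    normalization: str = "global"  # "global" | "local"
    search_radius_mm: float | None = None  # default 3 * dta_mm
    interp_step_mm: float | None = None    # default dta_mm / 10

    def __post_init__(self):
        if min(self.dose_tolerance_pct, self.dta_mm, self.low_dose_threshold_pct) <= 0:
            raise ValueError("DT, DTA and threshold must be > 0")
        if self.normalization not in ("global", "local"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.search_radius_mm is None:
            self.search_radius_mm = 3.0 * self.dta_mm
        if self.interp_step_mm is None:
            self.interp_step_mm = self.dta_mm / 10.0
        if self.interp_step_mm > self.dta_mm:
            raise ValueError("interp_step_mm must be <= dta_mm")


@dataclass
class GammaResult:
    """Per-voxel γ over evaluated voxels (NaN elsewhere) and the pass rate."""

    gamma_map: np.ndarray
    pass_rate_pct: float
    n_evaluated: int


def _displacement_lattice(params: GammaParams) -> tuple[np.ndarray, np.ndarray]:
    """All displacements (mm) on the interp_step lattice within the search sphere,
    plus their squared DTA penalties."""
    step = params.interp_step_mm
    r = params.search_radius_mm
    n = int(np.floor(r / step))
    axis = np.arange(-n, n + 1) * step
    zz, yy, xx = np.meshgrid(axis, axis, axis, indexing="ij")
    disp = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    d2 = np.einsum("ij,ij->i", disp, disp)
    keep = d2 <= r**2 + 1e-9
    return disp[keep], d2[keep] / params.dta_mm**2


def _check_inputs(reference: DoseGrid, evaluated: DoseGrid, params: GammaParams):
    ref_max = float(reference.values.max())
    if ref_max <= 0:
        raise DegenerateInputError("reference dose is identically zero")
    threshold = params.low_dose_threshold_pct / 100.0 * ref_max
    eval_mask = reference.values >= threshold
    if not eval_mask.any():
        raise DegenerateInputError("no reference voxel above the low-dose threshold")
    return ref_max, eval_mask


def _ref_points_mm(reference: DoseGrid, eval_mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(eval_mask).astype(float)
    return idx * np.asarray(reference.spacing) + np.asarray(reference.origin)


def _result(reference, eval_mask, gamma_vals) -> GammaResult:
    gmap = np.full(reference.shape, np.nan)
    gmap[eval_mask] = gamma_vals
    n = int(eval_mask.sum())
    return GammaResult(gmap, float(np.mean(gamma_vals <= 1.0) * 100.0), n)


def gamma_map(reference: DoseGrid, evaluated: DoseGrid, p: GammaParams | None = None) -> GammaResult:
    """Gamma index of ``evaluated`` against ``reference`` (the asymmetric
    convention: reference plays the measurement role).

    Deterministic; uses sorted displacements with early termination, which is
    exact: once every remaining displacement's DTA penalty alone exceeds the
    current best γ², no later candidate can improve the minimum.
    """
    p = p if p is not None else GammaParams()
    ref_max, eval_mask = _check_inputs(reference, evaluated, p)
    disp, dta_pen = _displacement_lattice(p)
    order = np.argsort(dta_pen, kind="stable")
    disp, dta_pen = disp[order], dta_pen[order]

    if p.normalization == "global":
        denom = (p.dose_tolerance_pct / 100.0 * ref_max) ** 2
    else:
        denom = (p.dose_tolerance_pct / 100.0 * reference.values[eval_mask]) ** 2

    pts = _ref_points_mm(reference, eval_mask)
    ref_doses = reference.values[eval_mask]
    spacing = np.asarray(evaluated.spacing)
    origin = np.asarray(evaluated.origin)
    upper = np.asarray(evaluated.shape, dtype=float) - 1.0

    best = np.full(len(pts), np.inf)
    active = np.arange(len(pts))
    ev = np.asarray(evaluated.values, dtype=np.float64)
    chunk = 512  # displacements per interpolation call, keeps memory bounded
    i = 0
    while i < len(disp) and len(active):
        d_block = disp[i : i + chunk]
        pen_block = dta_pen[i : i + chunk]
        # world -> fractional index for every (active point, displacement)
        coords = (pts[active][:, None, :] + d_block[None, :, :] - origin) / spacing
        inside = np.all((coords >= 0.0) & (coords <= upper), axis=2)
        vals = ndimage.map_coordinates(
            ev, coords.reshape(-1, 3).T, order=1, mode="nearest"
        ).reshape(len(active), len(d_block))
        dd2 = (vals - ref_doses[active][:, None]) ** 2
        dnm = denom if np.isscalar(denom) or np.ndim(denom) == 0 else denom[active][:, None]
        g2 = dd2 / dnm + pen_block[None, :]
        g2[~inside] = np.inf
        best[active] = np.minimum(best[active], g2.min(axis=1))
        i += chunk
        if i < len(disp):
            active = active[best[active] > dta_pen[i]]
    return _result(reference, eval_mask, np.sqrt(best))


def _trilinear(ev: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Manual trilinear interpolation at fractional (z, y, x) indices.

    Independent of scipy's resampler on purpose: this is the oracle's own
    interpolation. Coordinates must lie inside the grid.
    """
    shape = np.asarray(ev.shape)
    c0 = np.floor(coords).astype(int)
    c0 = np.minimum(np.maximum(c0, 0), shape - 2) if (shape >= 2).all() else np.zeros_like(c0)
    frac = coords - c0
    out = np.zeros(len(coords))
    for dz in (0, 1):
        wz = frac[:, 0] if dz else 1 - frac[:, 0]
        for dy in (0, 1):
            wy = frac[:, 1] if dy else 1 - frac[:, 1]
            for dx in (0, 1):
                wx = frac[:, 2] if dx else 1 - frac[:, 2]
                out += (
                    wz * wy * wx
                    * ev[c0[:, 0] + dz, np.minimum(c0[:, 1] + dy, shape[1] - 1),
                         np.minimum(c0[:, 2] + dx, shape[2] - 1)]
                )
    return out


def gamma_brute_force(
    reference: DoseGrid, evaluated: DoseGrid, p: GammaParams | None = None
) -> GammaResult:
    """Exhaustive gamma over the full displacement lattice (validation oracle).

    Refuses grids larger than 32³ as a guard rail.
    """
    p = p if p is not None else GammaParams()
    if max(reference.shape) > 32 or max(evaluated.shape) > 32:
        raise ValueError("gamma_brute_force guard rail: grids must be <= 32 per axis")
    ref_max, eval_mask = _check_inputs(reference, evaluated, p)
    disp, dta_pen = _displacement_lattice(p)
    if p.normalization == "global":
        denom = np.full(int(eval_mask.sum()), (p.dose_tolerance_pct / 100.0 * ref_max) ** 2)
    else:
        denom = (p.dose_tolerance_pct / 100.0 * reference.values[eval_mask]) ** 2
    pts = _ref_points_mm(reference, eval_mask)
    ref_doses = reference.values[eval_mask]
    spacing = np.asarray(evaluated.spacing)
    origin = np.asarray(evaluated.origin)
    upper = np.asarray(evaluated.shape, dtype=float) - 1.0
    ev = np.asarray(evaluated.values, dtype=np.float64)

    best = np.full(len(pts), np.inf)
    for d, pen in zip(disp, dta_pen):
        coords = (pts + d - origin) / spacing
        inside = np.all((coords >= 0.0) & (coords <= upper), axis=1)
        if not inside.any():
            continue
        vals = _trilinear(ev, coords[inside])
        g2 = (vals - ref_doses[inside]) ** 2 / denom[inside] + pen
        best[inside] = np.minimum(best[inside], g2)
    return _result(reference, eval_mask, np.sqrt(best))


def resample_dose_grid(dose: DoseGrid, new_spacing_mm) -> DoseGrid:
    """Trilinearly resample a dose grid to a new voxel spacing over the same
    physical extent; a constant dose resamples exactly."""
    if np.isscalar(new_spacing_mm):
        new_spacing = (float(new_spacing_mm),) * 3
    else:
        new_spacing = tuple(float(s) for s in new_spacing_mm)
    if any(s <= 0 for s in new_spacing):
        raise ValueError("spacing must be positive")
    extent = [(n - 1) * s for n, s in zip(dose.shape, dose.spacing)]
    new_shape = tuple(int(np.floor(e / s)) + 1 for e, s in zip(extent, new_spacing))
    axes = [
        (np.arange(n) * s) / old_s
        for n, s, old_s in zip(new_shape, new_spacing, dose.spacing)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    vals = ndimage.map_coordinates(
        np.asarray(dose.values, dtype=np.float64),
        np.stack([zz.ravel(), yy.ravel(), xx.ravel()]),
        order=1,
        mode="nearest",
    ).reshape(new_shape)
    return DoseGrid(np.clip(vals, 0.0, None), new_spacing, dose.origin, dose.prescription_gy)


def pass_rate_report(results: list[GammaResult], labels: list | None = None) -> pd.DataFrame:
    """Mean ± sd pass rate per label (e.g. per dose-grid spacing)."""
    if not results:
        raise DegenerateInputError("no gamma results to report")
    labels = labels if labels is not None else ["all"] * len(results)
    df = pd.DataFrame(
        {"label": labels, "pass_rate_pct": [r.pass_rate_pct for r in results],
         "n_evaluated": [r.n_evaluated for r in results]}
    )
    out = (
        df.groupby("label", sort=False)
        .agg(
            mean_pass_rate_pct=("pass_rate_pct", "mean"),
            sd_pass_rate_pct=("pass_rate_pct", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            n_plans=("pass_rate_pct", "size"),
        )
        .reset_index()
    )
    return out
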