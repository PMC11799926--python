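"""Dosimetric evaluation: DVH curves, conformity/homogeneity/gradient
indices, organ-at-risk dose-volume parameters and rigid dose overlay.

Conventions: a voxel belongs to a structure iff its center is inside the
binary mask (no partial-volume weighting); cumulative DVHs are built by
exact voxel counting at a fixed bin resolution (0.05 Gy default); Dx%
queries are answered as step quantiles on that exactly-counted curve, so
a uniform dose yields Dx% equal to that dose at every x.

The conformity index is the Paddick form

    CI = V_GTV,ref² / (V_GTV · V_ref)        (bounded in [0, 1]);

the ratio form V_ref / V_GTV, which can exceed 1, is available behind
``form="ratio"``. HI = (D2% − D98%)/D50% and GI = V50%/V100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, GridMismatchError
from .preprocess import RigidTransform
from .volume import DoseGrid, StructureMask, Volume

__all__ = [
    "DVHCurve",
    "DoseIndices",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "homogeneity_index",
    "conformity_index",
    "gradient_index",
    "oar_metrics",
    "overlay_dose",
]

DEFAULT_BIN_GY = 0.05


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    dose_bins: np.ndarray      # ascending Gy, bin edges
    cum_volume: np.ndarray     # fraction of structure receiving >= bin dose
    volume_cm3: float
    structure_doses: np.ndarray  # sorted voxel doses, kept for exact queries

    def d_mean(self) -> float:
        return float(self.structure_doses.mean())

    def d_max(self) -> float:
        return float(self.structure_doses.max())


def _mask_array(s) -> np.ndarray:
    return np.asarray(s.data if isinstance(s, Volume) else s, dtype=bool)


def compute_dvh(dose: DoseGrid, s: StructureMask, bin_gy: float = DEFAULT_BIN_GY) -> DVHCurve:
    """Exact-counting cumulative DVH at resolution ``bin_gy``."""
    m = _mask_array(s)
    if m.shape != dose.shape:
        raise GridMismatchError("dose and structure mask must share a grid")
    if not m.any():
        raise DegenerateInputError("empty structure mask")
    doses = np.sort(dose.values[m].ravel())
    n = doses.size
    top = doses[-1]
    edges = np.arange(0.0, top + 2 * bin_gy, bin_gy)
    # fraction receiving >= edge, counted exactly on the sorted doses
    cum = 1.0 - np.searchsorted(doses, edges, side="left") / n
    volume_cm3 = n * dose.voxel_volume_mm3 / 1000.0
    return DVHCurve(edges, cum, volume_cm3, doses)


def dose_at_volume(dvh: DVHCurve, q: float) -> float:
    """Dx%: the largest dose received by at least q% of the structure volume."""
    if not 0.0 < q < 100.0:
        raise ValueError(f"q must be in (0, 100), got {q}")
    ok = dvh.cum_volume >= q / 100.0
    if not ok.any():
        return float(dvh.dose_bins[0])
    return float(dvh.dose_bins[np.nonzero(ok)[0][-1]])


def volume_at_dose(dvh: DVHCurve, dose_gy: float) -> float:
    """Vx: percent of the structure volume receiving >= ``dose_gy``."""
    frac = 1.0 - np.searchsorted(dvh.structure_doses, dose_gy, side="left") / len(
        dvh.structure_doses
    )
    return float(frac * 100.0)


def homogeneity_index(dvh: DVHCurve) -> float:
    """HI = (D2% - D98%) / D50%; 0 for a perfectly uniform dose."""
    d50 = dose_at_volume(dvh, 50.0)
    if d50 == 0.0:
        raise DegenerateInputError("D50% is zero; homogeneity index undefined")
    return (dose_at_volume(dvh, 2.0) - dose_at_volume(dvh, 98.0)) / d50


def conformity_index(
    dose: DoseGrid,
    gtv: StructureMask,
    ref_gy: float | None = None,
    form: str = "paddick",
) -> float:
    """Conformity of the prescription isodose to the target.

    ``form="paddick"``: V_GTV,ref² / (V_GTV · V_ref), in [0, 1].
    ``form="ratio"``:   V_ref / V_GTV (can exceed 1).
    """
    m = _mask_array(gtv)
    if m.shape != dose.shape:
        raise GridMismatchError("dose and GTV mask must share a grid")
    if not m.any():
        raise DegenerateInputError("empty GTV mask")
    ref = float(ref_gy if ref_gy is not None else dose.prescription_gy)
    covered = dose.values >= ref
    v_ref = int(covered.sum())
    v_gtv = int(m.sum())
    v_overlap = int((covered & m).sum())
    if v_ref == 0:
        warnings.warn("no voxel reaches the prescription dose; CI defined as 0")
        return 0.0
    if form == "ratio":
        return v_ref / v_gtv
    return v_overlap**2 / (v_gtv * v_ref)


def gradient_index(dose: DoseGrid, ref_gy: float | None = None) -> float:
    """GI = V50% / V100%: how fast dose falls off outside the prescription isodose."""
    ref = float(ref_gy if ref_gy is not None else dose.prescription_gy)
    v100 = int((dose.values >= ref).sum())
    if v100 == 0:
        raise DegenerateInputError("no voxel receives the full prescription dose")
    v50 = int((dose.values >= 0.5 * ref).sum())
    return v50 / v100


def oar_metrics(
    dose: DoseGrid,
    structures: dict[str, StructureMask],
    v_levels_gy: tuple[float, ...] = (5.0, 20.0, 30.0),
    bin_gy: float = DEFAULT_BIN_GY,
) -> pd.DataFrame:
    """Per-structure Dmean/Dmax (Gy) and Vx (% of structure volume).

    One row per provided structure; raises ``KeyError`` for an empty dict and
    ``DegenerateInputError`` for an empty mask.
    """
    if not structures:
        raise KeyError("no structures provided")
    rows = []
    for name, mask in structures.items():
        dvh = compute_dvh(dose, mask, bin_gy)
        row = {
            "structure": name,
            "volume_cm3": dvh.volume_cm3,
            "d_mean_gy": dvh.d_mean(),
            "d_max_gy": dvh.d_max(),
        }
        for lvl in v_levels_gy:
            row[f"v{lvl:g}_pct"] = volume_at_dose(dvh, lvl)
        rows.append(row)
    return pd.DataFrame(rows)


def overlay_dose(dose: DoseGrid, t: RigidTransform, target: Volume | DoseGrid) -> DoseGrid:
    """Transfer a dose grid onto ``target``'s grid under a rigid transform
    (trilinear interpolation, zero fill outside the source grid)."""
    from scipy import ndimage

    tgt = target.as_volume() if isinstance(target, DoseGrid) else target
    if tgt.data.size == 0:
        raise GridMismatchError("degenerate target grid")
    src = dose.as_volume()
    if (
        t.translation_mm == (0.0, 0.0, 0.0)
        and t.rotation_deg == (0.0, 0.0, 0.0)
        and src.same_grid(tgt)
    ):
        return DoseGrid(dose.values.copy(), tgt.spacing, tgt.origin, dose.prescription_gy)
    zz, yy, xx = np.meshgrid(*tgt.world_coordinates(), indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    c = np.asarray(t.center_mm)
    tr = np.asarray(t.translation_mm)
    src_pts = (pts - c - tr) @ t._rot() + c
    idx = ((src_pts - np.asarray(src.origin)) / np.asarray(src.spacing)).T
    vals = ndimage.map_coordinates(dose.values, idx, order=1, mode="constant", cval=0.0)
    vals = np.clip(vals.reshape(tgt.shape), 0.0, None)
    return DoseGrid(vals, tgt.spacing, tgt.origin, dose.prescription_gy)
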