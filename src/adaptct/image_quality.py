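"""Image-quality evaluation: MAE, PSNR, SSIM and cohort reports.

MAE is the mean absolute HU difference over an evaluation region; PSNR is
``10·log10(MAX² / MSE)`` in dB (capped at 100 dB when the images are
identical); SSIM is available in two forms: the *global* single-window
formula

    SSIM = (2 μ1 μ2 + c1)(2 σ12 + c2) / ((μ1² + μ2² + c1)(σ1² + σ2² + c2))

evaluated once with whole-region statistics, and the conventional *windowed*
form (local SSIM averaged over the image). Cohort evaluation compares both
the uncorrected CBCT and the synthesized CT against the planning CT and
aggregates per-case rows into mean ± sd with improvement percentages; the
formula used for each improvement is recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, GridMismatchError
from .volume import StructureMask, Volume

__all__ = ["SSIMParams", "MetricReport", "mae", "psnr", "ssim", "evaluate_cohort",
           "PSNR_CAP_DB"]

PSNR_CAP_DB = 100.0

#: percentage-change formulas used by evaluate_cohort, recorded in its report
IMPROVEMENT_FORMULAS = {
    "mae": "(mae_cbct - mae_act) / mae_act * 100",
    "psnr": "(psnr_act - psnr_cbct) / psnr_cbct * 100",
    "ssim": "(ssim_act - ssim_cbct) / ssim_cbct * 100",
}


@dataclass
class SSIMParams:
    """Stabilizer constants c1 = (k1·L)², c2 = (k2·L)² and evaluation mode."""

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 4000.0  # HU span; robust against negative-HU per-image maxima
    mode: str = "global"  # "global" | "windowed"

    def __post_init__(self):
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be > 0")
        if self.mode not in ("global", "windowed"):
            raise ValueError(f"unknown SSIM mode {self.mode!r}")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def _arrays(i1, i2, region=None):
    a = np.asarray(i1.data if isinstance(i1, Volume) else i1, dtype=np.float64)
    b = np.asarray(i2.data if isinstance(i2, Volume) else i2, dtype=np.float64)
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch {a.shape} vs {b.shape}")
    if region is not None:
        r = np.asarray(region.data if isinstance(region, Volume) else region, dtype=bool)
        if r.shape != a.shape:
            raise GridMismatchError("region shape mismatch")
        if not r.any():
            raise DegenerateInputError("empty evaluation region")
        return a[r], b[r]
    return a.ravel(), b.ravel()


def mae(i1, i2, region: StructureMask | np.ndarray | None = None) -> float:
    """Mean absolute difference (HU) over the region; symmetric in arguments."""
    a, b = _arrays(i1, i2, region)
    return float(np.mean(np.abs(a - b)))


def psnr(
    i1,
    i2,
    max_value: float | None = None,
    region: StructureMask | np.ndarray | None = None,
) -> float:
    """Peak signal-to-noise ratio in dB; identical inputs return the 100 dB cap.

    ``max_value`` defaults to the maximum of the reference image (``i1``)
    within the evaluation region.
    """
    a, b = _arrays(i1, i2, region)
    mse = float(np.mean((a - b) ** 2))
    if max_value is None:
        max_value = float(np.max(a))
    if mse == 0.0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(max_value**2 / mse), PSNR_CAP_DB))


def ssim(
    i1,
    i2,
    params: SSIMParams | None = None,
    region: StructureMask | np.ndarray | None = None,
) -> float:
    """Structural similarity; 1 exactly iff the images are identical."""
    params = params if params is not None else SSIMParams()
    if params.mode == "windowed":
        from skimage.metrics import structural_similarity

        a = np.asarray(i1.data if isinstance(i1, Volume) else i1, dtype=np.float64)
        b = np.asarray(i2.data if isinstance(i2, Volume) else i2, dtype=np.float64)
        if a.shape != b.shape:
            raise GridMismatchError(f"shape mismatch {a.shape} vs {b.shape}")
        win = min(7, *(s - (1 - s % 2) for s in a.shape))
        full = structural_similarity(
            a, b, data_range=params.dynamic_range, gaussian_weights=True,
            sigma=1.5, use_sample_covariance=False, win_size=win, full=True,
        )[1]
        if region is not None:
            r = np.asarray(region.data if isinstance(region, Volume) else region, dtype=bool)
            return float(full[r].mean())
        return float(full.mean())
    a, b = _arrays(i1, i2, region)
    mu1, mu2 = a.mean(), b.mean()
    v1, v2 = a.var(), b.var()
    cov = float(np.mean((a - mu1) * (b - mu2)))
    c1, c2 = params.c1, params.c2
    return float(
        ((2 * mu1 * mu2 + c1) * (2 * cov + c2))
        / ((mu1**2 + mu2**2 + c1) * (v1 + v2 + c2))
    )


# ---------------------------------------------------------------------------
# cohort evaluation
# ---------------------------------------------------------------------------

def line_profile(
    volumes: dict[str, Volume], slice_index: int, axis: str = "x", position: int | None = None
) -> pd.DataFrame:
    """Extract an in-plane HU line profile through one slice of each volume.

    ``axis="x"`` samples along columns at a fixed row, ``axis="y"`` along rows
    at a fixed column; ``position`` defaults to the image center. Useful for
    overlaying CBCT / synthetic CT / planning CT HU traces.
    """
    rows = {}
    for name, v in volumes.items():
        sl = v.data[slice_index]
        if axis == "x":
            pos = position if position is not None else sl.shape[0] // 2
            prof = sl[pos, :]
            coord = np.arange(sl.shape[1]) * v.spacing[2]
        elif axis == "y":
            pos = position if position is not None else sl.shape[1] // 2
            prof = sl[:, pos]
            coord = np.arange(sl.shape[0]) * v.spacing[1]
        else:
            raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
        rows["position_mm"] = coord
        rows[name] = np.asarray(prof, dtype=float)
    return pd.DataFrame(rows)


@dataclass
class MetricReport:
    """Per-case metric rows plus aggregates and improvement percentages."""

    per_case: pd.DataFrame
    aggregates: dict[str, tuple[float, float]]  # column -> (mean, sd)
    improvement_pct: dict[str, float]
    formulas: dict[str, str] = field(default_factory=lambda: dict(IMPROVEMENT_FORMULAS))

    def to_csv(self, path) -> None:
        self.per_case.to_csv(path, index=False)


def evaluate_cohort(
    cases: list[tuple],
    ssim_params: SSIMParams | None = None,
    region: str = "body",
) -> MetricReport:
    """Evaluate (cbct, act, pct, body) cases against the planning CT.

    ``region`` selects the evaluation domain: ``"body"`` (default, matching
    the body-masked training loss) or ``"full"``.
    """
    if not cases:
        raise DegenerateInputError("empty cohort")
    ssim_params = ssim_params if ssim_params is not None else SSIMParams()
    rows = []
    for idx, (cbct, act, pct, body) in enumerate(cases):
        for vol in (act, pct, body):
            v0 = cbct if isinstance(cbct, Volume) else None
            if v0 is not None and isinstance(vol, Volume):
                v0.require_same_grid(vol)
        reg = body if region == "body" else None
        rows.append(
            {
                "case": idx,
                "mae_cbct": mae(cbct, pct, reg),
                "mae_act": mae(act, pct, reg),
                "psnr_cbct": psnr(pct, cbct, region=reg),
                "psnr_act": psnr(pct, act, region=reg),
                "ssim_cbct": ssim(cbct, pct, ssim_params, reg),
                "ssim_act": ssim(act, pct, ssim_params, reg),
            }
        )
    df = pd.DataFrame(rows)
    aggregates = {
        c: (float(df[c].mean()), float(df[c].std(ddof=1)) if len(df) > 1 else 0.0)
        for c in df.columns
        if c != "case"
    }
    m = {c: aggregates[c][0] for c in aggregates}
    improvement = {
        "mae": (m["mae_cbct"] - m["mae_act"]) / m["mae_act"] * 100 if m["mae_act"] else np.inf,
        "psnr": (m["psnr_act"] - m["psnr_cbct"]) / m["psnr_cbct"] * 100,
        "ssim": (m["ssim_act"] - m["ssim_cbct"]) / m["ssim_cbct"] * 100,
    }
    return MetricReport(per_case=df, aggregates=aggregates, improvement_pct=improvement)
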