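"""Synthetic thorax phantom and CBCT degradation simulator.

Every downstream stage of the toolkit (preprocessing, synthesis model,
image-quality metrics, DVH/gamma dosimetry) is exercised on seeded digital
phantoms produced here, so the whole pipeline is testable without patient
data.

The phantom is an axial thorax: an elliptical soft-tissue body on an air
background, two lung ellipsoids, a heart ellipsoid, a posterior vertebral
column with a spinal-cord canal, rib-like bone arcs on the body shell, and a
spherical lesion (GTV) inside one lung. Hounsfield values are drawn per
tissue class as mean ± sd.

CBCT-like degradation stacks the dominant cone-beam artifact families on top
of the clean CT: a low-frequency radial cupping bias, in-plane streaks,
a global affine HU miscalibration (gain/offset), and white HU noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateInputError
from .volume import DoseGrid, StructureMask, Volume

__all__ = [
    "ThoraxGeometry",
    "PhantomSpec",
    "ArtifactSpec",
    "SyntheticCase",
    "generate_thorax_ct",
    "thorax_masks",
    "degrade_to_cbct",
    "generate_dataset",
    "generate_synthetic_dose",
]


@dataclass
class ThoraxGeometry:
    """Placement of the phantom's organs, in mm relative to the volume center.

    Axes are (z, y, x) = (slice, row, column); +y is posterior.
    """

    body_axes_mm: tuple[float, float] = (48.0, 58.0)          # (y, x) half-axes
    lung_axes_mm: tuple[float, float, float] = (60.0, 30.0, 20.0)
    lung_center_y_mm: float = -2.0
    lung_center_x_mm: float = 27.0                            # mirrored for left/right
    heart_axes_mm: tuple[float, float, float] = (30.0, 18.0, 15.0)
    heart_center_mm: tuple[float, float, float] = (0.0, 4.0, -6.0)
    vertebra_center_y_mm: float = 36.0
    vertebra_radius_mm: float = 11.0
    cord_radius_mm: float = 4.0
    rib_shell_lo: float = 0.90                                # body-ellipse radius fractions
    rib_shell_hi: float = 0.99
    rib_count: int = 8
    rib_phase_rad: float = 0.0
    lesion_center_mm: tuple[float, float, float] = (0.0, -2.0, 27.0)
    lesion_radius_mm: float = 10.0
    lesion_side: str = "right"


@dataclass
class PhantomSpec:
    """Grid, tissue HU statistics and geometry of a synthetic thorax."""

    grid_shape: tuple[int, int, int] = (16, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tissue_hu: dict = field(
        default_factory=lambda: {
            "air": (-1000.0, 0.0),
            "lung": (-700.0, 50.0),
            "soft": (40.0, 20.0),
            "bone": (700.0, 100.0),
        }
    )
    geometry: ThoraxGeometry = field(default_factory=ThoraxGeometry)
    lesion_hu: float = 30.0

    def validate(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError(f"spacing_mm must be positive, got {self.spacing_mm}")
        for name, (mu, sd) in self.tissue_hu.items():
            if not -1000.0 <= mu <= 3000.0:
                raise ConfigurationError(f"tissue {name!r} mean HU {mu} outside [-1000, 3000]")
            if sd < 0:
                raise ConfigurationError(f"tissue {name!r} HU sd must be >= 0")
        g = self.geometry
        # conservative containment check: lesion sphere inside the lung ellipsoid
        lc = np.asarray(g.lesion_center_mm, dtype=float)
        lung_c = np.array([0.0, g.lung_center_y_mm, math.copysign(g.lung_center_x_mm, lc[2])])
        axes = np.asarray(g.lung_axes_mm, dtype=float)
        if np.any(np.abs(lc - lung_c) + g.lesion_radius_mm > axes):
            raise ConfigurationError("lesion sphere is not fully inside a lung ellipsoid")


@dataclass
class ArtifactSpec:
    """CBCT degradation parameters.

    ``cupping_amplitude`` is the HU bias added at the field-of-view center,
    decaying quadratically to zero at the edge (a scatter-like depression when
    negative). ``hu_drift`` is an affine (gain, offset) miscalibration applied
    after cupping and streaks; white noise of ``noise_sd`` HU is added last.
    The all-zero spec (gain 1, everything else 0) is the identity.
    """

    cupping_amplitude: float = -80.0
    noise_sd: float = 20.0
    hu_drift: tuple[float, float] = (1.02, -40.0)
    streak_count: int = 4
    streak_amplitude: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.streak_count < 0:
            raise ConfigurationError("streak_count must be >= 0")

    @classmethod
    def none(cls) -> "ArtifactSpec":
        """Identity degradation."""
        return cls(0.0, 0.0, (1.0, 0.0), 0, 0.0, 0)

    @classmethod
    def affine_only(cls, gain: float = 1.02, offset: float = -40.0) -> "ArtifactSpec":
        """Pure global HU miscalibration — a degradation a model can undo exactly."""
        return cls(0.0, 0.0, (gain, offset), 0, 0.0, 0)

    def is_identity(self) -> bool:
        return (
            self.cupping_amplitude == 0
            and self.noise_sd == 0
            and tuple(self.hu_drift) == (1.0, 0.0)
            and (self.streak_count == 0 or self.streak_amplitude == 0)
        )


@dataclass
class SyntheticCase:
    """An aligned (pCT, CBCT) pair with body and organ masks."""

    pct: Volume
    cbct: Volume
    body: StructureMask
    structures: dict[str, StructureMask]
    dose: DoseGrid | None = None
    seed: int = 0


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _centered_coords(spec: PhantomSpec):
    """World coordinates (mm) relative to the grid center, per axis."""
    out = []
    for n, s in zip(spec.grid_shape, spec.spacing_mm):
        out.append((np.arange(n) - (n - 1) / 2.0) * s)
    return np.meshgrid(*out, indexing="ij", sparse=True)


def _ellipsoid(zz, yy, xx, center, axes) -> np.ndarray:
    cz, cy, cx = center
    az, ay, ax = axes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _region_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boolean tissue regions from the geometry; keys are anatomical names."""
    g = spec.geometry
    zz, yy, xx = _centered_coords(spec)
    by, bx = g.body_axes_mm
    rho2 = (yy / by) ** 2 + (xx / bx) ** 2
    body = np.broadcast_to(rho2 <= 1.0, spec.grid_shape).copy()

    sign = 1.0 if g.lesion_side == "right" else -1.0
    lungs = {}
    for name, sx in (("right", 1.0), ("left", -1.0)):
        lungs[name] = _ellipsoid(
            zz, yy, xx, (0.0, g.lung_center_y_mm, sx * g.lung_center_x_mm), g.lung_axes_mm
        )
    heart = _ellipsoid(zz, yy, xx, g.heart_center_mm, g.heart_axes_mm)

    vert = np.broadcast_to(
        (yy - g.vertebra_center_y_mm) ** 2 + xx**2 <= g.vertebra_radius_mm**2,
        spec.grid_shape,
    ).copy()
    cord = np.broadcast_to(
        (yy - g.vertebra_center_y_mm) ** 2 + xx**2 <= g.cord_radius_mm**2, spec.grid_shape
    ).copy()

    theta = np.arctan2(np.broadcast_to(yy, spec.grid_shape), np.broadcast_to(xx, spec.grid_shape))
    rho = np.sqrt(np.broadcast_to(rho2, spec.grid_shape))
    ribs = (
        (rho >= g.rib_shell_lo)
        & (rho <= g.rib_shell_hi)
        & (np.sin(g.rib_count * theta + g.rib_phase_rad) > 0.35)
    )

    lesion = _ellipsoid(
        zz, yy, xx, g.lesion_center_mm, (g.lesion_radius_mm,) * 3
    )

    # lungs exclude overlapping mediastinal/bony structures, mirroring the
    # painting order of the HU generator
    not_lung = heart | vert | cord | ribs
    ipsi = lungs["right"] if g.lesion_side == "right" else lungs["left"]
    masks = {
        "body": body,
        "lung_left": lungs["left"] & body & ~not_lung,
        "lung_right": lungs["right"] & body & ~not_lung,
        "heart": heart & body,
        "vertebra": (vert & body) & ~cord,
        "spinal_cord": cord & body,
        "ribs": ribs & body,
        "gtv": lesion & body & ~not_lung,
        "lung_ipsilateral": ipsi & body & ~not_lung,
    }
    masks["lungs"] = masks["lung_left"] | masks["lung_right"]
    return masks


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_thorax_ct(spec: PhantomSpec, seed: int = 0) -> Volume:
    """Render a clean thorax CT in HU, deterministic for fixed (spec, seed).

    Voxels outside the body ellipse are exactly -1000 HU (air).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    m = _region_masks(spec)
    shape = spec.grid_shape

    def draw(name: str, region: np.ndarray, out: np.ndarray) -> None:
        mu, sd = spec.tissue_hu[name]
        vals = mu + sd * rng.standard_normal(shape)
        out[region] = vals[region]

    hu = np.full(shape, spec.tissue_hu["air"][0], dtype=np.float32)
    # paint from outside in so later classes override earlier ones
    draw("soft", m["body"], hu)
    draw("lung", m["lungs"], hu)
    draw("soft", m["heart"], hu)
    draw("bone", m["vertebra"] | m["ribs"], hu)
    draw("soft", m["spinal_cord"], hu)
    lesion_sd = spec.tissue_hu["soft"][1]
    hu[m["gtv"]] = (spec.lesion_hu + lesion_sd * rng.standard_normal(shape))[m["gtv"]]
    return Volume(hu, spec.spacing_mm)


def thorax_masks(spec: PhantomSpec) -> dict[str, StructureMask]:
    """Ground-truth structure masks (body, lungs, GTV, heart, spinal cord...)."""
    spec.validate()
    return {
        name: Volume(arr, spec.spacing_mm)
        for name, arr in _region_masks(spec).items()
    }


def degrade_to_cbct(ct: Volume, art: ArtifactSpec) -> Volume:
    """Apply CBCT-like artifacts: drift ∘ (ct + cupping + streaks) + noise."""
    art.validate()
    rng = np.random.default_rng(art.seed)
    nz, ny, nx = ct.shape
    out = ct.data.astype(np.float32).copy()

    if art.cupping_amplitude != 0.0:
        y = (np.arange(ny) - (ny - 1) / 2.0) / (ny / 2.0)
        x = (np.arange(nx) - (nx - 1) / 2.0) / (nx / 2.0)
        rho2 = y[:, None] ** 2 + x[None, :] ** 2
        field_2d = art.cupping_amplitude * np.clip(1.0 - rho2, 0.0, None)
        out += field_2d[None, :, :].astype(np.float32)

    if art.streak_count > 0 and art.streak_amplitude != 0.0:
        yy = (np.arange(ny) - (ny - 1) / 2.0) * ct.spacing[1]
        xx = (np.arange(nx) - (nx - 1) / 2.0) * ct.spacing[2]
        Y, X = np.meshgrid(yy, xx, indexing="ij")
        half_width = max(ct.spacing[1], ct.spacing[2]) / 2.0
        r_max = min(abs(yy[0]), abs(xx[0]))
        for k in range(nz):
            for _ in range(art.streak_count):
                phi = rng.uniform(0, np.pi)
                offset = rng.uniform(-0.6, 0.6) * r_max
                sign = 1.0 if rng.random() < 0.5 else -1.0
                dist = np.abs(np.cos(phi) * Y + np.sin(phi) * X - offset)
                out[k][dist <= half_width] += sign * art.streak_amplitude

    gain, bias = art.hu_drift
    out = gain * out + bias

    if art.noise_sd > 0:
        out += art.noise_sd * rng.standard_normal(ct.shape).astype(np.float32)

    return Volume(out.astype(np.float32), ct.spacing, ct.origin)


def _jitter_geometry(g: ThoraxGeometry, rng: np.random.Generator) -> ThoraxGeometry:
    """Per-case anatomical variation; containment is re-validated by the caller."""
    j = replace(g)
    j.body_axes_mm = tuple(a * rng.uniform(0.94, 1.06) for a in g.body_axes_mm)
    j.lung_center_y_mm = g.lung_center_y_mm + rng.uniform(-2.0, 2.0)
    j.heart_center_mm = (
        g.heart_center_mm[0],
        g.heart_center_mm[1] + rng.uniform(-2.0, 2.0),
        g.heart_center_mm[2] + rng.uniform(-2.0, 2.0),
    )
    j.lesion_radius_mm = g.lesion_radius_mm * rng.uniform(0.85, 1.15)
    j.lesion_center_mm = (
        g.lesion_center_mm[0] + rng.uniform(-3.0, 3.0),
        g.lesion_center_mm[1] + rng.uniform(-3.0, 3.0),
        g.lesion_center_mm[2] + rng.uniform(-3.0, 3.0),
    )
    j.rib_phase_rad = rng.uniform(0, 2 * np.pi)
    return j


def generate_dataset(
    n_cases: int,
    spec: PhantomSpec | None = None,
    art: ArtifactSpec | None = None,
    seed: int = 0,
    with_dose: bool = False,
) -> list[SyntheticCase]:
    """Generate a cohort of jittered, seeded phantom cases.

    Per-case seeds are derived deterministically from the master seed, so the
    same call always returns a bit-identical dataset.
    """
    if n_cases < 1:
        raise ConfigurationError(f"n_cases must be >= 1, got {n_cases}")
    spec = spec if spec is not None else PhantomSpec()
    art = art if art is not None else ArtifactSpec()
    spec.validate()
    art.validate()

    master = np.random.default_rng(seed)
    cases = []
    for _ in range(n_cases):
        case_seed = int(master.integers(0, 2**31 - 1))
        jrng = np.random.default_rng(case_seed)
        for _attempt in range(20):
            geo = _jitter_geometry(spec.geometry, jrng)
            jspec = replace(spec, geometry=geo)
            try:
                jspec.validate()
                break
            except ConfigurationError:
                continue
        else:  # pragma: no cover - defensive
            jspec = spec
        pct = generate_thorax_ct(jspec, case_seed)
        masks = thorax_masks(jspec)
        cbct = degrade_to_cbct(pct, replace(art, seed=case_seed + 1))
        structures = {
            k: masks[k]
            for k in ("gtv", "lungs", "lung_ipsilateral", "heart", "spinal_cord")
        }
        case = SyntheticCase(
            pct=pct,
            cbct=cbct,
            body=masks["body"],
            structures=structures,
            seed=case_seed,
        )
        if with_dose:
            case.dose = generate_synthetic_dose(case)
        cases.append(case)
    return cases


def generate_synthetic_dose(
    case: SyntheticCase, prescription_gy: float = 60.0, falloff_mm: float = 8.0
) -> DoseGrid:
    """Analytic dose: prescription inside the GTV, halving every ``falloff_mm``
    of distance outside it. ``falloff_mm = inf`` gives a uniform dose."""
    gtv = case.structures.get("gtv")
    if gtv is None or not np.any(gtv.data):
        raise DegenerateInputError("case has no (nonempty) GTV mask")
    if math.isinf(falloff_mm):
        dose = np.full(gtv.shape, prescription_gy, dtype=float)
    else:
        dist = ndimage.distance_transform_edt(~gtv.data.astype(bool), sampling=gtv.spacing)
        dose = prescription_gy * np.power(0.5, dist / falloff_mm)
    return DoseGrid(dose, gtv.spacing, gtv.origin, prescription_gy=prescription_gy)
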