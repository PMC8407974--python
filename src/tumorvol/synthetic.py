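"""Digital tumor phantoms with known analytic geometry.

The generator emulates the geometry of a surgical meningioma cohort: tumor
volumes follow a lognormal distribution with median 26.65 mL and interquartile
range 11.38-51.21 mL, masks are sampled on an MRI-like anisotropic grid
(default in-plane pixel 0.449 mm — a 230 mm field of view on a 512 matrix —
with 4 mm slices), every tumor is a single connected component, and tumors
spanning four or fewer axial slices are redrawn, mirroring the study-style
inclusion filter. Shapes are either rotated ellipsoids (regular, high
ellipsoidity) or lobulated unions of a parent ellipsoid with smaller
overlapping lobes (irregular, lower ellipsoidity).

For ellipsoid phantoms the analytic volume (4/3)*pi*a*b*c is carried as ground
truth; lobulated phantoms have no closed-form volume and carry none.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import CohortError
from .estimators import estimate_volumes
from .mask_io import SegmentationMask
from .morphometry import morphometry
from .records import CohortRecord

log = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "CohortConfig",
    "rasterize_ellipsoid",
    "lobulated_phantom",
    "sample_cohort",
    "measure_cohort",
    "ellipsoid_calibration_cohort",
]

# Normal quartile spacing: ln(IQR ratio) / (2 * 0.6745) gives the lognormal sigma.
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class PhantomSpec:
    """Fully resolved geometry of one phantom (rasterisation is deterministic)."""

    case_id: str
    shape: str  # "ellipsoid" | "lobulated"
    half_axes: tuple[float, float, float]  # mm, parent ellipsoid
    rotation: np.ndarray  # 3x3, body -> world
    spacing: tuple[float, float, float]  # (dz, dy, dx) mm
    target_volume_ml: float
    n_lobes: int = 1
    lobe_scale: float = 1.0
    # resolved lobe geometry: world-frame centers (mm), axes (mm), rotations
    lobe_centers: tuple[tuple[float, float, float], ...] = ()
    lobe_axes: tuple[tuple[float, float, float], ...] = ()
    lobe_rotations: tuple = ()

    @property
    def analytic_volume_ml(self) -> float | None:
        if self.shape != "ellipsoid":
            return None
        a, b, c = self.half_axes
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for cohort generation.

    Defaults encode the emulated cohort: volume median 26.65 mL with IQR
    11.38-51.21 mL, 4 x 0.449 x 0.449 mm grid, and a >4 tumor-bearing-slice
    inclusion filter. Roughly 60% of tumors are regular (ellipsoid) and 40%
    lobulated — the shape mix of the real cohort is unpublished, so this is a
    configuration knob, not a claim.
    """

    spacing: tuple[float, float, float] = (4.0, 0.449, 0.449)
    volume_median_ml: float = 26.65
    volume_iqr_ml: tuple[float, float] = (11.38, 51.21)
    ellipsoid_fraction: float = 0.6
    axis_ratio_range: tuple[float, float] = (0.6, 1.0)
    n_lobes_range: tuple[int, int] = (2, 4)
    lobe_scale_range: tuple[float, float] = (0.4, 0.7)
    min_slices: int = 5  # "> 4 tumor-bearing slices"
    max_redraws: int = 50

    @property
    def lognormal_params(self) -> tuple[float, float]:
        mu = math.log(self.volume_median_ml)
        lo, hi = self.volume_iqr_ml
        sigma = math.log(hi / lo) / (2.0 * _Z75)
        return mu, sigma


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _rasterize_union(
    components: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    spacing: tuple[float, float, float],
    margin_voxels: int = 2,
) -> SegmentationMask:
    """Rasterise a union of ellipsoids given as (center_mm, half_axes, rotation).

    A voxel is foreground iff its center satisfies at least one component's
    ellipsoid inequality. The grid is sized to the union's bounding box plus a
    margin; the grid origin voxel index maps to physical coordinate 0 of a
    frame centred so the union is fully inside.
    """
    spacing_arr = np.asarray(spacing, dtype=float)
    reach = np.zeros(3)
    for center, axes, rot in components:
        # extent of the rotated ellipsoid along each world axis
        ext = np.sqrt(((rot * axes[None, :]) ** 2).sum(axis=1))
        reach = np.maximum(reach, np.abs(center) + ext)
    half_counts = np.ceil(reach / spacing_arr).astype(int) + margin_voxels
    shape = tuple(2 * half_counts + 1)
    grids = [
        (np.arange(shape[ax]) - half_counts[ax]) * spacing_arr[ax] for ax in range(3)
    ]
    mask = np.zeros(shape, dtype=bool)
    zz = grids[0][:, None, None]
    yy = grids[1][None, :, None]
    xx = grids[2][None, None, :]
    for center, axes, rot in components:
        # world -> body: q = R^T (p - c); inside iff sum (q_i / a_i)^2 <= 1
        B = rot @ np.diag(1.0 / axes**2) @ rot.T
        dz_ = zz - center[0]
        dy_ = yy - center[1]
        dx_ = xx - center[2]
        q = (
            B[0, 0] * dz_**2
            + B[1, 1] * dy_**2
            + B[2, 2] * dx_**2
            + 2 * B[0, 1] * dz_ * dy_
            + 2 * B[0, 2] * dz_ * dx_
            + 2 * B[1, 2] * dy_ * dx_
        )
        mask |= q <= 1.0
    # guarantee at least the central voxel of the first component
    c0 = components[0][0]
    idx0 = tuple(int(round(c0[ax] / spacing_arr[ax])) + half_counts[ax] for ax in range(3))
    mask[idx0] = True
    return SegmentationMask(voxels=mask.astype(np.uint8), spacing=tuple(spacing_arr))


def rasterize_ellipsoid(
    half_axes,
    rotation: np.ndarray | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    margin_voxels: int = 2,
    case_id: str = "",
) -> SegmentationMask:
    """Binary mask of a single (optionally rotated) ellipsoid, center-voxel rule."""
    axes = np.asarray(half_axes, dtype=float)
    if (axes <= 0).any():
        raise CohortError(f"half axes must be positive, got {half_axes}")
    rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    mask = _rasterize_union([(np.zeros(3), axes, rot)], spacing, margin_voxels)
    if case_id:
        mask = SegmentationMask(mask.voxels, mask.spacing, case_id)
    return mask


def _resolve_lobes(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Draw lobe centers/axes/rotations for a lobulated spec (idempotent)."""
    if spec.shape != "lobulated" or spec.lobe_centers:
        return spec
    if spec.n_lobes < 2:
        raise CohortError("a lobulated phantom needs n_lobes >= 2")
    if not 0 < spec.lobe_scale <= 1:
        raise CohortError(f"lobe_scale must be in (0, 1], got {spec.lobe_scale}")
    axes = np.asarray(spec.half_axes)
    centers, lobe_axes, rots = [], [], []
    for _ in range(spec.n_lobes - 1):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        radial = rng.uniform(0.3, 0.85)  # keep lobe centers inside the parent
        body = radial * u * axes
        centers.append(tuple(spec.rotation @ body))
        lobe_axes.append(tuple(axes * spec.lobe_scale))
        rots.append(_random_rotation(rng))
    return replace(
        spec,
        lobe_centers=tuple(centers),
        lobe_axes=tuple(lobe_axes),
        lobe_rotations=tuple(rots),
    )


def rasterize_phantom(spec: PhantomSpec) -> SegmentationMask:
    """Deterministically rasterise a fully resolved phantom spec."""
    comps = [(np.zeros(3), np.asarray(spec.half_axes, float), np.asarray(spec.rotation, float))]
    for c, ax, r in zip(spec.lobe_centers, spec.lobe_axes, spec.lobe_rotations):
        comps.append((np.asarray(c, float), np.asarray(ax, float), np.asarray(r, float)))
    mask = _rasterize_union(comps, spec.spacing)
    return SegmentationMask(mask.voxels, mask.spacing, spec.case_id)


def lobulated_phantom(spec: PhantomSpec, rng: np.random.Generator) -> SegmentationMask:
    """Union of a parent ellipsoid and (n_lobes - 1) overlapping lobes.

    Lobe centers are constrained inside the parent, so the union is a single
    connected component. With n_lobes = 1 this reduces to the plain ellipsoid.
    """
    if spec.n_lobes == 1:
        return rasterize_phantom(spec)
    return rasterize_phantom(_resolve_lobes(spec, rng))


def _draw_spec(
    i: int, attempt: int, seed: int, config: CohortConfig, rng: np.random.Generator
) -> PhantomSpec:
    mu, sigma = config.lognormal_params
    volume_ml = float(np.exp(rng.normal(mu, sigma)))
    r2, r3 = rng.uniform(*config.axis_ratio_range, size=2)
    a1 = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi * r2 * r3)) ** (1.0 / 3.0)
    half_axes = (a1, a1 * r2, a1 * r3)
    rotation = _random_rotation(rng)
    if rng.uniform() < config.ellipsoid_fraction:
        shape, n_lobes, lobe_scale = "ellipsoid", 1, 1.0
    else:
        shape = "lobulated"
        n_lobes = int(rng.integers(config.n_lobes_range[0], config.n_lobes_range[1] + 1))
        lobe_scale = float(rng.uniform(*config.lobe_scale_range))
    return PhantomSpec(
        case_id=f"sim-{i:04d}",
        shape=shape,
        half_axes=half_axes,
        rotation=rotation,
        spacing=config.spacing,
        target_volume_ml=volume_ml,
        n_lobes=n_lobes,
        lobe_scale=lobe_scale,
    )


def sample_cohort(
    n: int, config: CohortConfig | None = None, seed: int = 0
) -> list[tuple[SegmentationMask, PhantomSpec]]:
    """Generate ``n`` phantoms reproducibly from ``seed``.

    Each phantom has its own counter-derived random substream, so a cohort is
    reproducible independently of generation order. Phantoms violating the
    minimum-slice inclusion filter are redrawn from a fresh substream (logged).
    """
    if n < 1:
        raise CohortError("cohort size must be >= 1")
    config = config or CohortConfig()
    out: list[tuple[SegmentationMask, PhantomSpec]] = []
    for i in range(n):
        for attempt in range(config.max_redraws):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(i, attempt))
            )
            spec = _draw_spec(i, attempt, seed, config, rng)
            if spec.shape == "lobulated":
                spec = _resolve_lobes(spec, rng)
            mask = rasterize_phantom(spec)
            n_slices = int(mask.voxels.any(axis=(1, 2)).sum())
            if n_slices >= config.min_slices:
                out.append((mask, spec))
                break
            log.info(
                "phantom %s attempt %d spans %d slices (< %d); redrawing",
                spec.case_id, attempt, n_slices, config.min_slices,
            )
        else:
            raise CohortError(
                f"could not satisfy the {config.min_slices}-slice filter for "
                f"phantom {i} within {config.max_redraws} redraws"
            )
    return out


def measure_cohort(
    cohort: list[tuple[SegmentationMask, PhantomSpec]],
    with_ellipsoidity: bool = True,
    mvee_tolerance: float = 1e-6,
) -> list[CohortRecord]:
    """Run morphometry + formula estimates on every phantom of a cohort."""
    records = []
    for mask, spec in cohort:
        m = morphometry(mask, with_ellipsoidity=with_ellipsoidity, mvee_tolerance=mvee_tolerance)
        est = estimate_volumes(m.a, m.b, m.s, m.h)
        records.append(
            CohortRecord(
                case_id=spec.case_id,
                morphometry=m,
                estimates=est,
                shape=spec.shape,
                truth_volume_ml=spec.analytic_volume_ml,
                truth_half_axes_mm=spec.half_axes if spec.shape == "ellipsoid" else None,
            )
        )
    return records


def ellipsoid_calibration_cohort(
    n: int,
    seed: int = 0,
    half_axis_range: tuple[float, float] = (15.0, 35.0),
    axis_ratio_range: tuple[float, float] = (0.6, 1.0),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[tuple[SegmentationMask, PhantomSpec]]:
    """Randomly rotated pure-ellipsoid phantoms on a fine isotropic grid.

    Used to check the analytic calibration of the formula methods: for any
    rotated ellipsoid 2/3*S*H equals the true volume and 1/2*A*B*C equals
    (3/pi) times it, so the discretised pipeline should reproduce these limits.
    """
    out = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        a1 = rng.uniform(*half_axis_range)
        r2, r3 = rng.uniform(*axis_ratio_range, size=2)
        half_axes = (a1, a1 * r2, a1 * r3)
        spec = PhantomSpec(
            case_id=f"cal-{i:04d}",
            shape="ellipsoid",
            half_axes=half_axes,
            rotation=_random_rotation(rng),
            spacing=spacing,
            target_volume_ml=4.0 / 3.0 * math.pi * a1**3 * r2 * r3 / 1000.0,
        )
        out.append((rasterize_phantom(spec), spec))
    return out
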