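"""Per-tumor geometric measurements on axial segmentation masks.

This module computes the slice-based caliper parameters used by the ellipsoid
approximation formulas — S (largest axial cross-section area), A (maximum
in-slice length), B (maximum in-slice width perpendicular to A) and H (slice
thickness times tumor-bearing slice count) — together with planimetric volume,
maximum 3D tumor diameter, and "ellipsoidity": the ratio of tumor volume to the
volume of its minimum-volume enclosing ellipsoid (MVEE).

Conventions
-----------
* Masks are ``(slice, row, col)`` with spacing ``(dz, dy, dx)`` mm.
* Results are on clinical scales: lengths in cm, areas in cm^2, volumes in mL.
* A and B use pixel *centers*; the systematic underestimate is below one pixel.
* The tumor surface is the set of foreground voxels with at least one of their
  six face neighbours background or outside the grid.
* The MVEE for ellipsoidity is fitted to the 8 box corners of every surface
  voxel, so the ellipsoid provably contains the whole voxelised tumor and
  ellipsoidity is structurally <= 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import (
    ConvergenceError,
    DegenerateGeometryError,
    EmptyMaskError,
    MultiComponentError,
)
from .mask_io import SegmentationMask

__all__ = [
    "TumorMorphometry",
    "Ellipsoid",
    "planimetric_volume",
    "max_area_slice",
    "inplane_axes",
    "tumor_height",
    "max_diameter",
    "mvee",
    "ellipsoidity",
    "morphometry",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)   # 6-connectivity
_FULL_STRUCT = ndimage.generate_binary_structure(3, 3)   # 26-connectivity


@dataclass(frozen=True)
class TumorMorphometry:
    """All per-tumor geometric quantities for one case."""

    case_id: str
    v_plan: float            # planimetric volume, mL
    s: float                 # max axial cross-section area, cm^2
    a: float                 # max in-slice length, cm
    b: float                 # max in-slice width perpendicular to a, cm
    h: float                 # tumor height (= C), cm
    max_diameter: float      # cm
    ellipsoidity: float | None  # dimensionless, in (0, 1]; None if not computed
    n_slices: int
    max_slice_index: int


@dataclass(frozen=True)
class Ellipsoid:
    """Ellipsoid {x : (x - center)^T M (x - center) <= 1} with M symmetric PD."""

    center: np.ndarray
    shape_matrix: np.ndarray
    volume: float  # mm^3


def _require_foreground(mask: SegmentationMask) -> None:
    if mask.n_foreground == 0:
        raise EmptyMaskError(f"mask '{mask.case_id}' has no foreground voxels")


def planimetric_volume(mask: SegmentationMask) -> float:
    """Volume in mL as foreground voxel count times voxel volume."""
    _require_foreground(mask)
    return mask.n_foreground * mask.voxel_volume_mm3 / 1000.0


def max_area_slice(mask: SegmentationMask) -> tuple[int, float]:
    """Index of the axial slice with the largest tumor area, and that area S (cm^2).

    Ties go to the lowest slice index.
    """
    _require_foreground(mask)
    counts = mask.voxels.sum(axis=(1, 2))
    idx = int(np.argmax(counts))
    _, dy, dx = mask.spacing
    return idx, float(counts[idx]) * dy * dx / 100.0


def _max_pair(points: np.ndarray, indices: np.ndarray) -> tuple[float, int, int]:
    """Maximum pairwise distance and the attaining pair.

    Candidates are reduced to convex-hull vertices when possible (the maximum
    pairwise distance is attained between hull vertices). Among pairs attaining
    the maximum, the lexicographically smallest pair of original grid indices
    is returned, which makes the direction of A deterministic.
    """
    if len(points) == 1:
        return 0.0, 0, 0
    cand = np.arange(len(points))
    if len(points) > points.shape[1] + 1:
        try:
            hull = ConvexHull(points)
            cand = np.sort(hull.vertices)
        except QhullError:
            pass  # degenerate (collinear/coplanar) — brute force over all points
    sub = points[cand]
    d = pdist(sub)
    dmax = d.max()
    n = len(sub)
    best = None
    for k in np.flatnonzero(d == dmax):
        i, rem, row = 0, int(k), n - 1
        while rem >= row:
            rem -= row
            i += 1
            row -= 1
        j = i + 1 + rem
        key = (tuple(indices[cand[i]]), tuple(indices[cand[j]]))
        if best is None or key < best[0]:
            best = (key, cand[i], cand[j])
    assert best is not None
    return float(dmax), int(best[1]), int(best[2])


def inplane_axes(mask: SegmentationMask, slice_index: int) -> tuple[float, float]:
    """(A, B) in cm for one axial slice.

    A is the maximum pairwise distance between foreground pixel centers in
    physical in-plane coordinates; B is the Feret width perpendicular to the
    A direction (extent of the projections onto the perpendicular unit vector).
    A single-pixel slice yields A = B = 0.
    """
    sl = mask.voxels[slice_index]
    ii, jj = np.nonzero(sl)
    if ii.size == 0:
        raise EmptyMaskError(f"slice {slice_index} of '{mask.case_id}' is empty")
    _, dy, dx = mask.spacing
    pts = np.column_stack([ii * dy, jj * dx]).astype(float)
    idx = np.column_stack([ii, jj])
    if len(pts) == 1:
        return 0.0, 0.0
    a_mm, p1, p2 = _max_pair(pts, idx)
    if a_mm == 0.0:
        return 0.0, 0.0
    u = (pts[p2] - pts[p1]) / a_mm
    perp = np.array([-u[1], u[0]])
    proj = pts @ perp
    b_mm = float(proj.max() - proj.min())
    return a_mm / 10.0, b_mm / 10.0


def tumor_height(mask: SegmentationMask) -> tuple[float, int]:
    """(H in cm, number of tumor-bearing axial slices).

    H = n_slices * dz. Internal empty slices are not interpolated: only slices
    actually containing foreground count.
    """
    _require_foreground(mask)
    bearing = np.flatnonzero(mask.voxels.any(axis=(1, 2)))
    n = int(bearing.size)
    dz = mask.spacing[0]
    return n * dz / 10.0, n


def surface_voxel_indices(mask: SegmentationMask) -> np.ndarray:
    """Indices (n, 3) of foreground voxels with a face-exposed side."""
    _require_foreground(mask)
    fg = mask.voxels.astype(bool)
    interior = ndimage.binary_erosion(fg, structure=_FACE_STRUCT, border_value=0)
    return np.argwhere(fg & ~interior)


def _physical(indices: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    return indices.astype(float) * np.asarray(spacing, dtype=float)


def max_diameter(mask: SegmentationMask) -> float:
    """Maximum 3D Euclidean distance (cm) between surface-voxel centers."""
    idx = surface_voxel_indices(mask)
    pts = _physical(idx, mask.spacing)
    if len(pts) == 1:
        return 0.0
    d_mm, _, _ = _max_pair(pts, idx)
    return d_mm / 10.0


def mvee(points: np.ndarray, tolerance: float = 1e-6, max_iter: int = 300_000) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid of a 3D point set.

    Uses the Khachiyan first-order scheme with Wolfe–Atwood away steps on the
    dual weights and Harman–Pronzato safe point elimination, stopped when
    every point lies within a factor ``1 + tolerance`` of the unit level set
    and every support point within the same factor from below. Rasterised
    clouds can have near-degenerate support sets where first-order progress
    stalls; runs that exhaust the iteration cap within 100x the tolerance are
    accepted (the volume suboptimality this admits is far below the method's
    discretisation error). The returned ellipsoid is rescaled so containment
    of all input points is exact, hence volumes derived from it are upper
    bounds.
    """
    P_in = np.asarray(points, dtype=float)
    if P_in.ndim != 2:
        raise DegenerateGeometryError("points must be an (n, d) array")
    n, d = P_in.shape
    mu = P_in.mean(axis=0)
    centered = P_in - mu
    if n < d + 1 or np.linalg.matrix_rank(centered) < d:
        raise DegenerateGeometryError("point set is affinely rank-deficient")
    # center and scale per axis for conditioning; undone exactly afterwards
    scale = np.abs(centered).max(axis=0)
    P = centered / scale
    Q = np.hstack([P, np.ones((n, 1))]).T  # (d+1, n)
    u = np.full(n, 1.0 / n)
    dp1 = d + 1
    for it in range(max_iter):
        X = (Q * u) @ Q.T
        try:
            invXQ = np.linalg.solve(X, Q)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
            raise DegenerateGeometryError("singular moment matrix") from exc
        M = np.einsum("ij,ij->j", Q, invXQ)
        j_plus = int(np.argmax(M))
        kappa_plus = M[j_plus]
        support = u > 1e-12
        M_supp = np.where(support, M, np.inf)
        j_minus = int(np.argmin(M_supp))
        kappa_minus = M_supp[j_minus]
        eps_plus = kappa_plus / dp1 - 1.0
        eps_minus = 1.0 - kappa_minus / dp1
        if eps_plus <= tolerance and eps_minus <= tolerance:
            break
        if it and it % 200 == 0 and 0 < eps_plus < 1:
            # Harman-Pronzato bound: points this deep inside cannot support
            # the optimum and may be dropped
            thresh = dp1 * (
                1 + eps_plus / 2
                - np.sqrt(eps_plus * (4 + eps_plus - 4 / dp1)) / 2
            )
            keep = (M >= thresh) | support
            if keep.sum() < len(u):
                Q = Q[:, keep]
                u = u[keep]
                u /= u.sum()
                continue
        if eps_plus >= eps_minus:
            j, kappa = j_plus, kappa_plus
            step = (kappa - dp1) / (dp1 * (kappa - 1.0))
        else:
            j, kappa = j_minus, kappa_minus
            step = (kappa - dp1) / (dp1 * (kappa - 1.0))  # negative: away step
            step = max(step, -u[j] / (1.0 - u[j]))
        u *= 1.0 - step
        u[j] += step
        np.clip(u, 0.0, None, out=u)
    else:
        if eps_plus > 100 * tolerance or eps_minus > 100 * tolerance:
            raise ConvergenceError(
                f"MVEE did not converge within {max_iter} iterations "
                f"(gap {max(eps_plus, eps_minus):.2e})"
            )
    P = Q[:d].T
    c = P.T @ u
    S = P.T @ (u[:, None] * P) - np.outer(c, c)
    A = np.linalg.inv(S) / d
    # undo the axis scaling: x_orig = mu + scale * x
    A = A / np.outer(scale, scale)
    A = (A + A.T) / 2.0
    c = mu + scale * c
    # exact containment: inflate so max_p (p-c)^T A (p-c) = 1 if any point sticks out
    diff = P_in - c
    q = np.einsum("ij,jk,ik->i", diff, A, diff)
    qmax = q.max()
    if qmax > 1.0:
        A = A / qmax
    volume = 4.0 / 3.0 * np.pi / np.sqrt(np.linalg.det(A))
    return Ellipsoid(center=c, shape_matrix=A, volume=float(volume))


def _corner_cloud(mask: SegmentationMask) -> np.ndarray:
    """Convex-hull-reduced cloud of surface-voxel box corners (mm).

    The hull of all foreground voxel centers equals the hull of the surface
    voxel centers (every extreme center is face-exposed), and the hull of all
    box corners is the Minkowski sum of that hull with the corner offsets, so
    the reduced cloud spans exactly the convex hull of the voxelised tumor.
    """
    idx = surface_voxel_indices(mask)
    centers = _physical(idx, mask.spacing)
    if len(centers) > 4:
        try:
            centers = centers[ConvexHull(centers).vertices]
        except QhullError:
            pass
    dz, dy, dx = mask.spacing
    offsets = np.array(list(itertools.product((-dz / 2, dz / 2),
                                              (-dy / 2, dy / 2),
                                              (-dx / 2, dx / 2))))
    corners = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    corners = np.unique(corners, axis=0)
    if len(corners) > 8:
        try:
            corners = corners[ConvexHull(corners).vertices]
        except QhullError:
            pass
    return corners


def ellipsoidity(mask: SegmentationMask, tolerance: float = 1e-6) -> float:
    """Ratio of planimetric volume to the volume of the tumor's MVEE.

    The MVEE is fitted to the box corners of all surface voxels, which by
    convexity contains every foreground voxel box, so the result lies in
    (0, 1]. 1 means perfectly ellipsoidal; lower values mean irregular shape.
    """
    v_mm3 = planimetric_volume(mask) * 1000.0
    ell = mvee(_corner_cloud(mask), tolerance=tolerance)
    return v_mm3 / ell.volume


def morphometry(
    mask: SegmentationMask,
    with_ellipsoidity: bool = True,
    mvee_tolerance: float = 1e-6,
) -> TumorMorphometry:
    """Compute all morphometric parameters for a single-component tumor mask.

    Raises on empty masks and on masks with more than one 26-connected
    foreground component (the study design includes only solitary tumors).
    ``with_ellipsoidity=False`` skips the MVEE, which dominates the runtime.
    """
    _require_foreground(mask)
    _, n_comp = ndimage.label(mask.voxels, structure=_FULL_STRUCT)
    if n_comp > 1:
        raise MultiComponentError(
            f"mask '{mask.case_id}' has {n_comp} connected components; expected 1"
        )
    v_plan = planimetric_volume(mask)
    slice_idx, s = max_area_slice(mask)
    a, b = inplane_axes(mask, slice_idx)
    h, n_slices = tumor_height(mask)
    diam = max_diameter(mask)
    ell = ellipsoidity(mask, tolerance=mvee_tolerance) if with_ellipsoidity else None
    return TumorMorphometry(
        case_id=mask.case_id,
        v_plan=v_plan,
        s=s,
        a=a,
        b=b,
        h=h,
        max_diameter=diam,
        ellipsoidity=ell,
        n_slices=n_slices,
        max_slice_index=slice_idx,
    )
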