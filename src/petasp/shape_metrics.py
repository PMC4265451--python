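"""Shape and uptake metrics of a segmented lesion.

The central quantity is the asphericity

    ASP = 100 * [ (S^3 / (36 pi V^2))^(1/3) - 1 ]  (percent),

the relative excess of the lesion surface S over the surface of the
sphere with the same volume V, ``(36 pi V^2)^(1/3)``.  ASP is zero for a
sphere, positive for every other shape (isoperimetric inequality), and
invariant under spatial scaling.  Solidity is the complementary
convexity measure: the fraction of voxels inside the convex hull of the
ROI that belong to the ROI itself.

Surfaces are estimated by extracting the 0.5 iso-surface of the binary
mask (marching cubes, anisotropic spacing respected) and relaxing the
staircase artifacts with Taubin mesh smoothing, which flattens the
voxelization ripple without the global shrinkage of a pure Laplacian
filter.  Raw voxel-face counting overestimates the area of smooth
shapes by up to ~50% and would bias ASP upward for spheres; it remains
available as ``method="voxel"`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from .pet_io import VoxelGrid


@dataclass(frozen=True)
class LesionGeometry:
    """Surface/volume pair of a lesion plus the triangle mesh it came from.

    ``surface_mm2`` is the total triangle area; for masks with internal
    cavities the mesh contains both the outer and the inner closed
    surface and ``surface_mm2`` is their sum (this is what makes necrosis
    raise ASP).  ``volume_mm3`` is the enclosed material volume computed
    from the same mesh by the divergence theorem, so the (S, V) pair is
    geometrically consistent.
    """

    surface_mm2: float
    volume_mm3: float
    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) vertex indices

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0


@dataclass(frozen=True)
class LesionMetrics:
    """Per-lesion summary: uptake statistics, volume and shape."""

    suv_max: float
    suv_mean: float
    mtv_ml: float
    tlg_ml: float
    asp_pct: float
    solidity: float
    surface_mm2: float


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    return mask.astype(bool)


def mask_volume(mask: np.ndarray, grid: VoxelGrid) -> float:
    """Metabolic tumor volume: voxel count times voxel volume, in ml."""
    mask = _as_bool_mask(mask)
    if mask.shape != grid.shape:
        raise ValueError("mask and grid shapes differ")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    return n * grid.voxel_volume_ml


def surface_area(
    mask: np.ndarray,
    grid: VoxelGrid,
    method: str = "mesh",
    taubin_iterations: int | str = "auto",
) -> LesionGeometry:
    """Estimate the lesion surface (and mesh-enclosed volume).

    Parameters
    ----------
    method : {"mesh", "voxel"}
        "mesh": marching cubes at level 0.5 on the binary mask (vertex
        coordinates scaled by the anisotropic spacing) followed by
        Taubin smoothing of the mesh (lambda 0.5, mu -0.53), which
        removes the staircase area excess (~8-10% on digitized balls)
        while leaving flat faces and enclosed volume nearly unchanged.
        "voxel": sum of exposed voxel faces — simple but biased upward
        for smooth shapes; volume is then the voxel-count volume.
    taubin_iterations : int or "auto"
        Smoothing passes (mesh method only); 0 disables smoothing.
        "auto" scales the pass count with the inverse squared voxel
        size (40 at 1 mm isotropic) so the smoothed physical scale is
        resolution-independent and estimates converge toward the
        continuous surface under grid refinement.
    """
    mask = _as_bool_mask(mask)
    if mask.shape != grid.shape:
        raise ValueError("mask and grid shapes differ")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    if n < 2:
        raise ValueError("single-voxel mask is below surface resolution")

    if method == "voxel":
        return _voxel_face_geometry(mask, grid)
    if method != "mesh":
        raise ValueError(f"unknown surface method {method!r}")

    # pad so the iso-surface closes even if the mask touches the border
    pad = 2
    padded = np.pad(mask.astype(float), pad)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=grid.spacing)
    verts = verts - pad * np.asarray(grid.spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if taubin_iterations == "auto":
        h = float(np.prod(grid.spacing)) ** (1.0 / 3.0)
        taubin_iterations = int(np.clip(round(40.0 / h**2), 5, 300))
    if taubin_iterations > 0:
        trimesh.smoothing.filter_taubin(
            mesh, lamb=0.5, nu=0.53, iterations=taubin_iterations
        )
    # signed volume; marching-cubes orientation is consistent per closed
    # component, so internal cavities subtract as they should
    return LesionGeometry(
        surface_mm2=float(mesh.area),
        volume_mm3=abs(float(mesh.volume)),
        vertices=np.asarray(mesh.vertices),
        faces=np.asarray(mesh.faces),
    )


def _voxel_face_geometry(mask: np.ndarray, grid: VoxelGrid) -> LesionGeometry:
    dx, dy, dz = grid.spacing
    face_areas = (dy * dz, dx * dz, dx * dy)
    padded = np.pad(mask, 1)
    area = 0.0
    for axis, fa in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        area += fa * float(np.abs(diff).sum())
    volume = float(mask.sum()) * grid.voxel_volume_mm3
    return LesionGeometry(
        surface_mm2=area,
        volume_mm3=volume,
        vertices=np.empty((0, 3)),
        faces=np.empty((0, 3), dtype=int),
    )


def asphericity(surface: float, volume: float) -> float:
    """ASP in percent from a surface/volume pair in consistent units.

    ``asphericity(S, V) = 100 * ((S**3 / (36 pi V**2))**(1/3) - 1)``.
    Scale-invariant: ``asphericity(l**2 S, l**3 V)`` is identical for any
    ``l > 0``.  Zero for an exact sphere.
    """
    if surface <= 0 or volume <= 0:
        raise ValueError("surface and volume must be positive")
    ratio = surface**3 / (36.0 * np.pi * volume**2)
    return 100.0 * (ratio ** (1.0 / 3.0) - 1.0)


def solidity(mask: np.ndarray, grid: VoxelGrid | None = None) -> float:
    """Fraction of convex-hull voxels that belong to the ROI.

    The hull is taken over ROI voxel centers in physical coordinates; the
    denominator counts grid voxels whose centers lie inside or on the
    hull (boundary inclusive, tolerance 1e-9 relative to the hull
    diameter).  1.0 for convex lesions.
    """
    mask = _as_bool_mask(mask)
    idx = np.argwhere(mask)
    if len(idx) < 4:
        raise ValueError("need at least 4 ROI voxels for a 3D hull")
    spacing = np.asarray(grid.spacing) if grid is not None else np.ones(3)
    pts = (idx + 0.5) * spacing
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("degenerate (coplanar or collinear) ROI") from exc

    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    grids = np.meshgrid(*(np.arange(lo[k], hi[k] + 1) for k in range(3)), indexing="ij")
    cand = np.stack([g.ravel() for g in grids], axis=1)
    cand_pts = (cand + 0.5) * spacing

    diameter = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    tol = 1e-9 * max(diameter, 1.0)
    # hull.equations: A x + b <= 0 inside
    inside = np.all(
        cand_pts @ hull.equations[:, :3].T + hull.equations[:, 3] <= tol, axis=1
    )
    n_hull = int(inside.sum())
    return float(mask.sum()) / n_hull


def suv_stats(grid: VoxelGrid, mask: np.ndarray) -> tuple[float, float]:
    """(SUVmax, SUVmean) over the mask: max and arithmetic mean."""
    mask = _as_bool_mask(mask)
    if mask.shape != grid.shape:
        raise ValueError("mask and grid shapes differ")
    vals = grid.values[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(vals.max()), float(vals.mean())


def tlg(mtv_ml: float, suv_mean: float) -> float:
    """Total lesion glycolysis: MTV (ml) times SUVmean."""
    if mtv_ml <= 0 or suv_mean <= 0:
        raise ValueError("MTV and SUVmean must be positive")
    return mtv_ml * suv_mean


def lesion_report(
    grid: VoxelGrid,
    mask: np.ndarray,
    surface_method: str = "mesh",
) -> LesionMetrics:
    """Compute the full per-lesion record.

    MTV is the voxel-count volume (the VOI volume).  ASP uses the
    mesh-consistent (S, V) pair from :func:`surface_area` so that the
    sphere null (ASP -> 0) holds under discretization.  Component
    failures are re-raised with the failing metric named.
    """
    failures = []
    mtv = smax = smean = asp = sol = surf = None
    try:
        mtv = mask_volume(mask, grid)
    except ValueError as exc:
        failures.append(f"mask_volume: {exc}")
    try:
        smax, smean = suv_stats(grid, mask)
    except ValueError as exc:
        failures.append(f"suv_stats: {exc}")
    try:
        geom = surface_area(mask, grid, method=surface_method)
        surf = geom.surface_mm2
        asp = asphericity(geom.surface_mm2, geom.volume_mm3)
    except ValueError as exc:
        failures.append(f"surface_area/asphericity: {exc}")
    try:
        sol = solidity(mask, grid)
    except ValueError as exc:
        failures.append(f"solidity: {exc}")
    if failures:
        raise ValueError("lesion_report failed: " + "; ".join(failures))
    return LesionMetrics(
        suv_max=smax,
        suv_mean=smean,
        mtv_ml=mtv,
        tlg_ml=tlg(mtv, smean),
        asp_pct=asp,
        solidity=sol,
        surface_mm2=surf,
    )
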