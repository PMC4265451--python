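"""Background-corrected adaptive threshold delineation.

The metabolically active tumor volume is delineated by iterating a
volume-reproducing threshold defined relative to the local background:

    T_{k+1} = B_k + f * (mAV_k - B_k)

where ``mAV_k`` is the mean uptake inside the current mask, ``B_k`` the
mean uptake in a thin shell around it, and ``f`` the volume-reproducing
fraction (default 0.39; calibratable against phantoms of known volume).
The mask at each step is the 26-connected component containing the seed
among voxels with value >= T (closed threshold).  On a noiseless
two-level image the iteration reaches its fixed point
``T = B + f * (uptake - B)`` in one step after initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pet_io import VoxelGrid

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Delineation failure; carries the last two iteration states."""

    def __init__(self, message: str, last_thresholds: tuple | None = None):
        super().__init__(message)
        self.last_thresholds = last_thresholds


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the adaptive threshold iteration.

    threshold_fraction : f in (0, 1), the volume-reproducing fraction.
    shell_gap, shell_width : background shell geometry in voxels — the
        shell is the dilation by ``gap + width`` minus the dilation by
        ``gap`` voxels, keeping the estimate clear of the blurred edge.
    tol : relative convergence tolerance on the threshold change,
        compared against ``tol * (mAV - B)``.
    bbox : optional ``((i0, i1), (j0, j1), (k0, k1))`` half-open voxel
        bounding box restricting the seed search (the user's VOI box).
    seed_point : optional explicit seed voxel index, overrides bbox.
    """

    threshold_fraction: float = 0.39
    shell_gap: int = 1
    shell_width: int = 2
    tol: float = 0.01
    max_iter: int = 50
    bbox: tuple | None = None
    seed_point: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.shell_gap < 0:
            raise ValueError("shell_gap must be >= 0")
        if self.shell_width < 1:
            raise ValueError("shell_width must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class LesionMask:
    """A binary lesion mask with provenance bookkeeping."""

    values: np.ndarray
    provenance: str = "auto"  # auto | auto+corrected | external

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=bool))
        if self.provenance not in ("auto", "auto+corrected", "external"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass(frozen=True)
class SegmentationResult:
    mask: LesionMask
    threshold: float
    background: float
    mean_uptake: float
    n_iter: int
    threshold_history: tuple = field(default_factory=tuple)


def estimate_background(
    grid: VoxelGrid,
    mask: np.ndarray,
    gap: int = 1,
    width: int = 2,
    exclude: tuple[np.ndarray, ...] = (),
) -> float:
    """Mean value in a shell around the mask.

    The shell is ``dilate(mask, gap + width) & ~dilate(mask, gap)``;
    voxels belonging to any mask in ``exclude`` (e.g. other lesions) are
    removed from it.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    outer = ndimage.binary_dilation(mask, _STRUCT_26, iterations=gap + width)
    inner = ndimage.binary_dilation(mask, _STRUCT_26, iterations=gap) if gap > 0 else mask
    shell = outer & ~inner
    for other in exclude:
        shell &= ~np.asarray(other, dtype=bool)
    if not shell.any():
        raise ValueError("empty background shell (mask fills the grid?)")
    return float(grid.values[shell].mean())


def _seed_component(values: np.ndarray, threshold: float, seed: tuple) -> np.ndarray:
    above = values >= threshold
    labels, _ = ndimage.label(above, structure=_STRUCT_26)
    lab = labels[seed]
    if lab == 0:
        return np.zeros_like(above)
    return labels == lab


def _find_seed(values: np.ndarray, params: SegmentationParams) -> tuple[int, int, int]:
    if params.seed_point is not None:
        return tuple(int(i) for i in params.seed_point)
    if params.bbox is not None:
        (i0, i1), (j0, j1), (k0, k1) = params.bbox
        sub = values[i0:i1, j0:j1, k0:k1]
        if sub.size == 0:
            raise ValueError("empty bounding box")
        off = np.array([i0, j0, k0])
        loc = np.unravel_index(int(np.argmax(sub)), sub.shape)
        return tuple(int(x) for x in (np.array(loc) + off))
    loc = np.unravel_index(int(np.argmax(values)), values.shape)
    return tuple(int(x) for x in loc)


def adaptive_threshold_segment(
    grid: VoxelGrid,
    params: SegmentationParams | None = None,
) -> SegmentationResult:
    """Run the background-corrected adaptive threshold iteration.

    Initialisation: the global background is estimated by the image
    median (the lesion occupies a small fraction of the field of view),
    and ``T_0 = B_global + 0.5 * (local max - B_global)``.  Each
    iteration re-derives the mask, the local background B and the mean
    uptake mAV, and updates ``T = B + f * (mAV - B)`` until the change
    falls below ``tol * (mAV - B)``.
    """
    params = params or SegmentationParams()
    values = grid.values
    seed = _find_seed(values, params)
    local_max = float(values[seed])
    b_global = float(np.median(values))
    if local_max <= b_global:
        raise SegmentationError("no lesion: seed value does not exceed the image median")

    t = b_global + 0.5 * (local_max - b_global)
    history = [t]
    mask = _seed_component(values, t, seed)
    if not mask.any():
        raise SegmentationError("no voxel above the initial threshold")

    for k in range(params.max_iter):
        b = estimate_background(grid, mask, params.shell_gap, params.shell_width)
        mav = float(values[mask].mean())
        if mav <= b:
            raise SegmentationError(
                "lesion mean does not exceed local background",
                last_thresholds=tuple(history[-2:]),
            )
        t_next = b + params.threshold_fraction * (mav - b)
        history.append(t_next)
        new_mask = _seed_component(values, t_next, seed)
        if not new_mask.any():
            raise SegmentationError(
                "threshold update removed the seed voxel",
                last_thresholds=tuple(history[-2:]),
            )
        converged = abs(t_next - t) < params.tol * (mav - b)
        t, mask = t_next, new_mask
        if converged:
            return SegmentationResult(
                mask=LesionMask(mask, "auto"),
                threshold=t,
                background=b,
                mean_uptake=mav,
                n_iter=k + 1,
                threshold_history=tuple(history),
            )
    raise SegmentationError(
        f"no convergence in {params.max_iter} iterations "
        f"(last thresholds {history[-2]:.4g}, {history[-1]:.4g})",
        last_thresholds=tuple(history[-2:]),
    )


def check_min_volume(mask: np.ndarray, grid: VoxelGrid, min_ml: float = 3.0) -> bool:
    """True iff the mask volume reaches ``min_ml`` (boundary inclusive).

    Lesions below ~3 ml cannot be reliably delineated; callers should
    flag failing lesions rather than drop them silently.
    """
    mask = np.asarray(mask, dtype=bool)
    volume_ml = float(mask.sum()) * grid.voxel_volume_ml
    return bool(volume_ml >= min_ml - 1e-12)
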