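"""Volume and table I/O plus SUV conversion.

PET volumes are held in :class:`VoxelGrid`, a thin container around a 3D
scalar field with anisotropic voxel spacing in millimetres.  Values are
either tracer activity concentration (MBq/ml) or standardized uptake
values (SUV, dimensionless g/ml).  Conversion between the two uses the
conventional body-weight normalisation with physical decay correction of
the injected dose to the start of the emission scan.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: F-18 physical half-life in minutes.
F18_HALF_LIFE_MINUTES = 109.77

#: Required column schema of cohort tables (one row per subject/endpoint).
COHORT_COLUMNS = (
    "id",
    "suvmax",
    "suvmean",
    "mtv_ml",
    "tlg_ml",
    "asp_pct",
    "solidity",
    "time_months",
    "event",
    "endpoint",
)


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar field with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values, activity concentration (MBq/ml) or SUV.
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in mm; all strictly positive.
    origin : tuple of float
        Physical coordinate (mm) of the corner of voxel (0, 0, 0).
    value_kind : {"activity", "suv"}
        Physical meaning of the values.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    value_kind: str = "activity"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.value_kind not in ("activity", "suv"):
            raise ValueError(f"value_kind must be 'activity' or 'suv', got {self.value_kind!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of voxel centers along each axis.

        Centers sit at ``origin + (i + 0.5) * spacing``.
        """
        return tuple(
            self.origin[k] + (np.arange(self.shape[k]) + 0.5) * self.spacing[k]
            for k in range(3)
        )

    def with_values(self, values: np.ndarray, value_kind: str | None = None) -> "VoxelGrid":
        return dataclasses.replace(
            self, values=values, value_kind=value_kind or self.value_kind
        )


@dataclass(frozen=True)
class AcquisitionInfo:
    """Acquisition metadata needed for SUV conversion.

    ``injection_to_scan_minutes`` is the delay between tracer injection
    and the start of the emission scan; the injected dose is decayed over
    this interval before normalisation.
    """

    injected_dose_mbq: float
    injection_to_scan_minutes: float = 0.0
    body_weight_kg: float = 70.0
    half_life_minutes: float = F18_HALF_LIFE_MINUTES

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.injection_to_scan_minutes < 0:
            raise ValueError("injection-to-scan delay must be non-negative")
        if self.half_life_minutes <= 0:
            raise ValueError("half-life must be positive")


def decay_correct(
    dose_mbq: float,
    delay_minutes: float,
    half_life_minutes: float = F18_HALF_LIFE_MINUTES,
) -> float:
    """Physical decay of an activity over ``delay_minutes``.

    Returns ``dose * 2**(-delay / half_life)``; with the delay equal to the
    injection-to-scan interval this is the dose "decay corrected to the
    start time" of the scan.
    """
    if dose_mbq <= 0:
        raise ValueError("dose must be positive")
    if half_life_minutes <= 0:
        raise ValueError("half-life must be positive")
    if delay_minutes < 0:
        raise ValueError("delay must be non-negative")
    return float(dose_mbq) * 2.0 ** (-float(delay_minutes) / float(half_life_minutes))


def to_suv(grid: VoxelGrid, acq: AcquisitionInfo) -> VoxelGrid:
    """Convert an activity-concentration volume to SUV (body weight).

    SUV = concentration (MBq/ml) / (decay-corrected dose (MBq) / body
    weight (g)).  Body weight is converted from kg to grams so that the
    result is the conventional dimensionless g/ml quantity.
    """
    if grid.value_kind != "activity":
        raise ValueError("grid is already in SUV units")
    dose = decay_correct(
        acq.injected_dose_mbq, acq.injection_to_scan_minutes, acq.half_life_minutes
    )
    weight_g = acq.body_weight_kg * 1000.0
    return grid.with_values(grid.values * (weight_g / dose), value_kind="suv")


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid (or a binary mask wrapped in a grid) as NIfTI.

    Spacing goes into the affine diagonal, origin into the translation.
    """
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(grid.values.astype(np.float32), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path, value_kind: str = "activity") -> VoxelGrid:
    """Read a 3D NIfTI volume; spacing from the affine column norms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {np.asanyarray(img.dataobj).shape}")
    affine = img.affine
    spacing = tuple(float(np.linalg.norm(affine[:3, k])) for k in range(3))
    if any(s <= 0 for s in spacing):
        raise ValueError("volume has non-positive voxel spacing in header")
    origin = tuple(float(x) for x in affine[:3, 3])
    return VoxelGrid(data.astype(float), spacing=spacing, origin=origin, value_kind=value_kind)


def write_mask(mask: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Write a binary mask aligned to ``grid`` as NIfTI (uint8)."""
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 3:
        raise ValueError("mask must be 3D")
    return data > 0.5


# ---------------------------------------------------------------------------
# Cohort tables


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as comma-separated UTF-8 CSV with header."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    table.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if (table["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return table
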