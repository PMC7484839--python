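"""Core domain types shared across the verification pipeline.

All grids live on the DICOM patient coordinate system (LPS), in mm, with a
voxel-center convention and 0-based indices.  Arrays are stored C-ordered
with shape ``(nz, ny, nx)`` so that x is the fastest-varying axis, matching
the on-disk raster order of the batch interchange format.  Dose grids are
always co-registered to the CT grid they were scored on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

HU_MIN = -1024
HU_MAX = 4000

DoseUnit = str  # one of {"Gy", "Gy_per_particle", "keV_per_um"}
DOSE_UNITS = ("Gy", "Gy_per_particle", "keV_per_um")


class PipelineError(Exception):
    """Base class for all pipeline errors."""


class IntegrityError(PipelineError):
    """Input data failed an integrity/consistency check."""


class GeometryMismatchError(PipelineError):
    """Two grids expected to share a geometry do not."""


@dataclass(frozen=True)
class Geometry:
    """Regular-grid geometry: shape, spacing and origin in patient (LPS) mm.

    ``origin`` is the patient-space position of the *center* of voxel
    (0, 0, 0); ``spacing`` is ``(dx, dy, dz)``.  Orientation is restricted
    to the identity (axis-aligned HFS acquisitions), which is what the
    pipeline's scoring and fixtures produce.
    """

    shape: tuple[int, int, int]  # (nz, ny, nx)
    spacing: tuple[float, float, float]  # (dx, dy, dz) mm
    origin: tuple[float, float, float]  # (x, y, z) mm of voxel (0,0,0) center
    orientation: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)
    patient_position: str = "HFS"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 2 for n in self.shape):
            raise ValueError(f"grid dimensions must be >= 2 per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axis_coords(self, axis: str) -> np.ndarray:
        """Patient-space voxel-center coordinates along ``axis`` ('x'|'y'|'z')."""
        i = "xyz".index(axis)
        n = self.shape[2 - i]  # shape is (nz, ny, nx)
        return self.origin[i] + self.spacing[i] * np.arange(n)

    def same_grid(self, other: "Geometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class CTVolume:
    """A 3D Hounsfield-unit grid with geometry, the substrate for all scoring."""

    hu: np.ndarray  # int grid, shape (nz, ny, nx)
    geometry: Geometry
    frame_of_reference_uid: str = ""

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.shape != self.geometry.shape:
            raise ValueError(
                f"HU grid shape {self.hu.shape} != geometry shape {self.geometry.shape}"
            )
        lo, hi = int(self.hu.min()), int(self.hu.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(f"HU out of range [{HU_MIN}, {HU_MAX}]: [{lo}, {hi}]")

    def copy(self) -> "CTVolume":
        return CTVolume(self.hu.copy(), self.geometry, self.frame_of_reference_uid)


@dataclass
class Structure:
    name: str
    mask: np.ndarray  # bool, CT grid shape
    contours: list = field(default_factory=list)  # per-slice polygons [(z, Nx2 array)]


@dataclass
class StructureSet:
    structures: dict[str, Structure]
    frame_of_reference_uid: str = ""

    BODY_NAMES = ("body", "external", "skin", "outer contour")

    def __getitem__(self, name: str) -> Structure:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def names(self) -> list[str]:
        return list(self.structures)

    def body(self) -> Structure:
        for s in self.structures.values():
            if s.name.lower() in self.BODY_NAMES:
                return s
        raise IntegrityError("no body contour in structure set")


@dataclass
class Spot:
    energy_mev: float
    x_mm: float
    y_mm: float
    mu: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"spot MU must be >= 0, got {self.mu}")


@dataclass
class FieldDef:
    """One spot-scanning field: geometry, range-shifter setting, spot list."""

    gantry_angle: float
    couch_angle: float
    isocenter: tuple[float, float, float]
    range_shifter: str = "none"  # none | board | nozzle_40mm
    spots: list[Spot] = field(default_factory=list)
    name: str = ""

    RANGE_SHIFTERS = ("none", "board", "nozzle_40mm")

    def __post_init__(self) -> None:
        if self.range_shifter not in self.RANGE_SHIFTERS:
            raise ValueError(f"unknown range shifter {self.range_shifter!r}")
        if not self.spots:
            raise ValueError("field must contain at least one spot")

    @property
    def total_mu(self) -> float:
        return float(sum(s.mu for s in self.spots))

    def energies(self) -> list[float]:
        return sorted({s.energy_mev for s in self.spots})


@dataclass
class SpotPlan:
    plan_id: str
    prescription_dose_gy: float
    fields: list[FieldDef]
    frame_of_reference_uid: str = ""

    def __post_init__(self) -> None:
        if self.prescription_dose_gy <= 0:
            raise ValueError("prescription dose must be > 0")
        if not self.fields:
            raise ValueError("plan must contain at least one field")

    def energies(self) -> list[float]:
        return sorted({s.energy_mev for f in self.fields for s in f.spots})


@dataclass
class DoseGrid:
    """A non-negative 3D grid of dose (or dose-shaped LET_d) values."""

    values: np.ndarray
    unit: DoseUnit
    geometry: Geometry
    frame_of_reference_uid: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.unit not in DOSE_UNITS:
            raise ValueError(f"unknown dose unit {self.unit!r}")
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"grid shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if self.values.min() < 0:
            raise ValueError("dose grid contains negative values")

    def copy(self) -> "DoseGrid":
        return DoseGrid(self.values.copy(), self.unit, self.geometry,
                        self.frame_of_reference_uid)


@dataclass
class IntegrityReport:
    """Outcome of the pre-flight data check; never raised, always returned."""

    missing_items: list[str]
    frame_of_reference_consistent: bool

    @property
    def ok(self) -> bool:
        return not self.missing_items and self.frame_of_reference_consistent

    def summary(self) -> str:
        if self.ok:
            return "integrity check passed"
        parts = []
        if self.missing_items:
            parts.append("missing: " + ", ".join(self.missing_items))
        if not self.frame_of_reference_consistent:
            parts.append("frame of reference mismatch")
        return "; ".join(parts)


def require_same_geometry(*grids) -> Geometry:
    """Raise GeometryMismatchError unless all grids share one geometry."""
    geo = grids[0].geometry
    for g in grids[1:]:
        if not geo.same_grid(g.geometry):
            raise GeometryMismatchError(
                f"geometry mismatch: {geo.shape} vs {g.geometry.shape}"
            )
    return geo
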