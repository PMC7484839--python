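"""CT preprocessing: turn the planning CT into the treatment-condition CT.

The planning scan shows the simulation couch and possibly external objects
(blankets, positioning aids) that are absent at treatment, and omits devices
that are present (the treatment couch, an on-couch range-shifter board).
Before transport the CT is therefore edited in a fixed order:

1. every voxel outside the body contour is overridden to -1000 HU (air),
2. a model of the treatment couch is burned in below the patient,
3. an optional range-shifter board is burned in on the beam-entry side,
4. structure HU overrides from the clinical plan (surgical clips, shifting
   devices) are applied, later overrides winning on overlap.

Each step records a machine-readable provenance entry (rule, voxel count)
so the edit trail can be audited.  No step other than a named override may
modify a voxel inside the body.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    HU_MAX,
    HU_MIN,
    CTVolume,
    GeometryMismatchError,
    PipelineError,
    StructureSet,
)

log = logging.getLogger(__name__)

AIR_HU = -1000


@dataclass(frozen=True)
class HUOverride:
    """Set all voxels of a named structure to a fixed HU value."""

    target: str
    hu_value: int

    def __post_init__(self) -> None:
        if not HU_MIN <= self.hu_value <= HU_MAX:
            raise ValueError(f"override HU {self.hu_value} outside [{HU_MIN}, {HU_MAX}]")


@dataclass(frozen=True)
class CouchSlab:
    thickness_mm: float
    width_mm: float
    hu_value: int

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("slab thickness must be > 0")


@dataclass(frozen=True)
class CouchModel:
    """Treatment couch as a stack of uniform slabs below the patient.

    Slabs are ordered top (closest to the patient surface) to bottom and
    burned in along +y (posterior in LPS) starting ``offset_mm`` below the
    posterior-most body surface.  The default is a foam-like core under a
    thin hard shell, configurable per institution.
    """

    slabs: tuple[CouchSlab, ...] = (
        CouchSlab(thickness_mm=10.0, width_mm=400.0, hu_value=200),
        CouchSlab(thickness_mm=50.0, width_mm=400.0, hu_value=-700),
    )
    offset_mm: float = 5.0


@dataclass(frozen=True)
class BoardGeometry:
    """On-couch range-shifter board: a slab perpendicular to the beam axis.

    ``entry_face_mm`` is the patient-space coordinate (along the beam axis)
    of the face closest to the body; the board extends ``thickness_mm``
    away from the patient.  ``axis`` is the beam axis ('x' or 'y') and
    ``direction`` +1 if the beam travels toward +axis.
    """

    thickness_mm: float
    entry_face_mm: float
    axis: str = "y"
    direction: int = -1  # beam travels toward -axis => board on +axis side
    half_width_mm: float = 200.0


@dataclass(frozen=True)
class DensityCurve:
    """Piecewise-linear HU -> mass density (g/cm^3) conversion.

    The curve is scanner-dependent; the default 5-point curve spans air,
    lung, water, cortical bone and a metal cap, and is clamped at its
    endpoints.
    """

    control_points: tuple[tuple[float, float], ...] = (
        (-1000.0, 0.00121),
        (-700.0, 0.30),
        (0.0, 1.00),
        (1500.0, 1.85),
        (3000.0, 2.8),
    )

    def __post_init__(self) -> None:
        hu = np.array([p[0] for p in self.control_points])
        rho = np.array([p[1] for p in self.control_points])
        if not np.all(np.diff(hu) > 0):
            raise ValueError("density curve HU values must be strictly increasing")
        if np.any(rho < 0):
            raise ValueError("density must be >= 0")

    def __call__(self, hu) -> np.ndarray:
        return hu_to_density(hu, self)


@dataclass
class ProvenanceEntry:
    rule: str
    voxels_changed: int
    detail: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"rule": self.rule, "voxels_changed": self.voxels_changed,
                **self.detail}


def _check_mask(ct: CTVolume, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ct.geometry.shape:
        raise GeometryMismatchError(
            f"mask shape {mask.shape} != CT shape {ct.geometry.shape}"
        )
    return mask


def override_outside_body(
    ct: CTVolume, body_mask: np.ndarray,
    provenance: list[ProvenanceEntry] | None = None,
) -> CTVolume:
    """Override every voxel outside the body contour to -1000 HU (air).

    Removes the simulation couch, external artifacts and anything else not
    present at treatment.  Idempotent; voxels inside the body are untouched.
    """
    body_mask = _check_mask(ct, body_mask)
    out = ct.copy()
    outside = ~body_mask
    changed = int(np.count_nonzero(outside & (ct.hu != AIR_HU)))
    out.hu[outside] = AIR_HU
    if provenance is not None:
        provenance.append(ProvenanceEntry("override_outside_body", changed))
    return out


def replace_couch(
    ct: CTVolume, body_mask: np.ndarray, couch: CouchModel,
    provenance: list[ProvenanceEntry] | None = None,
) -> CTVolume:
    """Burn the treatment couch model in below the posterior body surface.

    Assumes the outside-body air override has already removed the
    simulation couch.  Slabs are stacked along +y (posterior) starting at
    the configured offset below the posterior-most body voxel, centred
    laterally on the body.  Raises if a slab would intersect the body.
    """
    body_mask = _check_mask(ct, body_mask)
    if not body_mask.any():
        raise PipelineError("empty body mask; cannot locate couch position")
    geo = ct.geometry
    ys = geo.axis_coords("y")
    xs = geo.axis_coords("x")
    iz, iy, ix = np.nonzero(body_mask)
    y_post = ys[iy.max()] + geo.spacing[1] / 2.0  # posterior body surface
    x_mid = float(xs[ix.min()] + xs[ix.max()]) / 2.0
    out = ct.copy()
    total_changed = 0
    y_top = y_post + couch.offset_mm
    for slab in couch.slabs:
        sel_y = (ys >= y_top) & (ys < y_top + slab.thickness_mm)
        sel_x = np.abs(xs - x_mid) <= slab.width_mm / 2.0
        if not sel_y.any():
            log.warning("couch slab at y=[%.1f, %.1f] mm falls outside the grid",
                        y_top, y_top + slab.thickness_mm)
            y_top += slab.thickness_mm
            continue
        region = (
            np.ones((geo.shape[0], 1, 1), dtype=bool)
            & sel_y[None, :, None]
            & sel_x[None, None, :]
        )
        if (region & body_mask).any():
            raise PipelineError("couch model intersects the body mask")
        changed = int(np.count_nonzero(region))
        out.hu[region] = slab.hu_value
        total_changed += changed
        y_top += slab.thickness_mm
    if provenance is not None:
        provenance.append(ProvenanceEntry(
            "replace_couch", total_changed,
            {"n_slabs": len(couch.slabs), "offset_mm": couch.offset_mm}))
    return out


def apply_overrides(
    ct: CTVolume, structures: StructureSet, overrides: list[HUOverride],
    provenance: list[ProvenanceEntry] | None = None,
) -> CTVolume:
    """Apply structure HU overrides in list order; later overrides win."""
    out = ct.copy()
    for ov in overrides:
        if ov.target not in structures:
            raise PipelineError(f"override target {ov.target!r} not in structure set")
        mask = _check_mask(ct, structures[ov.target].mask)
        changed = int(np.count_nonzero(mask & (out.hu != ov.hu_value)))
        out.hu[mask] = ov.hu_value
        if provenance is not None:
            provenance.append(ProvenanceEntry(
                "apply_override", changed,
                {"target": ov.target, "hu_value": ov.hu_value}))
    return out


def burn_range_shifter_board(
    ct: CTVolume, body_mask: np.ndarray, board: BoardGeometry, hu_value: int,
    provenance: list[ProvenanceEntry] | None = None,
) -> CTVolume:
    """Burn an on-couch range-shifter board into the CT on the entry side."""
    if not HU_MIN <= hu_value <= HU_MAX:
        raise ValueError(f"board HU {hu_value} outside [{HU_MIN}, {HU_MAX}]")
    body_mask = _check_mask(ct, body_mask)
    out = ct.copy()
    if board.thickness_mm == 0:
        if provenance is not None:
            provenance.append(ProvenanceEntry("burn_range_shifter_board", 0,
                                              {"thickness_mm": 0.0}))
        return out
    if board.thickness_mm < 0:
        raise ValueError("board thickness must be >= 0")
    geo = ct.geometry
    coords = geo.axis_coords(board.axis)
    # board spans [entry_face, entry_face + thickness] away from the patient
    if board.direction < 0:  # beam toward -axis: board on the +axis... no:
        # beam travels toward -axis means it enters from +axis side; the
        # board sits upstream, i.e. at coordinates >= entry_face
        lo, hi = board.entry_face_mm, board.entry_face_mm + board.thickness_mm
    else:
        lo, hi = board.entry_face_mm - board.thickness_mm, board.entry_face_mm
    sel = (coords >= lo) & (coords < hi)
    perp = "x" if board.axis == "y" else "y"
    pcoords = geo.axis_coords(perp)
    iz, iy, ix = np.nonzero(body_mask) if body_mask.any() else (None, None, None)
    if ix is not None:
        pidx = ix if perp == "x" else iy
        p_mid = float(pcoords[pidx.min()] + pcoords[pidx.max()]) / 2.0
    else:
        p_mid = float(pcoords.mean())
    psel = np.abs(pcoords - p_mid) <= board.half_width_mm
    nz = geo.shape[0]
    if board.axis == "y":
        region = (np.ones((nz, 1, 1), bool) & sel[None, :, None] & psel[None, None, :])
    else:
        region = (np.ones((nz, 1, 1), bool) & psel[None, :, None] & sel[None, None, :])
    if (region & body_mask).any():
        raise PipelineError("range-shifter board intersects the body")
    changed = int(np.count_nonzero(region))
    out.hu[region] = hu_value
    if provenance is not None:
        provenance.append(ProvenanceEntry(
            "burn_range_shifter_board", changed,
            {"thickness_mm": board.thickness_mm, "hu_value": hu_value}))
    return out


def hu_to_density(hu, curve: DensityCurve | None = None) -> np.ndarray:
    """Convert HU to mass density (g/cm^3) by piecewise-linear interpolation.

    Clamped at the curve endpoints; monotone whenever the curve is.
    """
    if curve is None:
        curve = DensityCurve()
    pts = np.asarray(curve.control_points, dtype=float)
    return np.interp(np.asarray(hu, dtype=float), pts[:, 0], pts[:, 1])


@dataclass
class PreprocessResult:
    ct: CTVolume
    provenance: list[ProvenanceEntry]

    def provenance_dicts(self) -> list[dict]:
        return [p.as_dict() for p in self.provenance]


def preprocess_ct(
    ct: CTVolume,
    structures: StructureSet,
    couch: CouchModel | None = None,
    board: BoardGeometry | None = None,
    board_hu: int = -100,
    overrides: list[HUOverride] | None = None,
) -> PreprocessResult:
    """Run the full preprocessing chain in the canonical order.

    Order: outside-body air override -> couch burn-in -> range-shifter
    board -> structure overrides.  Returns the edited CT plus the full
    provenance trail.
    """
    prov: list[ProvenanceEntry] = []
    body = structures.body().mask
    out = override_outside_body(ct, body, prov)
    if couch is not None:
        out = replace_couch(out, body, couch, prov)
    if board is not None:
        out = burn_range_shifter_board(out, body, board, board_hu, prov)
    if overrides:
        out = apply_overrides(out, structures, overrides, prov)
    return PreprocessResult(ct=out, provenance=prov)
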