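"""Synthetic input generation: phantoms, plans, calibration, planes.

Everything the pipeline consumes can be generated here so a full
verification run needs no external data: a cylindrical water phantom CT
series (with a simulation couch, an external artifact and internal
inserts, so preprocessing has real work to do), a body + insert structure
set, one- or two-field spot-scanning plans, a particles-per-MU calibration
table consistent with the mock engine, and measured-plane fixtures derived
from a noiseless mock-engine reference run (optionally perturbed for
negative gamma tests).

Defaults emulate the study conditions at desk scale: a 48 x 80 x 24 voxel
grid at 3 mm spacing stands in for the clinical 512 x 512 x N scoring
grid, and 5 batches x 2e4 histories stand in for 50 batches x 4e6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dicom_io
from .combine import CalibrationTable, combine_batches, derive_calibration
from .core import CTVolume, DoseGrid, FieldDef, Geometry, Spot, SpotPlan
from .engine import (
    MACHINE_ENERGIES,
    JobSpec,
    MockEngine,
    MockEngineConfig,
    plan_to_jobs,
)
from .gamma import MeasurementPlane, extract_plane
from .preprocess import DensityCurve

FIXTURE_N_BATCHES = 5
FIXTURE_HISTORIES = 20_000


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical water phantom with couch, artifact and inserts."""

    shape: tuple[int, int, int] = (24, 80, 48)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    body_radius_mm: float = 45.0
    body_hu: int = 0
    insert_bone: bool = True  # 12 mm-radius bone sphere, 800 HU
    insert_clip: bool = True  # small clip cube, 100 HU, override target
    sim_couch: bool = True  # simulation couch slab outside the body
    artifact: bool = True  # +500 HU external blob (blanket-like)


def make_phantom_ct(spec: PhantomSpec = PhantomSpec()) -> CTVolume:
    """Build the phantom CT volume (axis of the cylinder along z)."""
    nz, ny, nx = spec.shape
    dx, dy, dz = spec.spacing
    # center the grid on the patient axis
    origin = (-(nx - 1) * dx / 2.0, -(ny - 1) * dy / 2.0, 0.0)
    geo = Geometry(shape=spec.shape, spacing=spec.spacing, origin=origin)
    xs, ys = geo.axis_coords("x"), geo.axis_coords("y")
    zs = geo.axis_coords("z")
    gx = xs[None, None, :]
    gy = ys[None, :, None]
    gz = zs[:, None, None]
    hu = np.full(spec.shape, -1000, dtype=np.int32)
    r2 = gx**2 + gy**2
    body = r2 <= spec.body_radius_mm**2
    hu[np.broadcast_to(body, spec.shape)] = spec.body_hu
    if spec.insert_bone:
        bone = (gx - 20.0) ** 2 + (gy - 10.0) ** 2 + (
            gz - zs[nz // 2]) ** 2 <= 12.0**2
        hu[bone] = 800
    if spec.insert_clip:
        clip = ((np.abs(gx + 25.0) <= 5.0) & (np.abs(gy + 15.0) <= 5.0)
                & (np.abs(gz - zs[nz // 2]) <= 5.0))
        hu[clip] = 100
    if spec.sim_couch:
        couch_y = spec.body_radius_mm + 12.0
        couch = (gy >= couch_y) & (gy <= couch_y + 24.0) & (np.abs(gx) <= 66.0)
        hu[np.broadcast_to(couch, spec.shape)] = -600
    if spec.artifact:
        blob = (gx + 66.0) ** 2 + (gy + 45.0) ** 2 + (
            gz - zs[nz // 3]) ** 2 <= 9.0**2
        hu[blob] = 500
    from pydicom.uid import generate_uid

    return CTVolume(hu, geo, frame_of_reference_uid=generate_uid())


def phantom_contours(ct: CTVolume, spec: PhantomSpec = PhantomSpec(),
                     n_vertices: int = 128) -> dict:
    """Contour polygons for the phantom: body cylinder and clip insert."""
    zs = ct.geometry.axis_coords("z")
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    circle = spec.body_radius_mm * np.column_stack([np.cos(theta), np.sin(theta)])
    contours = {"BODY": [(float(z), circle) for z in zs]}
    if spec.insert_clip:
        nz = ct.geometry.shape[0]
        square = np.array([[-30.0, -20.0], [-20.0, -20.0],
                           [-20.0, -10.0], [-30.0, -10.0]])
        zmid = zs[nz // 2]
        clip_slices = [float(z) for z in zs if abs(z - zmid) <= 5.0]
        contours["CLIP"] = [(z, square) for z in clip_slices]
    return contours


def make_plan(
    ct: CTVolume,
    energies: tuple[float, ...] = (92.5, 97.0, 101.5),
    n_spots_side: int = 5,
    spot_spacing_mm: float = 6.0,
    rx_gy: float = 2.0,
    gantry_angle: float = 0.0,
    range_shifter: str = "none",
    two_fields: bool = False,
) -> SpotPlan:
    """A spot plan on the phantom: square spot grids per energy layer.

    Spot MU values are uniform and normalized downstream (the fixture
    pipeline scales the plan so the calculated maximum equals the
    prescription; see :func:`normalize_plan_mu`).
    """
    for e in energies:
        assert any(abs(e - m) < 1e-6 for m in MACHINE_ENERGIES), e
    nz = ct.geometry.shape[0]
    iso = (0.0, 0.0, float(ct.geometry.axis_coords("z")[nz // 2]))
    half = (n_spots_side - 1) / 2.0
    offsets = (np.arange(n_spots_side) - half) * spot_spacing_mm
    spots = [
        Spot(energy_mev=e, x_mm=float(sx), y_mm=float(sy), mu=1.0)
        for e in energies for sx in offsets for sy in offsets
    ]
    fields = [FieldDef(gantry_angle=gantry_angle, couch_angle=0.0,
                       isocenter=iso, range_shifter=range_shifter,
                       spots=spots, name="F1")]
    if two_fields:
        spots2 = [Spot(s.energy_mev, s.x_mm, s.y_mm, s.mu) for s in spots]
        fields.append(FieldDef(gantry_angle=180.0, couch_angle=0.0,
                               isocenter=iso, range_shifter=range_shifter,
                               spots=spots2, name="F2"))
    return SpotPlan(plan_id="SYNTH-PLAN", prescription_dose_gy=rx_gy,
                    fields=fields,
                    frame_of_reference_uid=ct.frame_of_reference_uid)


# ---------------------------------------------------------------------------
# Calibration consistent with the mock engine


def make_water_phantom(depth_mm: float = 80.0) -> CTVolume:
    """Small water tank for single-spot calibration runs (beam along +y)."""
    ny = int(round(depth_mm / 2.0))
    geo = Geometry(shape=(15, ny, 15), spacing=(3.0, 2.0, 3.0),
                   origin=(-21.0, 1.0, 0.0))  # entry surface at y = 0
    hu = np.zeros(geo.shape, dtype=np.int32)
    return CTVolume(hu, geo)


def simulated_dose_per_particle(
    energies,
    depth_mm: float = 20.0,
    engine: MockEngine | None = None,
    curve: DensityCurve | None = None,
) -> list[tuple[float, float]]:
    """Noiseless single-spot mock runs scoring dose at depth in water."""
    engine = engine or MockEngine(noiseless=True)
    curve = curve or DensityCurve()
    water = make_water_phantom()
    geo = water.geometry
    iy = int(np.argmin(np.abs(geo.axis_coords("y") - depth_mm)))
    iz, ix = geo.shape[0] // 2, geo.shape[2] // 2
    out = []
    for e in energies:
        job = JobSpec(field_index=0, batch_index=0, n_batches=1, histories=1,
                      seed=0, spots=(Spot(e, 0.0, 0.0, 1.0),),
                      range_shifter="none", gantry_angle=0.0,
                      isocenter=(0.0, 0.0, float(geo.axis_coords("z")[iz])))
        res = engine.run(job, water, curve)
        out.append((float(e), float(res.dose.values[iz, iy, ix])))
    return out


def reference_particles_per_mu(energy_mev: float) -> float:
    """Fixture ground-truth particles/MU: ~2e9 at 100 MeV, rising with energy."""
    return 2.0e9 * (energy_mev / 100.0) ** 0.8


def make_calibration(
    energies=MACHINE_ENERGIES,
    engine: MockEngine | None = None,
    curve: DensityCurve | None = None,
) -> CalibrationTable:
    """Calibration table consistent with the mock engine.

    The simulated column comes from actual single-spot mock runs at 2 cm
    depth in water; the measured column is synthesized from the fixture's
    ground-truth particles-per-MU curve, so derive_calibration recovers
    that curve exactly.
    """
    simulated = simulated_dose_per_particle(energies, engine=engine, curve=curve)
    measured = [(e, dpp * reference_particles_per_mu(e)) for e, dpp in simulated]
    return derive_calibration(measured, simulated)


def normalize_plan_mu(plan: SpotPlan, ct: CTVolume,
                      calib: CalibrationTable,
                      curve: DensityCurve | None = None) -> SpotPlan:
    """Scale all spot MU so the calculated maximum dose equals Rx."""
    engine = MockEngine(noiseless=True)
    curve = curve or DensityCurve()
    total = np.zeros(ct.geometry.shape)
    from .combine import to_absolute_dose

    for fi, f in enumerate(plan.fields):
        job = JobSpec(field_index=fi, batch_index=0, n_batches=1, histories=1,
                      seed=0, spots=tuple(f.spots),
                      range_shifter=f.range_shifter,
                      gantry_angle=f.gantry_angle, isocenter=f.isocenter)
        res = engine.run(job, ct, curve)
        total += to_absolute_dose(res.dose, f, calib).values
    factor = plan.prescription_dose_gy / float(total.max())
    fields = [
        FieldDef(gantry_angle=f.gantry_angle, couch_angle=f.couch_angle,
                 isocenter=f.isocenter, range_shifter=f.range_shifter,
                 spots=[Spot(s.energy_mev, s.x_mm, s.y_mm, s.mu * factor)
                        for s in f.spots],
                 name=f.name)
        for f in plan.fields
    ]
    return SpotPlan(plan.plan_id, plan.prescription_dose_gy, fields,
                    plan.frame_of_reference_uid)


# ---------------------------------------------------------------------------
# Reference dose + measurement planes


def reference_dose(plan: SpotPlan, ct: CTVolume, calib: CalibrationTable,
                   curve: DensityCurve | None = None) -> DoseGrid:
    """Noiseless absolute dose for the plan on the (preprocessed) CT."""
    engine = MockEngine(noiseless=True)
    curve = curve or DensityCurve()
    from .combine import to_absolute_dose

    total = np.zeros(ct.geometry.shape)
    for fi, f in enumerate(plan.fields):
        job = JobSpec(field_index=fi, batch_index=0, n_batches=1, histories=1,
                      seed=0, spots=tuple(f.spots),
                      range_shifter=f.range_shifter,
                      gantry_angle=f.gantry_angle, isocenter=f.isocenter)
        res = engine.run(job, ct, curve)
        total += to_absolute_dose(res.dose, f, calib).values
    return DoseGrid(total, "Gy", ct.geometry, ct.frame_of_reference_uid)


def make_measurement_plane(
    dose: DoseGrid,
    depth_mm: float = 20.0,
    body_surface_y_mm: float = -60.0,
    shape: tuple[int, int] = (20, 20),
    spacing_mm: float = 3.0,
    scale: float = 1.0,
    shift_mm: tuple[float, float] = (0.0, 0.0),
) -> MeasurementPlane:
    """Extract an array-style measured plane at depth from a dose grid.

    The plane is normal to the beam axis (y), positioned ``depth_mm``
    beyond the anterior body surface; ``scale`` and ``shift_mm`` apply a
    controlled perturbation for negative gamma tests.
    """
    nr, nc = shape
    row0 = dose.geometry.origin[2] + (
        dose.geometry.shape[0] * dose.geometry.spacing[2]
        - (nr - 1) * spacing_mm) / 2.0
    col0 = -(nc - 1) * spacing_mm / 2.0 + shift_mm[0]
    plane = extract_plane(
        dose, axis="y", position_mm=body_surface_y_mm + depth_mm,
        origin_2d=(row0 + shift_mm[1], col0), shape=shape,
        spacing_mm=spacing_mm, depth_mm=depth_mm)
    plane.dose = plane.dose * scale
    # report the unshifted lattice so a shift acts as a dose perturbation
    if shift_mm != (0.0, 0.0):
        ox, oy, oz = plane.origin
        plane.origin = (ox - shift_mm[0], oy, oz - shift_mm[1])
    return plane


# ---------------------------------------------------------------------------
# File-level fixture generation


@dataclass(frozen=True)
class FixtureSpec:
    out_dir: Path
    phantom: PhantomSpec = PhantomSpec()
    two_fields: bool = False
    range_shifter: str = "none"
    plane_depths_mm: tuple[float, ...] = (20.0,)
    plane_scale: float = 1.0
    calibration_energies: tuple[float, ...] = (92.5, 97.0, 101.5)
    seed: int = 0


def make_fixtures(spec: FixtureSpec) -> dict[str, Path]:
    """Generate a complete synthetic input set on disk.

    Writes a CT series, structure set, RT ion plan, calibration CSV and
    measurement-plane CSVs; returns a name -> path map.  The measurement
    planes are derived from a noiseless mock-engine reference run on the
    preprocessed CT (perturbed by ``plane_scale`` if requested), so an
    unperturbed plane should pass 3%/3 mm gamma against any faithful
    recalculation.
    """
    from .preprocess import CouchModel, preprocess_ct

    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct = make_phantom_ct(spec.phantom)
    ct_dir = out / "ct"
    dicom_io.write_ct_series(ct, ct_dir)
    contours = phantom_contours(ct, spec.phantom)
    struct_path = dicom_io.write_structures(contours, ct, out / "structures.dcm")
    structures = dicom_io.read_structures(struct_path, ct)

    calib = make_calibration(spec.calibration_energies)
    calib_path = calib.to_csv(out / "calibration.csv")

    pre = preprocess_ct(ct, structures, couch=CouchModel())
    plan = make_plan(ct, energies=spec.calibration_energies,
                     two_fields=spec.two_fields,
                     range_shifter=spec.range_shifter)
    plan = normalize_plan_mu(plan, pre.ct, calib)
    plan_path = dicom_io.write_plan(plan, out / "plan.dcm")

    ref = reference_dose(plan, pre.ct, calib)
    paths = {"ct": ct_dir, "structures": struct_path, "plan": plan_path,
             "calibration": calib_path}
    surface_y = -spec.phantom.body_radius_mm
    for d in spec.plane_depths_mm:
        plane = make_measurement_plane(ref, depth_mm=d,
                                       body_surface_y_mm=surface_y,
                                       scale=spec.plane_scale)
        p = plane.to_csv(out / f"plane_d{d:g}.csv")
        paths[f"plane_d{d:g}"] = p
    return paths
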