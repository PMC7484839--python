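"""DICOM I/O: CT series, RT Structure Set, RT Ion Plan and RT Dose.

Readers return the pipeline's in-memory types (:class:`~protonqa.core.CTVolume`,
:class:`~protonqa.core.StructureSet`, :class:`~protonqa.core.SpotPlan`,
:class:`~protonqa.core.DoseGrid`); writers exist both for pipeline export
(RT Dose) and for generating fully synthetic input datasets.

Conventions
-----------
* Patient coordinates are DICOM LPS in mm; only axis-aligned HFS geometry
  is supported (no oblique acquisitions).
* RT Dose pixel data are 32-bit unsigned integers with
  ``DoseGridScaling = max / (2**32 - 1)``, which bounds the round-trip
  quantization error at ~1.2e-10 of the grid maximum.
* LET_d grids are written as RT-Dose-shaped objects carrying the content
  label ``LETD_KEV_UM`` in ``DoseComment`` so they can be loaded into a TPS
  or imaging software alongside dose.
* Slice spacing must be uniform within 0.01 mm; a larger gap is reported
  as a missing slice.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import (
    CTVolume,
    DoseGrid,
    FieldDef,
    Geometry,
    IntegrityError,
    IntegrityReport,
    PipelineError,
    Spot,
    SpotPlan,
    Structure,
    StructureSet,
)

SLICE_SPACING_TOL_MM = 0.01

CT_STORAGE_UID = "1.2.840.10008.5.1.4.1.1.2"
RTSTRUCT_STORAGE_UID = "1.2.840.10008.5.1.4.1.1.481.3"
RTDOSE_STORAGE_UID = "1.2.840.10008.5.1.4.1.1.481.2"
RTION_PLAN_STORAGE_UID = "1.2.840.10008.5.1.4.1.1.481.8"

_UNIT_LABELS = {"Gy": "DOSE_GY", "Gy_per_particle": "GY_PER_PARTICLE",
                "keV_per_um": "LETD_KEV_UM"}
_LABEL_UNITS = {v: k for k, v in _UNIT_LABELS.items()}


def _file_meta(sop_class_uid: str, sop_instance_uid: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = sop_instance_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(sop_class_uid: str, modality: str, frame_uid: str) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = generate_uid()
    ds.file_meta = _file_meta(sop_class_uid, ds.SOPInstanceUID)
    ds.Modality = modality
    ds.PatientName = "PHANTOM^SYNTHETIC"
    ds.PatientID = "PHANTOM"
    ds.FrameOfReferenceUID = frame_uid
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    return ds


# ---------------------------------------------------------------------------
# CT series


def write_ct_series(ct: CTVolume, directory: str | os.PathLike) -> list[Path]:
    """Write a CTVolume as one CT Image Storage file per slice."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nz, ny, nx = ct.geometry.shape
    dx, dy, dz = ct.geometry.spacing
    ox, oy, oz = ct.geometry.origin
    frame_uid = ct.frame_of_reference_uid or generate_uid()
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    for k in range(nz):
        ds = _base_dataset(CT_STORAGE_UID, "CT", frame_uid)
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [ox, oy, oz + k * dz]
        ds.ImageOrientationPatient = list(ct.geometry.orientation)
        ds.PatientPosition = ct.geometry.patient_position
        ds.PixelSpacing = [dy, dx]  # row spacing, column spacing
        ds.SliceThickness = dz
        ds.Rows = ny
        ds.Columns = nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = ct.hu[k].astype(np.int16).tobytes()
        path = directory / f"ct_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_ct_series(directory: str | os.PathLike) -> CTVolume:
    """Assemble a CT series directory into a CTVolume.

    Slices are sorted by position along the slice axis; rescale slope and
    intercept are applied so values are HU.  Non-uniform slice spacing
    (beyond 0.01 mm, e.g. a deleted slice) or mixed frames of reference
    raise :class:`IntegrityError`.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    slices = [pydicom.dcmread(p) for p in files]
    slices = [s for s in slices if getattr(s, "Modality", "") == "CT"]
    if len(slices) < 2:
        raise IntegrityError(f"CT series needs >= 2 slices, found {len(slices)}")
    frames = {s.FrameOfReferenceUID for s in slices}
    if len(frames) != 1:
        raise IntegrityError(f"mixed frames of reference in CT series: {sorted(frames)}")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    steps = np.diff(zs)
    dz = float(np.median(steps))
    bad = np.nonzero(np.abs(steps - dz) > SLICE_SPACING_TOL_MM)[0]
    if bad.size:
        gaps = ", ".join(f"{zs[i]:.2f}->{zs[i + 1]:.2f} mm" for i in bad)
        raise IntegrityError(f"non-uniform slice spacing (missing slices?) at {gaps}")
    s0 = slices[0]
    dy, dx = (float(v) for v in s0.PixelSpacing)
    hu = np.stack([
        s.pixel_array.astype(np.float64) * float(s.RescaleSlope)
        + float(s.RescaleIntercept)
        for s in slices
    ]).astype(np.int32)
    geo = Geometry(
        shape=(len(slices), int(s0.Rows), int(s0.Columns)),
        spacing=(dx, dy, dz),
        origin=tuple(float(v) for v in s0.ImagePositionPatient),
        orientation=tuple(float(v) for v in s0.ImageOrientationPatient),
        patient_position=str(getattr(s0, "PatientPosition", "HFS")),
    )
    return CTVolume(hu, geo, frame_of_reference_uid=s0.FrameOfReferenceUID)


# ---------------------------------------------------------------------------
# RT Structure Set


def write_structures(
    contours: dict[str, list[tuple[float, np.ndarray]]],
    ct: CTVolume,
    path: str | os.PathLike,
) -> Path:
    """Write an RT Structure Set from per-structure contour polygons.

    ``contours`` maps structure name to a list of ``(z_mm, polygon)`` where
    each polygon is an (N, 2) array of (x, y) vertices in patient mm.
    """
    ds = _base_dataset(RTSTRUCT_STORAGE_UID, "RTSTRUCT", ct.frame_of_reference_uid)
    ds.StructureSetLabel = "SYNTHETIC"
    roi_seq, contour_seq = [], []
    for num, (name, polys) in enumerate(contours.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = ct.frame_of_reference_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        items = []
        for z, poly in polys:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            poly = np.asarray(poly, dtype=float)
            c.NumberOfContourPoints = len(poly)
            data = np.column_stack([poly, np.full(len(poly), z)])
            c.ContourData = [f"{v:.6f}" for v in data.ravel()]
            items.append(c)
        rc.ContourSequence = items
        contour_seq.append(rc)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    path = Path(path)
    ds.save_as(path, enforce_file_format=True)
    return path


def rasterize_polygon(poly: np.ndarray, geo: Geometry) -> np.ndarray:
    """Rasterize an (N,2) xy polygon to a 2D bool mask by voxel-center test."""
    from matplotlib.path import Path as MplPath

    xs = geo.axis_coords("x")
    ys = geo.axis_coords("y")
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = MplPath(np.asarray(poly, float)).contains_points(pts)
    return inside.reshape(len(ys), len(xs))


def read_structures(path: str | os.PathLike, ct: CTVolume) -> StructureSet:
    """Read an RT Structure Set and rasterize every contour on the CT grid.

    Each closed planar contour is assigned to the nearest CT slice and
    filled by a voxel-center point-in-polygon test.  A body/external
    structure must be present and non-empty.
    """
    ds = pydicom.dcmread(path)
    frame = ""
    rois = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    if ds.StructureSetROISequence:
        frame = str(ds.StructureSetROISequence[0].ReferencedFrameOfReferenceUID)
    if frame and ct.frame_of_reference_uid and frame != ct.frame_of_reference_uid:
        raise IntegrityError("structure set frame of reference does not match CT")
    zs = ct.geometry.axis_coords("z")
    dz = ct.geometry.spacing[2]
    structures: dict[str, Structure] = {}
    for rc in getattr(ds, "ROIContourSequence", []):
        name = rois[int(rc.ReferencedROINumber)]
        mask = np.zeros(ct.geometry.shape, dtype=bool)
        contour_list = []
        for c in getattr(rc, "ContourSequence", []):
            data = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            z = float(np.mean(data[:, 2]))
            k = int(np.argmin(np.abs(zs - z)))
            if abs(zs[k] - z) > dz:  # contour off the CT grid entirely
                continue
            mask[k] |= rasterize_polygon(data[:, :2], ct.geometry)
            contour_list.append((z, data[:, :2]))
        structures[name] = Structure(name=name, mask=mask, contours=contour_list)
    sset = StructureSet(structures, frame_of_reference_uid=frame)
    body = sset.body()  # raises IntegrityError if absent
    if not body.mask.any():
        raise IntegrityError("body contour rasterized to an empty mask")
    return sset


# ---------------------------------------------------------------------------
# RT Ion Plan


def write_plan(plan: SpotPlan, path: str | os.PathLike,
               frame_uid: str = "") -> Path:
    """Write a SpotPlan as a minimal RT Ion Plan (spot-scanning)."""
    ds = _base_dataset(RTION_PLAN_STORAGE_UID, "RTPLAN",
                       frame_uid or plan.frame_of_reference_uid or generate_uid())
    ds.RTPlanLabel = plan.plan_id
    dose_ref = Dataset()
    dose_ref.DoseReferenceNumber = 1
    dose_ref.DoseReferenceStructureType = "SITE"
    dose_ref.TargetPrescriptionDose = plan.prescription_dose_gy
    ds.DoseReferenceSequence = [dose_ref]

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    ref_beams = []
    beams = []
    for bi, f in enumerate(plan.fields, start=1):
        rb = Dataset()
        rb.ReferencedBeamNumber = bi
        rb.BeamMeterset = f.total_mu
        ref_beams.append(rb)

        beam = Dataset()
        beam.BeamNumber = bi
        beam.BeamName = f.name or f"Field{bi}"
        beam.ScanMode = "MODULATED"
        beam.RadiationType = "PROTON"
        beam.TreatmentDeliveryType = "TREATMENT"
        beam.FinalCumulativeMetersetWeight = f.total_mu
        if f.range_shifter != "none":
            rs = Dataset()
            rs.RangeShifterNumber = 1
            rs.RangeShifterID = f.range_shifter
            rs.RangeShifterType = "BINARY"
            beam.RangeShifterSequence = [rs]
        # one control point per energy layer, spot weights in MU
        layers: dict[float, list[Spot]] = {}
        for s in f.spots:
            layers.setdefault(s.energy_mev, []).append(s)
        cps = []
        for ci, (energy, spots) in enumerate(sorted(layers.items(), reverse=True)):
            cp = Dataset()
            cp.ControlPointIndex = ci
            cp.NominalBeamEnergy = energy
            cp.GantryAngle = f.gantry_angle
            cp.PatientSupportAngle = f.couch_angle
            cp.IsocenterPosition = list(f.isocenter)
            cp.NumberOfScanSpotPositions = len(spots)
            cp.ScanSpotPositionMap = [float(v) for s in spots for v in (s.x_mm, s.y_mm)]
            cp.ScanSpotMetersetWeights = [float(s.mu) for s in spots]
            cps.append(cp)
        beam.NumberOfControlPoints = len(cps)
        beam.IonControlPointSequence = cps
        beams.append(beam)
    fg.ReferencedBeamSequence = ref_beams
    ds.FractionGroupSequence = [fg]
    ds.IonBeamSequence = beams
    path = Path(path)
    ds.save_as(path, enforce_file_format=True)
    return path


def read_plan(path: str | os.PathLike) -> SpotPlan:
    """Read an RT Ion Plan into a SpotPlan.

    Spot MU values are recovered as meterset weight x beam meterset /
    final cumulative meterset weight.  Non-ion (e.g. photon) plans raise
    :class:`PipelineError`.
    """
    ds = pydicom.dcmread(path)
    if not hasattr(ds, "IonBeamSequence"):
        raise PipelineError(
            f"unsupported modality: {getattr(ds, 'Modality', '?')} plan without "
            "ion spot-scanning beams"
        )
    rx = 1.0
    for dr in getattr(ds, "DoseReferenceSequence", []):
        if hasattr(dr, "TargetPrescriptionDose"):
            rx = float(dr.TargetPrescriptionDose)
    metersets = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)
    fields = []
    for beam in ds.IonBeamSequence:
        num = int(beam.BeamNumber)
        meterset = metersets.get(num)
        final_w = float(getattr(beam, "FinalCumulativeMetersetWeight", 0.0))
        rs = "none"
        for item in getattr(beam, "RangeShifterSequence", []):
            rs = str(item.RangeShifterID)
        spots: list[Spot] = []
        gantry = couch = 0.0
        iso = (0.0, 0.0, 0.0)
        energy = None
        for cp in beam.IonControlPointSequence:
            if hasattr(cp, "GantryAngle"):
                gantry = float(cp.GantryAngle)
            if hasattr(cp, "PatientSupportAngle"):
                couch = float(cp.PatientSupportAngle)
            if hasattr(cp, "IsocenterPosition"):
                iso = tuple(float(v) for v in cp.IsocenterPosition)
            if hasattr(cp, "NominalBeamEnergy"):
                energy = float(cp.NominalBeamEnergy)
            weights = getattr(cp, "ScanSpotMetersetWeights", None)
            if weights is None:
                continue
            weights = np.atleast_1d(np.asarray(weights, dtype=float))
            if weights.sum() == 0 and len(spots) > 0:
                continue  # paired end-of-layer control point
            pos = np.asarray(cp.ScanSpotPositionMap, dtype=float).reshape(-1, 2)
            for (x, y), w in zip(pos, weights):
                mu = w * meterset / final_w if (meterset and final_w) else w
                spots.append(Spot(energy_mev=energy, x_mm=x, y_mm=y, mu=mu))
        fields.append(FieldDef(gantry_angle=gantry, couch_angle=couch,
                               isocenter=iso, range_shifter=rs, spots=spots,
                               name=str(getattr(beam, "BeamName", ""))))
    return SpotPlan(
        plan_id=str(getattr(ds, "RTPlanLabel", "plan")),
        prescription_dose_gy=rx,
        fields=fields,
        frame_of_reference_uid=str(getattr(ds, "FrameOfReferenceUID", "")),
    )


# ---------------------------------------------------------------------------
# RT Dose


def write_dose(grid: DoseGrid, path: str | os.PathLike,
               frame_uid: str = "") -> Path:
    """Write a DoseGrid (dose in Gy or LET_d in keV/um) as RT Dose.

    Values are stored as 32-bit unsigned integers with
    ``DoseGridScaling = max / (2**32 - 1)``; the unit is recorded as a
    content label in ``DoseComment``.
    """
    if grid.unit == "Gy_per_particle":
        raise PipelineError("per-particle dose must be calibrated before DICOM export")
    vmax = float(grid.values.max())
    scaling = vmax / (2**32 - 1) if vmax > 0 else 1.0
    pixels = np.round(grid.values / scaling).astype(np.uint32)
    ds = _base_dataset(RTDOSE_STORAGE_UID, "RTDOSE",
                       frame_uid or grid.frame_of_reference_uid or generate_uid())
    nz, ny, nx = grid.geometry.shape
    dx, dy, dz = grid.geometry.spacing
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseComment = _UNIT_LABELS[grid.unit]
    ds.DoseGridScaling = scaling
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [dy, dx]
    ds.GridFrameOffsetVector = [k * dz for k in range(nz)]
    ds.ImagePositionPatient = list(grid.geometry.origin)
    ds.ImageOrientationPatient = list(grid.geometry.orientation)
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = pixels.tobytes()
    path = Path(path)
    ds.save_as(path, enforce_file_format=True)
    return path


def read_dose(path: str | os.PathLike) -> DoseGrid:
    """Read an RT Dose file back into a DoseGrid."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise PipelineError(f"not an RT Dose file: {path}")
    nz = int(ds.NumberOfFrames)
    ny, nx = int(ds.Rows), int(ds.Columns)
    raw = np.frombuffer(ds.PixelData, dtype=np.uint32).reshape(nz, ny, nx)
    values = raw.astype(np.float64) * float(ds.DoseGridScaling)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offsets[1] - offsets[0]) if nz > 1 else 1.0
    dy, dx = (float(v) for v in ds.PixelSpacing)
    geo = Geometry(
        shape=(nz, ny, nx),
        spacing=(dx, dy, dz),
        origin=tuple(float(v) for v in ds.ImagePositionPatient),
        orientation=tuple(float(v) for v in ds.ImageOrientationPatient),
    )
    unit = _LABEL_UNITS.get(str(getattr(ds, "DoseComment", "")), "Gy")
    return DoseGrid(values, unit, geo,
                    frame_of_reference_uid=str(getattr(ds, "FrameOfReferenceUID", "")))


# ---------------------------------------------------------------------------
# Integrity check


def check_integrity(
    ct: CTVolume | None,
    structures: StructureSet | None,
    plan: SpotPlan | None,
    calibration_energies: Iterable[float] | None = None,
) -> IntegrityReport:
    """Pre-flight data verification: reports, never raises.

    Checks presence of CT, structure set (with a body contour) and an ion
    spot plan; frame-of-reference consistency across the three; and, if a
    calibration energy list is supplied, coverage of every plan energy.
    """
    missing: list[str] = []
    frames = set()
    if ct is None:
        missing.append("CT series")
    else:
        if ct.frame_of_reference_uid:
            frames.add(ct.frame_of_reference_uid)
    if structures is None:
        missing.append("structure set")
    else:
        if structures.frame_of_reference_uid:
            frames.add(structures.frame_of_reference_uid)
        try:
            body = structures.body()
            if not body.mask.any():
                missing.append("non-empty body contour")
        except IntegrityError:
            missing.append("body contour")
    if plan is None:
        missing.append("RT ion plan")
    else:
        if plan.frame_of_reference_uid:
            frames.add(plan.frame_of_reference_uid)
        if calibration_energies is not None:
            cal = set(float(e) for e in calibration_energies)
            uncovered = sorted(e for e in plan.energies() if float(e) not in cal)
            if uncovered:
                missing.append(
                    f"calibration for energies {uncovered} MeV"
                )
    frame_ok = len(frames) <= 1
    return IntegrityReport(missing_items=missing,
                           frame_of_reference_consistent=frame_ok)
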