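"""Batch job preparation, the PVB1 batch interchange format, and a mock
analytical transport engine.

A plan's total proton histories (default 2e8 per field) are split among
parallel batches (default 50) with distinct per-batch seeds, mirroring the
way production Monte-Carlo transport is parallelized.  Each batch produces
a per-particle dose grid and a dose-averaged LET_d grid on the CT
voxelization, written in the little-endian binary PVB1 format.

The built-in :class:`MockEngine` is explicitly NOT a physics claim: it is a
fast analytical pencil-beam stand-in (Bragg-Kleeman range, parameterized
Bragg curve, depth-growing lateral Gaussian, monotone LET_d curve, seeded
multiplicative noise with variance proportional to 1/histories) that makes
batch combination, calibration, gamma QA and orchestration testable without
external transport code.  Real engines plug in through
:class:`EngineInterface`.
"""

from __future__ import annotations

import struct
from abc import ABC, abstractmethod
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import CTVolume, DoseGrid, FieldDef, PipelineError, Spot, SpotPlan
from .preprocess import DensityCurve, hu_to_density

#: Discrete machine energy list: 96 nominal energies, 70-212.5 MeV in
#: 1.5 MeV steps.
MACHINE_ENERGIES: tuple[float, ...] = tuple(70.0 + 1.5 * i for i in range(96))

DEFAULT_N_BATCHES = 50
DEFAULT_TOTAL_HISTORIES = int(2e8)


class CorruptBatchError(PipelineError):
    """A PVB1 batch file is truncated or internally inconsistent."""


@dataclass(frozen=True)
class JobSpec:
    """One parallel batch job: a field's spots, a history count and a seed."""

    field_index: int
    batch_index: int
    n_batches: int
    histories: int
    seed: int
    spots: tuple[Spot, ...]
    range_shifter: str
    gantry_angle: float
    isocenter: tuple[float, float, float]


@dataclass
class BatchResult:
    """One batch's output: per-particle dose + batch dose-averaged LET_d."""

    dose: DoseGrid  # Gy per simulated particle
    let: DoseGrid  # keV/um
    histories: int
    seed: int
    field_index: int
    batch_index: int

    def __post_init__(self) -> None:
        if not self.dose.geometry.same_grid(self.let.geometry):
            raise PipelineError("batch dose and LET grids have different geometry")


def plan_to_jobs(
    plan: SpotPlan,
    n_batches: int = DEFAULT_N_BATCHES,
    total_histories: int = DEFAULT_TOTAL_HISTORIES,
    base_seed: int = 0,
) -> list[JobSpec]:
    """Split each field's histories among ``n_batches`` jobs with distinct seeds.

    Histories are split as evenly as integers allow (the first
    ``total % n_batches`` jobs of a field receive one extra history); the
    per-job seed is ``base_seed + field_index * n_batches + batch_index``,
    pairwise distinct by construction.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if total_histories < n_batches:
        raise PipelineError(
            f"cannot split {total_histories} histories among {n_batches} batches"
        )
    base, rem = divmod(total_histories, n_batches)
    jobs = []
    for fi, f in enumerate(plan.fields):
        for bi in range(n_batches):
            jobs.append(JobSpec(
                field_index=fi,
                batch_index=bi,
                n_batches=n_batches,
                histories=base + (1 if bi < rem else 0),
                seed=base_seed + fi * n_batches + bi,
                spots=tuple(f.spots),
                range_shifter=f.range_shifter,
                gantry_angle=f.gantry_angle,
                isocenter=f.isocenter,
            ))
    return jobs


# ---------------------------------------------------------------------------
# PVB1 binary batch format

_MAGIC = b"PVB1"
_HEADER = struct.Struct("<4s3i3d3dqqii")  # magic, dims, spacing, origin,
#                                           histories, seed, field, batch


def write_batch(result: BatchResult, path: str | Path) -> Path:
    """Write a BatchResult to the PVB1 binary format (bit-exact round trip).

    Layout (little-endian): magic ``PVB1``; dims nx, ny, nz (int32);
    spacing dx, dy, dz (float64 mm); origin x, y, z (float64 mm);
    histories (int64); seed (int64); field, batch (int32); then the dose
    and LET rasters as float32, x fastest.
    """
    geo = result.dose.geometry
    nz, ny, nx = geo.shape
    header = _HEADER.pack(
        _MAGIC, nx, ny, nz, *geo.spacing, *geo.origin,
        result.histories, result.seed, result.field_index, result.batch_index,
    )
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(result.dose.values, dtype="<f4").tobytes())
        fh.write(np.ascontiguousarray(result.let.values, dtype="<f4").tobytes())
    return path


def read_batch(path: str | Path) -> BatchResult:
    """Read a PVB1 batch file; truncation or bad magic raises CorruptBatchError."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _HEADER.size:
        raise CorruptBatchError(
            f"{path}: truncated header ({len(blob)} < {_HEADER.size} bytes)"
        )
    (magic, nx, ny, nz, dx, dy, dz, ox, oy, oz,
     histories, seed, fi, bi) = _HEADER.unpack_from(blob)
    if magic != _MAGIC:
        raise CorruptBatchError(f"{path}: bad magic {magic!r}, expected {_MAGIC!r}")
    nvox = nx * ny * nz
    expected = _HEADER.size + 2 * 4 * nvox
    if len(blob) != expected:
        raise CorruptBatchError(
            f"{path}: payload inconsistent with header dims at byte offset "
            f"{len(blob)} (expected {expected} bytes)"
        )
    from .core import Geometry

    geo = Geometry(shape=(nz, ny, nx), spacing=(dx, dy, dz), origin=(ox, oy, oz))
    dose = np.frombuffer(blob, dtype="<f4", count=nvox,
                         offset=_HEADER.size).reshape(nz, ny, nx)
    let = np.frombuffer(blob, dtype="<f4", count=nvox,
                        offset=_HEADER.size + 4 * nvox).reshape(nz, ny, nx)
    return BatchResult(
        dose=DoseGrid(dose, "Gy_per_particle", geo),
        let=DoseGrid(let, "keV_per_um", geo),
        histories=histories, seed=seed, field_index=fi, batch_index=bi,
    )


# ---------------------------------------------------------------------------
# Engine interface and mock engine


class EngineInterface(ABC):
    """Contract for transport engines: deterministic given (seed, inputs),
    output grids co-registered to the CT."""

    @abstractmethod
    def run(self, job: JobSpec, ct: CTVolume,
            curve: DensityCurve) -> BatchResult: ...


@dataclass(frozen=True)
class MockEngineConfig:
    """Parameters of the analytical pencil-beam stand-in.

    Range follows Bragg-Kleeman R = alpha * E**p (R in cm, E in MeV);
    the depth-dose is an entrance plateau plus a Gaussian Bragg peak at the
    water-equivalent range; the lateral profile is a Gaussian whose sigma
    grows linearly with water-equivalent depth; LET_d rises sigmoidally
    toward the end of range, exceeding 6 keV/um distally.
    """

    alpha_cm: float = 0.0022
    p_exponent: float = 1.77
    plateau: float = 0.30  # entrance dose relative to peak
    plateau_slope: float = 0.70  # fractional rise of plateau toward the peak
    straggling_frac: float = 0.012  # Gaussian peak width as fraction of range
    straggling_min_mm: float = 1.5
    distal_falloff_mm: float = 1.0
    sigma0_mm: float = 3.0  # lateral sigma at the surface
    sigma_growth: float = 0.02  # lateral sigma growth per mm WET
    let_entry_kev_um: float = 1.2
    let_distal_kev_um: float = 12.0
    let_rise_offset_mm: float = 3.0  # sigmoid midpoint upstream of the range
    let_rise_width_mm: float = 2.5
    nozzle_rs_wet_mm: float = 46.0  # 40 mm slab x relative density 1.15
    noise_coeff: float = 2.0  # relative voxel noise = coeff / sqrt(histories)
    dose_scale: float = 1e-9  # Gy mm^2 per particle normalization
    dose_floor_rel: float = 1e-12  # relative cutoff below which dose is 0
    energies: tuple[float, ...] = MACHINE_ENERGIES


class MockEngine(EngineInterface):
    """Analytical pencil-beam engine with seeded per-batch noise.

    Deterministic given the job seed; the noiseless core is cached per
    (CT, field) so repeated batches of the same field are cheap.
    """

    def __init__(self, config: MockEngineConfig | None = None,
                 noiseless: bool = False):
        self.config = config or MockEngineConfig()
        self.noiseless = noiseless
        self._core_cache: dict = {}

    # -- physics pieces -----------------------------------------------------

    def range_mm(self, energy_mev: float) -> float:
        """Bragg-Kleeman water range in mm."""
        c = self.config
        return 10.0 * c.alpha_cm * energy_mev ** c.p_exponent

    def depth_dose(self, wet_mm: np.ndarray, energy_mev: float) -> np.ndarray:
        """Parameterized Bragg curve vs water-equivalent depth (peak ~1)."""
        c = self.config
        r = self.range_mm(energy_mev)
        sig_r = max(c.straggling_min_mm, c.straggling_frac * r)
        peak = np.exp(-0.5 * ((wet_mm - r) / sig_r) ** 2)
        frac = np.clip(wet_mm / r, 0.0, 1.0)
        plateau = c.plateau * (1.0 + c.plateau_slope * frac)
        distal_cut = 1.0 / (1.0 + np.exp((wet_mm - r - 2.0 * sig_r)
                                         / c.distal_falloff_mm))
        return peak + plateau * distal_cut * (wet_mm <= r + 4.0 * sig_r)

    def let_curve(self, wet_mm: np.ndarray, energy_mev: float) -> np.ndarray:
        """Monotone LET_d(depth): sigmoid rise toward the end of range."""
        c = self.config
        r = self.range_mm(energy_mev)
        z = (wet_mm - (r - c.let_rise_offset_mm)) / c.let_rise_width_mm
        return c.let_entry_kev_um + (
            c.let_distal_kev_um - c.let_entry_kev_um) / (1.0 + np.exp(-z))

    def lateral_sigma(self, wet_mm: np.ndarray) -> np.ndarray:
        c = self.config
        return c.sigma0_mm + c.sigma_growth * np.maximum(wet_mm, 0.0)

    # -- transport ----------------------------------------------------------

    def _beam_axes(self, gantry_angle: float) -> tuple[str, int]:
        """Map a cardinal gantry angle to (beam axis, direction).

        HFS convention: gantry 0 enters from the anterior (-y) side and
        travels toward +y; 180 travels toward -y; 90/270 along -x/+x.
        """
        a = gantry_angle % 360.0
        mapping = {0.0: ("y", +1), 180.0: ("y", -1),
                   90.0: ("x", -1), 270.0: ("x", +1)}
        if a not in mapping:
            raise PipelineError(
                f"mock engine supports cardinal gantry angles only, got {a}"
            )
        return mapping[a]

    def _wet_grid(self, ct: CTVolume, curve: DensityCurve,
                  axis: str, direction: int) -> np.ndarray:
        """Cumulative water-equivalent depth (mm) at voxel centers along the
        beam, approximating relative stopping power by mass density."""
        rho = hu_to_density(ct.hu, curve)
        ax = {"x": 2, "y": 1}[axis]
        step = ct.geometry.spacing[{"x": 0, "y": 1}[axis]]
        if direction < 0:
            rho = np.flip(rho, axis=ax)
        wet = np.cumsum(rho, axis=ax) * step - rho * (step / 2.0)
        if direction < 0:
            wet = np.flip(wet, axis=ax)
        return wet

    def _field_core(self, job: JobSpec, ct: CTVolume,
                    curve: DensityCurve) -> tuple[np.ndarray, np.ndarray]:
        """Noiseless per-particle dose and dose-averaged LET for the field."""
        key = (id(ct), job.field_index, job.range_shifter, job.gantry_angle,
               tuple((s.energy_mev, s.x_mm, s.y_mm, s.mu) for s in job.spots))
        if key in self._core_cache:
            return self._core_cache[key]
        c = self.config
        for s in job.spots:
            if not any(abs(s.energy_mev - e) < 1e-6 for e in c.energies):
                raise PipelineError(
                    f"spot energy {s.energy_mev} MeV not in the machine energy list"
                )
        axis, direction = self._beam_axes(job.gantry_angle)
        geo = ct.geometry
        wet = self._wet_grid(ct, curve, axis, direction)
        if job.range_shifter == "nozzle_40mm":
            wet = wet + c.nozzle_rs_wet_mm
        # lateral axes: in-plane axis perpendicular to the beam, plus z
        xs = geo.axis_coords("x")
        ys = geo.axis_coords("y")
        zs = geo.axis_coords("z")
        if axis == "y":
            lat1 = xs[None, None, :]  # BEV x -> patient x
            lat1_iso = job.isocenter[0]
        else:
            lat1 = ys[None, :, None]  # BEV x -> patient y
            lat1_iso = job.isocenter[1]
        lat2 = zs[:, None, None]  # BEV y -> patient z
        lat2_iso = job.isocenter[2]
        total_mu = sum(s.mu for s in job.spots)
        dose = np.zeros(geo.shape)
        let_num = np.zeros(geo.shape)
        sigma = self.lateral_sigma(wet)
        two_sig2 = 2.0 * sigma**2
        norm = 1.0 / (np.pi * two_sig2)
        for s in job.spots:
            w = s.mu / total_mu if total_mu > 0 else 1.0 / len(job.spots)
            if w == 0.0:
                continue
            r2 = (lat1 - (lat1_iso + s.x_mm)) ** 2 + (lat2 - (lat2_iso + s.y_mm)) ** 2
            kern = (c.dose_scale * w * self.depth_dose(wet, s.energy_mev)
                    * norm * np.exp(-r2 / two_sig2))
            dose += kern
            let_num += kern * self.let_curve(wet, s.energy_mev)
        with np.errstate(invalid="ignore"):
            let = np.where(dose > 0, let_num / np.where(dose > 0, dose, 1.0), 0.0)
        floor = c.dose_floor_rel * dose.max()
        low = dose <= floor
        dose[low] = 0.0
        let[low] = 0.0
        self._core_cache[key] = (dose, let)
        return dose, let

    def run(self, job: JobSpec, ct: CTVolume,
            curve: DensityCurve | None = None) -> BatchResult:
        """Simulate one batch: noiseless core plus seeded multiplicative noise."""
        curve = curve or DensityCurve()
        core_dose, core_let = self._field_core(job, ct, curve)
        c = self.config
        if self.noiseless or c.noise_coeff == 0.0:
            dose, let = core_dose.copy(), core_let.copy()
        else:
            rng = np.random.default_rng(job.seed)
            rel = c.noise_coeff / np.sqrt(job.histories)
            dose = core_dose * np.clip(
                1.0 + rel * rng.standard_normal(core_dose.shape), 1e-3, None)
            let = core_let * np.clip(
                1.0 + rel * rng.standard_normal(core_let.shape), 1e-3, None)
            let[dose == 0.0] = 0.0
        geo = ct.geometry
        return BatchResult(
            dose=DoseGrid(dose, "Gy_per_particle", geo,
                          frame_of_reference_uid=ct.frame_of_reference_uid),
            let=DoseGrid(let, "keV_per_um", geo,
                         frame_of_reference_uid=ct.frame_of_reference_uid),
            histories=job.histories,
            seed=job.seed,
            field_index=job.field_index,
            batch_index=job.batch_index,
        )
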