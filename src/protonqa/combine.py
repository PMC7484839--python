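"""Batch combination and absolute-dose calibration.

Per-batch results merge into final grids as

    D_bar     = (1/N) * sum_i Dose_i                    (voxel-wise mean)
    LETd_bar  = sum_i LET_i * Dose_i / sum_i Dose_i     (dose-weighted mean)

with LETd_bar defined as 0 where the summed dose is 0.  Statistical
uncertainty is the across-batch standard error of the mean divided by the
mean dose (relative, 1 sigma).

Per-particle dose becomes absolute dose through a particles-per-MU
calibration: for each nominal beam energy, the ratio of a measured single
spot dose per MU (ionization chamber at 2 cm depth in water) to the
simulated single-spot dose per particle gives particles/MU; a field's
scale factor is then sum over spots of MU x particles_per_MU(energy).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DoseGrid, FieldDef, PipelineError, require_same_geometry
from .engine import BatchResult

log = logging.getLogger(__name__)


def _stack(batches: list[BatchResult], attr: str) -> np.ndarray:
    if not batches:
        raise PipelineError("cannot combine an empty batch list")
    require_same_geometry(*[b.dose for b in batches],
                          *[b.let for b in batches])
    return np.stack([getattr(b, attr).values for b in batches])


def _weights(batches: list[BatchResult]) -> np.ndarray | None:
    """None for the printed equal-histories form, else history weights."""
    hist = np.array([b.histories for b in batches], dtype=float)
    if np.all(hist == hist[0]):
        return None
    log.warning(
        "batches have unequal histories (%s); falling back to "
        "histories-weighted mean", hist.astype(int).tolist())
    return hist / hist.sum()


def combine_dose(batches: list[BatchResult]) -> DoseGrid:
    """Voxel-wise mean dose over batches (histories-weighted if unequal)."""
    doses = _stack(batches, "dose")
    w = _weights(batches)
    if w is None:
        mean = doses.mean(axis=0)
    else:
        mean = np.tensordot(w, doses, axes=1)
    ref = batches[0].dose
    return DoseGrid(mean, ref.unit, ref.geometry, ref.frame_of_reference_uid)


def combine_let(batches: list[BatchResult]) -> DoseGrid:
    """Voxel-wise dose-weighted mean of batch LET_d; 0 where total dose is 0."""
    doses = _stack(batches, "dose")
    lets = np.stack([b.let.values for b in batches])
    w = _weights(batches)
    if w is not None:
        doses = doses * w[:, None, None, None]
    num = (lets * doses).sum(axis=0)
    den = doses.sum(axis=0)
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    ref = batches[0].let
    return DoseGrid(out, "keV_per_um", ref.geometry, ref.frame_of_reference_uid)


def batch_uncertainty(batches: list[BatchResult]) -> np.ndarray:
    """Relative 1-sigma standard error of the mean dose, per voxel.

    Sample standard deviation across the N batches divided by sqrt(N) and
    by the mean dose; 0 where the mean dose is 0.  Requires N >= 2.
    """
    if len(batches) < 2:
        raise PipelineError("batch uncertainty needs >= 2 batches")
    doses = _stack(batches, "dose")
    mean = doses.mean(axis=0)
    sem = doses.std(axis=0, ddof=1) / np.sqrt(len(batches))
    return np.divide(sem, mean, out=np.zeros_like(mean), where=mean > 0)


# ---------------------------------------------------------------------------
# Particles-per-MU calibration

_CAL_COLUMNS = ["energy_mev", "dose_per_mu_gy", "dose_per_particle_gy",
                "particles_per_mu"]


@dataclass
class CalibrationTable:
    """Energy -> particles-per-MU mapping.

    Each row holds the measured single-spot dose per MU, the simulated
    single-spot dose per particle and their ratio.  A full machine table
    nominally covers 96 energies; any energy list covering the plan is
    accepted.
    """

    table: pd.DataFrame  # columns _CAL_COLUMNS, sorted by energy

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _CAL_COLUMNS if c not in df.columns]
        if missing:
            raise PipelineError(f"calibration table missing columns {missing}")
        if df["energy_mev"].duplicated().any():
            raise PipelineError("calibration energies must be distinct")
        ratio = df["dose_per_mu_gy"] / df["dose_per_particle_gy"]
        if not np.allclose(ratio, df["particles_per_mu"], rtol=1e-9):
            raise PipelineError(
                "particles_per_mu inconsistent with dose ratio in table")
        self.table = df.sort_values("energy_mev").reset_index(drop=True)

    def energies(self) -> np.ndarray:
        return self.table["energy_mev"].to_numpy()

    def particles_per_mu(self, energy_mev: float) -> float:
        df = self.table
        hit = df[np.isclose(df["energy_mev"], energy_mev, atol=1e-6)]
        if hit.empty:
            raise PipelineError(
                f"energy {energy_mev} MeV missing from calibration table")
        return float(hit["particles_per_mu"].iloc[0])

    def covers(self, energies) -> bool:
        own = self.energies()
        return all(np.any(np.isclose(own, e, atol=1e-6)) for e in energies)

    # CSV round trip ---------------------------------------------------------

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False,
                          float_format="%.17g", columns=_CAL_COLUMNS)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationTable":
        return cls(pd.read_csv(path, float_precision="round_trip"))


def derive_calibration(
    measured: list[tuple[float, float]],
    simulated: list[tuple[float, float]],
) -> CalibrationTable:
    """Build a CalibrationTable from matched measured and simulated lists.

    ``measured`` holds (energy MeV, dose per MU in Gy); ``simulated`` holds
    (energy MeV, dose per particle in Gy).  The row-wise ratio is the
    number of particles per MU at each energy.
    """
    me = np.array([e for e, _ in measured], dtype=float)
    se = np.array([e for e, _ in simulated], dtype=float)
    if len(me) != len(se) or not np.allclose(np.sort(me), np.sort(se), atol=1e-6):
        raise PipelineError("measured and simulated energy lists do not match")
    sim = {round(e, 6): d for e, d in simulated}
    rows = []
    for e, dmu in measured:
        dpp = sim[round(e, 6)]
        if dmu <= 0 or dpp <= 0:
            raise PipelineError(
                f"nonpositive calibration input at {e} MeV: "
                f"dose/MU={dmu}, dose/particle={dpp}")
        rows.append((e, dmu, dpp, dmu / dpp))
    return CalibrationTable(pd.DataFrame(rows, columns=_CAL_COLUMNS))


def to_absolute_dose(
    per_particle: DoseGrid,
    field: FieldDef,
    calib: CalibrationTable,
    histories_simulated: int | None = None,
) -> DoseGrid:
    """Convert a per-particle dose grid to absolute dose in Gy.

    absolute = per_particle x sum over spots of MU x particles_per_MU(E);
    linear in total plan MU.  ``histories_simulated`` is accepted for
    provenance but cancels out of the per-particle formulation.
    """
    if per_particle.unit != "Gy_per_particle":
        raise PipelineError(
            f"expected a per-particle dose grid, got unit {per_particle.unit!r}")
    scale = sum(s.mu * calib.particles_per_mu(s.energy_mev) for s in field.spots)
    return DoseGrid(per_particle.values * scale, "Gy", per_particle.geometry,
                    per_particle.frame_of_reference_uid)


@dataclass
class CombinedResult:
    """Final combined output for one field: absolute dose, LET_d, uncertainty."""

    dose: DoseGrid  # Gy
    let: DoseGrid  # keV/um
    rel_uncertainty: np.ndarray  # fraction, 1 sigma
    n_batches: int


def combine_batches(
    batches: list[BatchResult],
    field: FieldDef,
    calib: CalibrationTable,
) -> CombinedResult:
    """Combine a field's batches and calibrate to absolute dose."""
    per_particle = combine_dose(batches)
    let = combine_let(batches)
    unc = (batch_uncertainty(batches) if len(batches) >= 2
           else np.zeros(per_particle.geometry.shape))
    dose = to_absolute_dose(per_particle, field, calib,
                            sum(b.histories for b in batches))
    return CombinedResult(dose=dose, let=let, rel_uncertainty=unc,
                          n_batches=len(batches))
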