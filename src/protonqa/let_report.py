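"""LET_d evaluation artifacts for biological-robustness review.

Two conventions drive the reports: the *in-field* region is where dose
exceeds 10% of the prescription (LET_d outside it is masked to zero for
display), and the *high-dose/high-LET overlap* is where dose exceeds 80%
of the prescription AND LET_d exceeds 6 keV/um — the region flagged for
review when it falls on a critical structure.  Both thresholds are strict
inequalities; volumes are voxel counts times voxel volume, reported in
cm^3, with no partial-volume correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import DoseGrid, PipelineError, StructureSet, require_same_geometry

MM3_PER_CM3 = 1000.0


def mask_infield(
    let: DoseGrid, dose: DoseGrid, rx_gy: float, fraction: float = 0.10
) -> DoseGrid:
    """Zero LET_d outside the in-field region (dose strictly > fraction x Rx)."""
    require_same_geometry(let, dose)
    if rx_gy <= 0:
        raise PipelineError("prescription dose must be > 0")
    infield = dose.values > fraction * rx_gy
    out = let.copy()
    out.values[~infield] = 0.0
    return out


@dataclass
class OverlapReport:
    """High-dose/high-LET overlap region and its volumes."""

    rx_dose_gy: float
    dose_fraction: float
    let_threshold_kev_um: float
    mask: np.ndarray
    volume_cm3: float
    per_structure_cm3: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "rx_dose_gy": self.rx_dose_gy,
            "dose_fraction": self.dose_fraction,
            "let_threshold_kev_um": self.let_threshold_kev_um,
            "overlap_volume_cm3": self.volume_cm3,
            "per_structure_cm3": self.per_structure_cm3,
            "n_voxels": int(np.count_nonzero(self.mask)),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.as_dict(), indent=2))
        return path


def overlap_high_dose_high_let(
    dose: DoseGrid,
    let: DoseGrid,
    rx_gy: float,
    structures: StructureSet | None = None,
    fraction: float = 0.80,
    threshold_kev_um: float = 6.0,
) -> OverlapReport:
    """Region with dose > fraction x Rx AND LET_d > threshold, with volumes."""
    geo = require_same_geometry(dose, let)
    if rx_gy <= 0:
        raise PipelineError("prescription dose must be > 0")
    mask = (dose.values > fraction * rx_gy) & (let.values > threshold_kev_um)
    vv = geo.voxel_volume_mm3 / MM3_PER_CM3
    per_structure: dict[str, float] = {}
    if structures is not None:
        for name in structures.names():
            smask = structures[name].mask
            if smask.shape != mask.shape:
                raise PipelineError(f"structure {name!r} mask shape mismatch")
            per_structure[name] = float(np.count_nonzero(mask & smask) * vv)
    return OverlapReport(
        rx_dose_gy=rx_gy,
        dose_fraction=fraction,
        let_threshold_kev_um=threshold_kev_um,
        mask=mask,
        volume_cm3=float(np.count_nonzero(mask) * vv),
        per_structure_cm3=per_structure,
    )
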