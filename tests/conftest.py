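"""Shared synthetic fixtures: one phantom dataset reused across the suite."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from protonqa import dicom_io
from protonqa.combine import CalibrationTable
from protonqa.core import CTVolume, Geometry
from protonqa.engine import MockEngine, plan_to_jobs
from protonqa.fixtures import (
    FIXTURE_HISTORIES,
    FIXTURE_N_BATCHES,
    FixtureSpec,
    make_fixtures,
    reference_dose,
)
from protonqa.preprocess import CouchModel, DensityCurve, preprocess_ct


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    return tmp_path_factory.mktemp("synth")


@pytest.fixture(scope="session")
def dataset(fixture_dir):
    """Full synthetic input set written to disk once per session."""
    return make_fixtures(FixtureSpec(out_dir=fixture_dir / "inputs"))


@pytest.fixture(scope="session")
def phantom_ct(dataset) -> CTVolume:
    return dicom_io.read_ct_series(dataset["ct"])


@pytest.fixture(scope="session")
def structures(dataset, phantom_ct):
    return dicom_io.read_structures(dataset["structures"], phantom_ct)


@pytest.fixture(scope="session")
def plan(dataset):
    return dicom_io.read_plan(dataset["plan"])


@pytest.fixture(scope="session")
def calibration(dataset) -> CalibrationTable:
    return CalibrationTable.from_csv(dataset["calibration"])


@pytest.fixture(scope="session")
def preprocessed_ct(phantom_ct, structures) -> CTVolume:
    return preprocess_ct(phantom_ct, structures, couch=CouchModel()).ct


@pytest.fixture(scope="session")
def ref_dose(plan, preprocessed_ct, calibration):
    """Noiseless absolute dose for the fixture plan."""
    return reference_dose(plan, preprocessed_ct, calibration)


@pytest.fixture(scope="session")
def batches(plan, preprocessed_ct):
    """Five seeded noisy batches of the fixture plan's single field."""
    engine = MockEngine()
    jobs = plan_to_jobs(plan, FIXTURE_N_BATCHES,
                        FIXTURE_N_BATCHES * FIXTURE_HISTORIES, base_seed=11)
    return [engine.run(j, preprocessed_ct, DensityCurve()) for j in jobs]


@pytest.fixture()
def water_geometry() -> Geometry:
    return Geometry(shape=(10, 12, 14), spacing=(2.0, 2.0, 2.0),
                    origin=(0.0, 0.0, 0.0))


def random_batch_arrays(rng: np.random.Generator, geometry: Geometry,
                        n: int, histories: int = 1000):
    """Random BatchResult list for combination algebra tests."""
    from protonqa.core import DoseGrid
    from protonqa.engine import BatchResult

    out = []
    for i in range(n):
        dose = rng.random(geometry.shape)
        let = 1.0 + 9.0 * rng.random(geometry.shape)
        out.append(BatchResult(
            dose=DoseGrid(dose, "Gy_per_particle", geometry),
            let=DoseGrid(let, "keV_per_um", geometry),
            histories=histories, seed=i, field_index=0, batch_index=i,
        ))
    return out
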