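"""DICOM round trips, contour rasterization and the integrity check."""

import numpy as np
import pytest

from protonqa import dicom_io
from protonqa.core import (
    CTVolume,
    DoseGrid,
    FieldDef,
    Geometry,
    IntegrityError,
    PipelineError,
    Spot,
    SpotPlan,
)
from protonqa.fixtures import PhantomSpec, make_phantom_ct, phantom_contours


class TestCTSeries:
    def test_round_trip_identity(self, phantom_ct, tmp_path):
        dicom_io.write_ct_series(phantom_ct, tmp_path / "ct")
        back = dicom_io.read_ct_series(tmp_path / "ct")
        np.testing.assert_array_equal(back.hu, phantom_ct.hu)
        assert back.geometry.same_grid(phantom_ct.geometry)

    def test_fixture_phantom_dims_and_water(self, phantom_ct):
        assert phantom_ct.geometry.shape == (24, 80, 48)
        # cylinder interior is water (0 HU) away from the inserts
        nz, ny, nx = phantom_ct.geometry.shape
        assert phantom_ct.hu[2, ny // 2, nx // 2] == 0

    def test_missing_slice_is_an_integrity_error(self, phantom_ct, tmp_path):
        paths = dicom_io.write_ct_series(phantom_ct, tmp_path / "ct")
        paths[7].unlink()
        with pytest.raises(IntegrityError, match="slice"):
            dicom_io.read_ct_series(tmp_path / "ct")

    def test_mixed_frames_rejected(self, phantom_ct, tmp_path):
        dicom_io.write_ct_series(phantom_ct, tmp_path / "a")
        other = phantom_ct.copy()
        other.frame_of_reference_uid = ""
        extra = dicom_io.write_ct_series(other, tmp_path / "b")
        (tmp_path / "a" / "zz.dcm").write_bytes(extra[0].read_bytes())
        with pytest.raises(IntegrityError, match="frame"):
            dicom_io.read_ct_series(tmp_path / "a")


class TestStructures:
    def test_cylinder_mask_volume_matches_analytic(self, tmp_path):
        r, sp, n = 100.0, 2.5, 88
        geo = Geometry(shape=(4, n, n), spacing=(sp, sp, 3.0),
                       origin=(-(n - 1) * sp / 2, -(n - 1) * sp / 2, 0.0))
        ct = CTVolume(np.zeros(geo.shape, dtype=np.int16), geo,
                      frame_of_reference_uid="1.2.3")
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        circle = r * np.column_stack([np.cos(theta), np.sin(theta)])
        zs = geo.axis_coords("z")
        path = dicom_io.write_structures(
            {"BODY": [(float(z), circle) for z in zs]}, ct, tmp_path / "c.dcm")
        body = dicom_io.read_structures(path, ct).body().mask
        analytic = np.pi * r**2 * geo.shape[0] * geo.spacing[2]
        measured = body.sum() * geo.voxel_volume_mm3
        assert abs(measured - analytic) / analytic < 0.01

    def test_square_contour_rasterizes_to_exact_voxel_block(self, tmp_path):
        geo = Geometry(shape=(3, 30, 30), spacing=(1.0, 1.0, 1.0),
                       origin=(0.0, 0.0, 0.0))
        ct = CTVolume(np.zeros(geo.shape, dtype=np.int16), geo,
                      frame_of_reference_uid="1.2.3")
        # square spanning voxel centers 10..19 on slice z=1
        square = np.array([[9.5, 9.5], [19.5, 9.5], [19.5, 19.5], [9.5, 19.5]])
        path = dicom_io.write_structures(
            {"BODY": [(1.0, square)]}, ct, tmp_path / "ss.dcm")
        sset = dicom_io.read_structures(path, ct)
        mask = sset["BODY"].mask
        assert mask[1].sum() == 100
        assert mask[[0, 2]].sum() == 0
        # brute-force voxel-center point-in-polygon over the block
        expected = np.zeros((30, 30), dtype=bool)
        expected[10:20, 10:20] = True
        np.testing.assert_array_equal(mask[1], expected)

    def test_rasterization_error_shrinks_with_voxel_size(self):
        r = 45.0
        errors = []
        for spacing in (4.0, 2.0):
            n = int(120 / spacing)
            geo = Geometry(shape=(2, n, n), spacing=(spacing, spacing, 3.0),
                           origin=(-(n - 1) * spacing / 2,
                                   -(n - 1) * spacing / 2, 0.0))
            theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
            poly = r * np.column_stack([np.cos(theta), np.sin(theta)])
            mask = dicom_io.rasterize_polygon(poly, geo)
            area = mask.sum() * spacing**2
            errors.append(abs(area - np.pi * r**2))
        assert errors[1] < errors[0]

    def test_missing_body_contour_is_an_error(self, phantom_ct, tmp_path):
        path = dicom_io.write_structures({}, phantom_ct, tmp_path / "e.dcm")
        with pytest.raises(IntegrityError, match="body"):
            dicom_io.read_structures(path, phantom_ct)


class TestPlan:
    def test_round_trip_spot_count_and_meterset(self, dataset, plan):
        # 3 energy layers x 25 spots
        assert len(plan.fields) == 1
        assert len(plan.fields[0].spots) == 75
        assert plan.fields[0].energies() == [92.5, 97.0, 101.5]

    def test_total_mu_matches_field_meterset(self, dataset):
        import pydicom

        ds = pydicom.dcmread(dataset["plan"])
        meterset = float(ds.FractionGroupSequence[0]
                         .ReferencedBeamSequence[0].BeamMeterset)
        plan = dicom_io.read_plan(dataset["plan"])
        assert plan.fields[0].total_mu == pytest.approx(meterset, rel=1e-6)

    def test_zero_mu_spot_retained(self, phantom_ct, tmp_path):
        spots = [Spot(92.5, 0.0, 0.0, 1.0), Spot(92.5, 6.0, 0.0, 0.0)]
        plan = SpotPlan("P", 2.0, [FieldDef(0.0, 0.0, (0, 0, 0), spots=spots)])
        path = dicom_io.write_plan(plan, tmp_path / "p.dcm")
        back = dicom_io.read_plan(path)
        assert len(back.fields[0].spots) == 2
        assert back.fields[0].spots[1].mu == 0.0

    def test_two_field_order_preserved(self, tmp_path):
        spots = [Spot(92.5, 0.0, 0.0, 1.0)]
        plan = SpotPlan("P", 2.0, [
            FieldDef(0.0, 0.0, (0, 0, 0), spots=list(spots), name="A"),
            FieldDef(180.0, 0.0, (0, 0, 0), spots=list(spots), name="B"),
        ])
        back = dicom_io.read_plan(dicom_io.write_plan(plan, tmp_path / "p.dcm"))
        assert [f.name for f in back.fields] == ["A", "B"]
        assert [f.gantry_angle for f in back.fields] == [0.0, 180.0]

    def test_photon_plan_rejected(self, tmp_path):
        import pydicom
        from pydicom.dataset import Dataset

        from protonqa.dicom_io import _base_dataset

        ds = _base_dataset("1.2.840.10008.5.1.4.1.1.481.5", "RTPLAN", "1.2.3")
        ds.BeamSequence = [Dataset()]
        ds.save_as(tmp_path / "photon.dcm", enforce_file_format=True)
        with pytest.raises(PipelineError, match="modality"):
            dicom_io.read_plan(tmp_path / "photon.dcm")


class TestDose:
    def _geo(self):
        return Geometry(shape=(8, 10, 12), spacing=(2.0, 2.5, 3.0),
                        origin=(-10.0, -5.0, 0.0))

    def test_uniform_grid_quantization_bound(self, tmp_path):
        grid = DoseGrid(np.full((8, 10, 12), 2.0), "Gy", self._geo())
        back = dicom_io.read_dose(dicom_io.write_dose(grid, tmp_path / "d.dcm"))
        assert np.abs(back.values - 2.0).max() <= 2e-4
        assert back.geometry.same_grid(grid.geometry)

    def test_random_grid_within_scaling_quantization(self, tmp_path):
        rng = np.random.default_rng(3)
        vals = rng.random((8, 10, 12)) * 4.0
        grid = DoseGrid(vals, "Gy", self._geo())
        back = dicom_io.read_dose(dicom_io.write_dose(grid, tmp_path / "d.dcm"))
        assert np.abs(back.values - vals).max() <= 1e-4 * vals.max()

    def test_zero_grid_round_trips_exactly(self, tmp_path):
        grid = DoseGrid(np.zeros((8, 10, 12)), "Gy", self._geo())
        back = dicom_io.read_dose(dicom_io.write_dose(grid, tmp_path / "z.dcm"))
        assert (back.values == 0.0).all()

    def test_let_grid_keeps_unit_label(self, tmp_path):
        rng = np.random.default_rng(4)
        vals = rng.random((8, 10, 12)) * 12.0
        grid = DoseGrid(vals, "keV_per_um", self._geo())
        back = dicom_io.read_dose(dicom_io.write_dose(grid, tmp_path / "l.dcm"))
        assert back.unit == "keV_per_um"
        assert np.abs(back.values - vals).max() <= 1e-4 * vals.max()

    def test_per_particle_grid_refused(self, tmp_path):
        grid = DoseGrid(np.ones((8, 10, 12)), "Gy_per_particle", self._geo())
        with pytest.raises(PipelineError, match="calibrat"):
            dicom_io.write_dose(grid, tmp_path / "pp.dcm")


class TestIntegrity:
    def test_complete_inputs_pass(self, phantom_ct, structures, plan,
                                  calibration):
        report = dicom_io.check_integrity(
            phantom_ct, structures, plan,
            calibration_energies=calibration.energies())
        assert report.ok
        assert report.missing_items == []

    def test_missing_structures_reported_not_raised(self, phantom_ct, plan):
        report = dicom_io.check_integrity(phantom_ct, None, plan)
        assert not report.ok
        assert "structure set" in report.missing_items

    def test_frame_mismatch_detected(self, phantom_ct, structures, plan):
        other = phantom_ct.copy()
        other.frame_of_reference_uid = "9.9.9"
        report = dicom_io.check_integrity(other, structures, plan)
        assert not report.frame_of_reference_consistent
        assert not report.ok

    def test_uncovered_plan_energy_reported(self, phantom_ct, structures, plan):
        report = dicom_io.check_integrity(
            phantom_ct, structures, plan, calibration_energies=[92.5, 97.0])
        assert not report.ok
        assert any("101.5" in item for item in report.missing_items)
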