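"""Preprocessing contract: air override, couch, board, overrides, density."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protonqa.core import CTVolume, Geometry, PipelineError
from protonqa.preprocess import (
    AIR_HU,
    BoardGeometry,
    CouchModel,
    CouchSlab,
    DensityCurve,
    HUOverride,
    apply_overrides,
    burn_range_shifter_board,
    hu_to_density,
    override_outside_body,
    preprocess_ct,
    replace_couch,
)


@pytest.fixture()
def body_mask(phantom_ct):
    geo = phantom_ct.geometry
    xs, ys = geo.axis_coords("x"), geo.axis_coords("y")
    r2 = xs[None, None, :] ** 2 + ys[None, :, None] ** 2
    return np.broadcast_to(r2 <= 45.0**2, geo.shape).copy()


class TestOutsideBodyOverride:
    def test_external_artifact_removed(self, phantom_ct, body_mask):
        assert (phantom_ct.hu == 500).any()  # blanket-like artifact present
        out = override_outside_body(phantom_ct, body_mask)
        assert not (out.hu == 500).any()
        assert (out.hu[~body_mask] == AIR_HU).all()

    def test_inside_body_untouched(self, phantom_ct, body_mask):
        out = override_outside_body(phantom_ct, body_mask)
        np.testing.assert_array_equal(out.hu[body_mask],
                                      phantom_ct.hu[body_mask])

    def test_all_inside_mask_is_identity(self, phantom_ct):
        mask = np.ones(phantom_ct.geometry.shape, dtype=bool)
        out = override_outside_body(phantom_ct, mask)
        np.testing.assert_array_equal(out.hu, phantom_ct.hu)

    def test_changed_count_matches_prediction(self, phantom_ct, body_mask):
        prov = []
        expected = int(((~body_mask) & (phantom_ct.hu != AIR_HU)).sum())
        override_outside_body(phantom_ct, body_mask, prov)
        assert prov[0].voxels_changed == expected

    def test_idempotent(self, phantom_ct, body_mask):
        once = override_outside_body(phantom_ct, body_mask)
        twice = override_outside_body(once, body_mask)
        np.testing.assert_array_equal(once.hu, twice.hu)

    def test_shape_mismatch_rejected(self, phantom_ct):
        with pytest.raises(Exception, match="shape"):
            override_outside_body(phantom_ct, np.ones((2, 2, 2), bool))


class TestCouch:
    couch = CouchModel(slabs=(CouchSlab(9.0, 120.0, 200),
                              CouchSlab(30.0, 120.0, -700)), offset_mm=6.0)

    def test_burned_voxel_count_matches_slab_volume(self, phantom_ct, body_mask):
        aired = override_outside_body(phantom_ct, body_mask)
        out = replace_couch(aired, body_mask, self.couch)
        geo = phantom_ct.geometry
        nz = geo.shape[0]
        changed = (out.hu != aired.hu)
        for slab in self.couch.slabs:
            analytic = slab.thickness_mm * slab.width_mm * nz * geo.spacing[2]
            count = (out.hu == slab.hu_value)[changed].sum() if False else \
                int(((out.hu == slab.hu_value) & changed).sum())
            measured = count * geo.voxel_volume_mm3
            # within one voxel layer per face (thickness and width faces)
            dy, dx = geo.spacing[1], geo.spacing[0]
            layer = (slab.width_mm * dy + slab.thickness_mm * dx) \
                * nz * geo.spacing[2]
            assert abs(measured - analytic) <= layer

    def test_body_voxels_never_modified(self, phantom_ct, body_mask):
        aired = override_outside_body(phantom_ct, body_mask)
        out = replace_couch(aired, body_mask, self.couch)
        np.testing.assert_array_equal(out.hu[body_mask], aired.hu[body_mask])

    def test_out_of_grid_couch_is_identity(self, phantom_ct, body_mask, caplog):
        couch = CouchModel(slabs=(CouchSlab(20.0, 120.0, 200),),
                           offset_mm=500.0)
        aired = override_outside_body(phantom_ct, body_mask)
        with caplog.at_level("WARNING"):
            out = replace_couch(aired, body_mask, couch)
        np.testing.assert_array_equal(out.hu, aired.hu)
        assert any("outside the grid" in r.message for r in caplog.records)

    def test_couch_intersecting_body_rejected(self, phantom_ct, body_mask):
        couch = CouchModel(slabs=(CouchSlab(20.0, 120.0, 200),),
                           offset_mm=-30.0)
        aired = override_outside_body(phantom_ct, body_mask)
        with pytest.raises(PipelineError, match="intersect"):
            replace_couch(aired, body_mask, couch)


class TestOverrides:
    def test_clip_override(self, phantom_ct, structures):
        out = apply_overrides(phantom_ct, structures,
                              [HUOverride("CLIP", 3000)])
        clip = structures["CLIP"].mask
        assert clip.any()
        assert (out.hu[clip] == 3000).all()
        np.testing.assert_array_equal(out.hu[~clip], phantom_ct.hu[~clip])

    def test_empty_override_list_is_identity(self, phantom_ct, structures):
        out = apply_overrides(phantom_ct, structures, [])
        np.testing.assert_array_equal(out.hu, phantom_ct.hu)

    def test_later_override_wins_on_overlap(self, phantom_ct, structures):
        out = apply_overrides(phantom_ct, structures, [
            HUOverride("CLIP", 1000), HUOverride("CLIP", 2000)])
        assert (out.hu[structures["CLIP"].mask] == 2000).all()

    def test_unknown_structure_rejected(self, phantom_ct, structures):
        with pytest.raises(PipelineError, match="NOPE"):
            apply_overrides(phantom_ct, structures, [HUOverride("NOPE", 0)])


class TestRangeShifterBoard:
    def _fine_ct(self):
        # 1 mm spacing along the beam axis so slab volumes are exact
        geo = Geometry(shape=(4, 100, 20), spacing=(2.0, 1.0, 2.0),
                       origin=(-19.0, -50.0, 0.0))
        hu = np.full(geo.shape, -1000, dtype=np.int16)
        return CTVolume(hu, geo)

    def test_wet_matches_thickness_times_density(self):
        ct = self._fine_ct()
        body = np.zeros(ct.geometry.shape, bool)
        body[:, 60:80, :] = True  # slab "body" downstream
        # beam travels +y; board occupies [-40, 0) just upstream of the body
        board = BoardGeometry(thickness_mm=40.0, entry_face_mm=0.0,
                              axis="y", direction=+1, half_width_mm=100.0)
        out = burn_range_shifter_board(ct, body, board, hu_value=-100)
        rho = hu_to_density(out.hu)
        wet = rho[0, :, 10].sum() * ct.geometry.spacing[1] \
            - hu_to_density(ct.hu)[0, :, 10].sum() * ct.geometry.spacing[1]
        expected = 40.0 * float(hu_to_density(-100))
        assert abs(wet - expected) / expected < 0.02

    def test_zero_thickness_is_identity(self, phantom_ct, body_mask):
        board = BoardGeometry(thickness_mm=0.0, entry_face_mm=-80.0)
        out = burn_range_shifter_board(phantom_ct, body_mask, board, -100)
        np.testing.assert_array_equal(out.hu, phantom_ct.hu)

    def test_board_voxel_count_matches_volume(self):
        ct = self._fine_ct()
        body = np.zeros(ct.geometry.shape, bool)
        board = BoardGeometry(thickness_mm=40.0, entry_face_mm=-5.0,
                              axis="y", direction=+1, half_width_mm=10.0)
        out = burn_range_shifter_board(ct, body, board, hu_value=-100)
        count = int((out.hu == -100).sum())
        geo = ct.geometry
        # 40 rows of 1 mm along y; x centers at odd mm, 10 within +-10 mm
        assert count == 40 * 10 * geo.shape[0]

    def test_board_through_body_rejected(self, phantom_ct, body_mask):
        board = BoardGeometry(thickness_mm=40.0, entry_face_mm=-20.0,
                              axis="y", direction=-1)
        with pytest.raises(PipelineError, match="body"):
            burn_range_shifter_board(phantom_ct, body_mask, board, -100)


class TestDensityCurve:
    def test_configured_endpoints(self):
        assert hu_to_density(-1000) == pytest.approx(0.00121)
        assert hu_to_density(0) == pytest.approx(1.000)
        assert hu_to_density(-2000) == pytest.approx(0.00121)  # clamped

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-1024, 4000), st.floats(-1024, 4000))
    def test_monotone(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert hu_to_density(lo) <= hu_to_density(hi)

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            DensityCurve(control_points=((0.0, 1.0), (0.0, 2.0)))


class TestFullChain:
    def test_body_only_changed_by_named_overrides(self, phantom_ct, structures):
        res = preprocess_ct(phantom_ct, structures, couch=CouchModel(),
                            overrides=[HUOverride("CLIP", 2500)])
        body = structures.body().mask
        clip = structures["CLIP"].mask
        inside_unchanged = body & ~clip
        np.testing.assert_array_equal(res.ct.hu[inside_unchanged],
                                      phantom_ct.hu[inside_unchanged])
        assert (res.ct.hu[clip] == 2500).all()

    def test_provenance_is_machine_readable(self, phantom_ct, structures):
        res = preprocess_ct(phantom_ct, structures, couch=CouchModel())
        dicts = res.provenance_dicts()
        assert [d["rule"] for d in dicts] == [
            "override_outside_body", "replace_couch"]
        assert all(d["voxels_changed"] >= 0 for d in dicts)
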