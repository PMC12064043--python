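"""Infrastructure indices: GBLI, effective mesh size, FI, RAWI, EISU."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, box

from enca import (
    assemble_infra_account,
    default_palette,
    effective_mesh_size,
    fragmentation_index,
    gbli,
    landscape_indices,
    lep_nlep,
    rawi,
    RiverSegment,
)
from enca.errors import DataError, DomainError, ParameterError
from enca.infrastructure import patch_areas, use_intensity
from enca.raster import Raster


class TestGbli:
    def test_uniform_class(self):
        raster = Raster(np.full((5, 5), 63))
        labels = np.ones((5, 5), dtype=int)
        g = gbli(raster, labels, default_palette().greenness())
        assert g.loc[1] == 95.0

    def test_fifty_fifty_mean(self):
        weights = {1: 40.0, 2: 80.0}
        data = np.array([1] * 8 + [2] * 8).reshape(4, 4)
        g = gbli(Raster(data), np.ones((4, 4), dtype=int), weights)
        assert g.loc[1] == pytest.approx(60.0)

    def test_matches_per_pixel_brute_force(self, rng):
        weights = default_palette().greenness()
        ids = [11, 51, 61, 131]
        data = rng.choice(ids, size=(9, 9))
        labels = rng.integers(1, 4, size=(9, 9))
        g = gbli(Raster(data), labels, weights)
        for ws in (1, 2, 3):
            sel = labels == ws
            if sel.any():
                expected = np.mean([weights[int(v)] for v in data[sel]])
                assert g.loc[ws] == pytest.approx(expected)

    def test_missing_weight_raises(self):
        with pytest.raises(ParameterError, match="7"):
            gbli(Raster(np.full((2, 2), 7)), np.ones((2, 2), int), {1: 10.0})


class TestEffectiveMeshSize:
    def test_single_patch_limit(self):
        assert effective_mesh_size([10.0], 10.0) == 10.0

    @pytest.mark.parametrize("n", [1, 2, 4, 5, 10])
    def test_equal_tiling_closed_form(self, n):
        area = 100.0
        patches = [area / n] * n
        assert effective_mesh_size(patches, area) == pytest.approx(area / n)

    def test_direct_arithmetic(self):
        assert effective_mesh_size([4.0, 1.0], 10.0) == pytest.approx(1.7)

    def test_zero_total_area_rejected(self):
        with pytest.raises(DomainError):
            effective_mesh_size([1.0], 0.0)

    def test_splitting_never_increases_meff(self, rng):
        area = 64.0
        patches = [32.0, 16.0, 16.0]
        before = effective_mesh_size(patches, area)
        # split the largest patch in two
        split = [16.0, 16.0, 16.0, 16.0]
        assert effective_mesh_size(split, area) <= before

    def test_patch_labelling_on_hand_grid(self):
        mask = np.array(
            [
                [1, 1, 0, 0],
                [1, 0, 0, 1],
                [0, 0, 1, 1],
                [0, 0, 0, 0],
            ],
            dtype=bool,
        )
        areas = sorted(patch_areas(mask, 1.0))
        assert areas == [3.0, 3.0]  # two 4-connected patches of 3 pixels


class TestFragmentationIndex:
    def test_intact_landscape(self):
        assert fragmentation_index(1.0, 1.0, 1.0) == 1.0

    def test_mean_of_components(self):
        assert fragmentation_index(1.0, 0.5, 0.0) == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            fragmentation_index(1.2, 0.5, 0.5)

    def test_isolated_pixels_on_toy_grid(self):
        """Fully fragmented 8x8 checkerboard: FI from hand-computed parts."""
        mask = np.indices((8, 8)).sum(axis=0) % 2 == 0  # 32 isolated pixels
        areas = patch_areas(mask, 1.0)
        assert len(areas) == 32
        total = 64.0
        meff_norm = effective_mesh_size(areas, total) / total  # 32/64/64
        fi = fragmentation_index(meff_norm, 1 / 32, 0.0)
        assert fi == pytest.approx((32 / 64 / 64 + 1 / 32 + 0.0) / 3)


class TestRawi:
    def seg(self, length, q, geom=None):
        return RiverSegment(1, geom, length, q)

    def test_direct_arithmetic(self):
        assert rawi([self.seg(10.0, 100.0)]) == pytest.approx(20.0)

    def test_unit_discharge_contributes_zero(self):
        assert rawi([self.seg(5.0, 1.0)]) == 0.0

    def test_no_rivers(self):
        assert rawi([]) == 0.0

    def test_nonpositive_discharge_names_segment(self):
        with pytest.raises(DataError, match="segment 1"):
            rawi([self.seg(5.0, 0.0)])

    def test_clipping_scales_length(self):
        geom = LineString([(0, 0), (200, 0)])
        half = box(-10, -10, 100, 10)  # covers half of the reach
        full = rawi([self.seg(10.0, 100.0, geom)])
        clipped = rawi([self.seg(10.0, 100.0, geom)], half)
        assert clipped == pytest.approx(full / 2)

    def test_log_base_configurable(self):
        assert rawi([self.seg(1.0, np.e)], log_base=np.e) == pytest.approx(1.0)


class TestLepNlep:
    def test_published_pattern(self):
        lep, _ = lep_nlep(59.91, 1.00, 0.62, 6241)
        assert lep == pytest.approx(37.14, abs=0.02)
        rep, _ = lep_nlep(18.77, 1.14, 1.00, 0)
        assert rep == pytest.approx(21.40, abs=0.02)

    def test_zero_fragmentation_zeroes_potential(self):
        lep, nlep = lep_nlep(80.0, 1.1, 0.0, 500.0)
        assert lep == 0.0 and nlep == 0.0

    def test_pixel_route_matches_closed_form_when_uniform(self):
        raster = Raster(np.full((6, 6), 61))
        labels = np.ones((6, 6), dtype=int)
        land = landscape_indices(raster, labels, default_palette())
        area = 36 * raster.pixel_area_ha
        assert land.loc[1, "FI"] == 1.0  # single intact habitat patch
        assert land.loc[1, "GBLI"] == 90.0
        _, nlep = lep_nlep(90.0, 1.0, 1.0, area)
        assert land.loc[1, "NLEP"] == pytest.approx(nlep)


class TestAssembly:
    def frames(self, teip1, teip2):
        land_o = pd.DataFrame(
            {"area_ha": [100.0], "GBLI": [80.0], "HNVI": [1.0], "FI": [1.0],
             "LEP": [80.0], "NLEP": [teip1 * 0.6]}, index=["s"])
        land_c = land_o.assign(NLEP=teip2 * 0.6)
        riv_o = pd.DataFrame(
            {"RAWI": [10.0], "HNVI_riv": [1.0], "frag_riv": [1.0],
             "REP": [10.0], "NREP": [teip1 * 0.4]}, index=["s"])
        riv_c = riv_o.assign(NREP=teip2 * 0.4)
        return land_o, land_c, riv_o, riv_c

    def test_teip_additivity_and_eisu(self):
        acct = assemble_infra_account(*self.frames(1000.0, 700.0), ehi=0.92)
        assert acct.loc["TEIP1", "s"] == pytest.approx(1000.0)
        assert acct.loc["TEIP2", "s"] == pytest.approx(700.0)
        assert acct.loc["EISU", "s"] == pytest.approx(0.7)
        assert acct.loc["EIIUV", "s"] == pytest.approx((0.7 + 0.92) / 2)

    def test_eisu_caps_at_one(self):
        acct = assemble_infra_account(*self.frames(1000.0, 1038.0), ehi=0.94)
        assert acct.loc["EISU", "s"] == 1.0
        assert acct.loc["EIIUV", "s"] == pytest.approx(0.97)

    def test_eisu_invariant_to_common_scaling(self):
        a = assemble_infra_account(*self.frames(1000.0, 700.0))
        b = assemble_infra_account(*self.frames(3000.0, 2100.0))
        assert a.loc["EISU", "s"] == pytest.approx(b.loc["EISU", "s"])

    def test_adjustment_scalars_applied(self):
        acct = assemble_infra_account(
            *self.frames(1000.0, 700.0), adjustment=(1.1287, 1.0854)
        )
        assert acct.loc["TEIP1_adj", "s"] == pytest.approx(1128.7)
        assert acct.loc["TEIP2_adj", "s"] == pytest.approx(759.78)

    def test_zero_opening_teip_flagged(self):
        with pytest.raises(DomainError):
            use_intensity(0.0, 10.0)
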