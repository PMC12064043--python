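"""Land-cover accounting: cross-tabulation, flow classification, closure."""

import numpy as np
import pandas as pd
import pytest

from enca import (
    FlowAccount,
    FlowRules,
    assemble_account,
    classify_flows,
    cross_tabulate,
    default_palette,
)
from enca.errors import AlignmentError, NomenclatureError
from enca.landcover import FLOW_CODES
from enca.raster import Raster


@pytest.fixture(scope="module")
def rules():
    return FlowRules.default(default_palette())


class TestCrossTabulate:
    def test_identical_rasters_are_diagonal(self, rng):
        data = rng.choice([11, 51, 61], size=(8, 8))
        tm = cross_tabulate(data, data.copy(), pixel_area=1.0)
        off = tm.counts.to_numpy().sum() - np.trace(tm.counts.to_numpy())
        assert off == 0
        assert tm.total_pixels == 64

    def test_hand_enumerated_two_by_two(self):
        a, b, c = 11, 21, 31
        opening = np.array([[a, a], [b, b]])
        closing = np.array([[a, c], [b, b]])
        tm = cross_tabulate(opening, closing, pixel_area=1.0)
        assert tm.counts.loc[a, c] == 1
        assert tm.counts.loc[a, a] == 1
        assert tm.counts.loc[b, b] == 2

    def test_scene_scenario_truth_recovered(self, scene):
        from conftest import available
        from enca import apply_change_scenario

        n = available(scene, 61, 50)
        assert n > 0
        changed = apply_change_scenario(scene, [(61, 41, n)])
        tm = cross_tabulate(changed.opening, changed.closing,
                            palette=changed.config.palette)
        assert tm.counts.loc[61, 41] == n

    def test_nodata_at_either_date_excluded_at_both(self):
        opening = Raster(np.full((3, 3), 11))
        closing = Raster(np.full((3, 3), 11))
        opening.data[0, 0] = opening.nodata
        closing.data[2, 2] = closing.nodata
        tm = cross_tabulate(opening, closing)
        assert tm.total_pixels == 7
        assert (tm.opening_stock == tm.closing_stock).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            cross_tabulate(np.zeros((2, 2), int) + 11, np.zeros((3, 3), int) + 11)

    def test_class_outside_palette_raises(self):
        data = np.full((2, 2), 999)
        with pytest.raises(NomenclatureError):
            cross_tabulate(data, data, palette=default_palette())

    def test_stock_identities(self, rng):
        opening = rng.choice([11, 21, 51, 61, 131], size=(16, 16))
        closing = rng.choice([11, 21, 51, 61, 131], size=(16, 16))
        tm = cross_tabulate(opening, closing, pixel_area=0.5)
        assert tm.opening_stock.sum() == pytest.approx(16 * 16 * 0.5)
        assert tm.counts.sum(axis=1).mul(0.5).equals(tm.opening_stock)
        assert tm.counts.sum(axis=0).mul(0.5).equals(tm.closing_stock)


class TestClassifyFlows:
    def test_all_diagonal_means_no_flows(self, rules):
        data = np.full((4, 4), 61)
        fa = classify_flows(cross_tabulate(data, data, pixel_area=1.0,
                                           palette=default_palette()), rules)
        assert fa.formation.to_numpy().sum() == 0
        assert fa.consumption.to_numpy().sum() == 0

    def test_single_cell_bookkeeping(self, rules):
        # 100 ha of savannah converted to rice: agricultural extension
        pal = default_palette()
        counts = pd.DataFrame(0, index=pal.ids, columns=pal.ids)
        counts.loc[51, 21] = 100
        from enca.landcover import TransitionMatrix

        fa = classify_flows(TransitionMatrix(pal.ids, counts, 1.0), rules)
        assert fa.formation.loc["lf2", 21] == 100
        assert fa.consumption.loc["lf2", 51] == 100
        assert fa.formation.drop(index="lf2").to_numpy().sum() == 0

    def test_default_rules_follow_causal_reading(self, rules):
        assert rules(51, 11) == "lf1"  # to village: artificialisation
        assert rules(61, 21) == "lf2"  # forest to rice: agricultural extension
        assert rules(21, 41) == "lf3"  # crop rotation
        assert rules(61, 62) == "lf3"  # density change within forest
        assert rules(61, 51) == "lf4"  # forest to savannah: alteration
        assert rules(51, 61) == "lf5"  # regeneration
        assert rules(63, 102) == "lf6"  # mangrove to tan: natural causes
        assert rules(61, 61) == "lf0"

    def test_conservation_on_random_matrices(self, rules, rng):
        from enca.landcover import TransitionMatrix

        pal = default_palette()
        ids = pal.ids[:5]
        for _ in range(25):
            counts = pd.DataFrame(
                rng.integers(0, 50, size=(5, 5)), index=ids, columns=ids
            )
            tm = TransitionMatrix(ids, counts, 0.25)
            fa = classify_flows(tm, rules)
            off = (counts.to_numpy().sum() - np.trace(counts.to_numpy())) * 0.25
            assert fa.total_formation.sum() == pytest.approx(off)
            assert fa.total_consumption.sum() == pytest.approx(off)


class TestAccountAssembly:
    def test_stock_closure_on_random_rasters(self, rules, rng):
        opening = rng.choice([11, 21, 51, 61, 131], size=(12, 12))
        closing = rng.choice([11, 21, 51, 61, 131], size=(12, 12))
        tm = cross_tabulate(opening, closing, pixel_area=0.0225,
                            palette=default_palette())
        fa = classify_flows(tm, rules)
        pd.testing.assert_series_equal(
            fa.closing_stock, tm.closing_stock, check_names=False
        )
        assert fa.net_change.sum() == pytest.approx(0.0, abs=1e-9)

    def test_brute_force_oracle_small_grid(self, rules, rng):
        """Account equals per-pixel enumeration on a 32x32 raster."""
        ids = [11, 21, 51, 61, 62, 131]
        opening = rng.choice(ids, size=(32, 32))
        closing = rng.choice(ids, size=(32, 32))
        px = 0.0225
        tm = cross_tabulate(opening, closing, pixel_area=px, palette=default_palette())
        fa = classify_flows(tm, rules)

        formation = {code: {} for code in FLOW_CODES}
        consumption = {code: {} for code in FLOW_CODES}
        for r in range(32):
            for c in range(32):
                i, j = int(opening[r, c]), int(closing[r, c])
                if i == j:
                    continue
                code = rules(i, j)
                formation[code][j] = formation[code].get(j, 0) + px
                consumption[code][i] = consumption[code].get(i, 0) + px
        for code in FLOW_CODES:
            for j, v in formation[code].items():
                assert fa.formation.loc[code, j] == pytest.approx(v)
            for i, v in consumption[code].items():
                assert fa.consumption.loc[code, i] == pytest.approx(v)

    def test_table_layout_and_totals(self, rules, scene):
        from conftest import available
        from enca import apply_change_scenario

        changed = apply_change_scenario(scene, [(61, 41, available(scene, 61, 30))])
        tm = cross_tabulate(changed.opening, changed.closing,
                            palette=changed.config.palette)
        table = assemble_account(classify_flows(tm, rules),
                                 changed.config.palette.names)
        assert table.index[0] == "Opening stock"
        assert table.index[-1] == "Closing stock"
        assert "Total" in table.columns
        # area conservation: identical landscape total at both dates
        assert table.loc["Opening stock", "Total"] == pytest.approx(
            table.loc["Closing stock", "Total"]
        )
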