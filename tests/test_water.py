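"""Water account: ETr estimate, derived rows, indices, totals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enca import (
    EtrParams,
    assemble_water_account,
    estimate_etr,
    totals_row,
    water_internal_value,
    water_use_index,
)
from enca.errors import DomainError, ParameterError, SchemaError


class TestEtr:
    def test_equal_averages_give_identity(self):
        p = EtrParams(1000, 1000, 123.0)
        assert estimate_etr(p, "as-printed") == pytest.approx(123.0)
        assert estimate_etr(p, "inverted") == pytest.approx(123.0)

    def test_zero_precipitation(self):
        assert estimate_etr(EtrParams(1554, 777, 0.0)) == 0.0

    def test_both_orientations(self):
        p = EtrParams(1554, 777, 100.0)
        assert estimate_etr(p, "as-printed") == pytest.approx(200.0)
        assert estimate_etr(p, "inverted") == pytest.approx(50.0)

    def test_as_printed_warns_when_inflating(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="enca.water"):
            estimate_etr(EtrParams(1554, 777, 100.0), "as-printed")
        assert any("ETr" in r.message for r in caplog.records)

    def test_nonpositive_averages_rejected(self):
        with pytest.raises(ParameterError):
            estimate_etr(EtrParams(0, 777, 10.0))
        with pytest.raises(ParameterError):
            estimate_etr(EtrParams(1554, -1, 10.0))


class TestUseIndex:
    def test_ratio_and_cap(self):
        assert water_use_index(53983, 68974) == pytest.approx(0.78266, abs=1e-5)
        assert water_use_index(200, 100) == 1.0

    def test_zero_use_is_fully_sustainable(self):
        assert water_use_index(10.0, 0.0) == 1.0

    def test_negative_resource_clamps_to_zero(self):
        assert water_use_index(-5.0, 10.0) == 0.0
        assert water_use_index(0.0, 10.0) == 0.0

    @settings(max_examples=60, derandomize=True)
    @given(
        w6=st.floats(0, 1e6), bump=st.floats(0, 1e5),
        w9=st.floats(0.1, 1e6),
    )
    def test_monotone_in_resource(self, w6, bump, w9):
        assert water_use_index(w6 + bump, w9) >= water_use_index(w6, w9)


class TestInternalValue:
    def test_mean_combiner(self):
        assert water_internal_value(0.53456, 0.95) == pytest.approx(0.74228, abs=1e-5)
        assert water_internal_value(1.0, 1.0) == 1.0

    def test_product_combiner(self):
        assert water_internal_value(0.5, 0.9, "product") == pytest.approx(0.45)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            water_internal_value(1.2, 0.9)

    @settings(max_examples=60, derandomize=True)
    @given(w13=st.floats(0, 1), w14=st.floats(0, 1), bump=st.floats(0, 1))
    def test_monotone_in_health(self, w13, w14, bump):
        hi = min(1.0, w14 + bump)
        assert water_internal_value(w13, hi) >= water_internal_value(w13, w14)


@pytest.fixture
def integer_items():
    """Two hand-computable SELU columns with round numbers."""
    codes = {
        "W1_1": [100, 200], "W1_2": [10, 20], "W1_4": [50, 60], "W1_5": [5, 6],
        "W2_1": [1000, 2000], "W2_2": [-200, -400], "W2_3": [600, 800],
        "W2_4": [40, 50], "W2_5": [10, 10], "W2_6": [50, 40],
        "W3_1": [400, 900], "W3_3": [700, 500], "W3_4": [100, 300],
        "W3_8": [20, 30], "W14": [0.95, 0.89],
    }
    return pd.DataFrame(codes, index=["a", "b"]).T


class TestAssembly:
    def test_derived_rows_match_hand_sums(self, integer_items):
        acct = assemble_water_account(integer_items)
        a = acct["a"]
        assert a["W2"] == 1000 - 200 + 600 + 40 + 10 + 50 == 1500
        assert a["W2a"] == 1400
        assert a["W2b"] == 100
        assert a["W3"] == 400 + 700 + 100 + 20 == 1220
        assert a["W4"] == 1500 - 1220 == 280
        assert a["W4a"] == 600
        assert a["W6"] == 1400 + 100 - 700 == 800
        assert a["W9"] == 500
        assert a["W13"] == 1.0  # 800/500 capped
        b = acct["b"]
        assert b["W6"] == 2400 + 100 - 500 == 2000
        assert b["W9"] == 1200
        assert b["W13"] == 1.0

    def test_balance_identity_any_input(self, rng):
        codes = ["W1_1", "W1_2", "W1_4", "W1_5", "W2_1", "W2_2", "W2_3",
                 "W2_4", "W2_5", "W2_6", "W3_1", "W3_3", "W3_4", "W3_8"]
        items = pd.DataFrame(
            rng.uniform(0, 1e5, size=(len(codes), 5)), index=codes
        )
        items.loc["W2_2"] *= -0.5
        items.loc["W14"] = 0.9
        acct = assemble_water_account(items)
        for c in range(5):
            assert acct.iloc[:, c]["W4"] == pytest.approx(
                acct.iloc[:, c]["W2"] - acct.iloc[:, c]["W3"]
            )

    def test_all_zero_items_zero_derived(self):
        items = pd.DataFrame(
            0.0,
            index=list(
                "W1_1 W1_2 W1_4 W1_5 W2_1 W2_2 W2_3 W2_4 W2_5 W2_6 "
                "W3_1 W3_3 W3_4 W3_8".split()
            ),
            columns=["only"],
        )
        items.loc["W14"] = 0.0
        acct = assemble_water_account(items)
        for code in ("W2", "W3", "W4", "W6", "W9"):
            assert acct.loc[code, "only"] == 0.0
        assert acct.loc["W13", "only"] == 1.0  # no use at all

    def test_missing_mandatory_code_names_selu_and_code(self, integer_items):
        broken = integer_items.drop(index="W3_1")
        with pytest.raises(SchemaError, match=r"'a'.*W3_1"):
            assemble_water_account(broken)

    def test_w3_sums_all_supplied_outflow_items(self, integer_items):
        extra = integer_items.copy()
        extra.loc["W3_7"] = [5, 5]  # an unprinted outflow component
        acct = assemble_water_account(extra)
        assert acct.loc["W3", "a"] == 1225


class TestTotals:
    def test_volume_totals_sum(self):
        assert totals_row(pd.Series([1.0, 2.0, 3.0]), "volume") == 6.0

    def test_index_totals_mean_matches_published_pattern(self):
        w13 = pd.Series([0.50, 0.53, 1.00, 1.00, 0.78, 0.50, 0.98])
        assert round(totals_row(w13, "index"), 2) == 0.76

    def test_single_selu_total_is_value(self):
        assert totals_row(pd.Series([0.42]), "index") == pytest.approx(0.42)
        assert totals_row(pd.Series([0.42]), "volume") == pytest.approx(0.42)
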