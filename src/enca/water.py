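"""The ecosystem water account.

Per-SELU line items (volumes in thousand cubic metres per year) are
assembled into the standard coded account: total inflows W2 (precipitation,
net groundwater drainage, upstream inflows, artificial inflows and
returns), total outflows W3 (evapotranspiration, downstream outflows,
abstraction, artificial outflows), and the derived balances and indices:

W2  = W2_1 + ... + W2_6          total inflows
W2a = W2_1 + W2_2 + W2_3         total natural renewable resource
W2b = W2_4 + W2_5 + W2_6         total secondary resource
W3  = sum of all supplied W3_x   total outflows
W4  = W2 - W3                    net ecosystem water balance
W4a = W2_1 - W3_1                available effective rainfall
W6  = W2a + W2b - W3_2 - W3_3    net primary & secondary resource
W9  = W3_1 + W3_4                total use of ecosystem water
W13 = min(1, W6 / W9)            sustainable-use index
W15 = combine(W13, W14)          water ecological internal unit value

W14 (composite health index) is a diagnostic input, not computed here.
The index combiner defaults to the arithmetic mean; a product combiner is
available via ``combiner="product"``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, SchemaError

log = logging.getLogger(__name__)

#: line items every SELU column must supply (W3_2 and W3_8 are optional,
#: defaulting to zero).
MANDATORY_CODES = (
    "W1_1", "W1_2", "W1_4", "W1_5",
    "W2_1", "W2_2", "W2_3", "W2_4", "W2_5", "W2_6",
    "W3_1", "W3_3", "W3_4",
    "W14",
)

ROW_LABELS = {
    "W1_1": "Lakes and reservoirs",
    "W1_2": "Rivers and other streams",
    "W1_4": "Ground water",
    "W1_5": "Soil and vegetation",
    "W2_1": "Precipitation",
    "W2_2": "Groundwater drainage to river minus percolation",
    "W2_3": "Natural inflows from upstream territories",
    "W2_4": "Artificial inflows of water from other territories and the sea",
    "W2_5": "Waste water returns/discharge to inland water assets",
    "W2_6": "Other returns of abstracted water to inland water bodies",
    "W2": "Total inflows of water = SUM (W21 to W26)",
    "W3_1": "Actual evapotranspiration",
    "W3_2": "Transfers of water",
    "W3_3": "Natural outflows to downstream territories and the sea",
    "W3_4": "Abstraction from inland water bodies",
    "W3_8": "Artificial outflow of water to other territories and the sea",
    "W3": "Total outflows of water",
    "W4": "Net ecosystem water balance = W2-W3",
    "W4a": "Available effective rainfall = W2_1 - W3_1",
    "W2a": "Total natural renewable water resources (TNWR) = W21 + W22 + W23",
    "W2b": "Total secondary water resources = W24 + W25 + W26",
    "W6": "Net primary & secondary water resource = W2a+W2b-W32-W33",
    "W9": "Total Use of Ecosystem Water = W3_1 + W3_4",
    "W13": "Index of water use",
    "W14": "Composite index of ecosystem water health",
    "W15": "Water ecological internal unit value",
}

#: rows whose Total column is a cross-SELU mean rather than a sum.
INDEX_ROWS = ("W13", "W14", "W15")


@dataclass
class EtrParams:
    """Inputs of the empirical actual-evapotranspiration estimate.

    p_avg : long-term average precipitation, mm/yr.
    etr_avg : long-term average evapotranspiration, mm/yr.
    p : precipitation of the accounting period, mm (scalar or array).
    """

    p_avg: float
    etr_avg: float
    p: float | np.ndarray


def estimate_etr(params: EtrParams, orientation: str = "inverted") -> float | np.ndarray:
    """Estimate actual evapotranspiration by climatological scaling of P.

    ``orientation="as-printed"`` uses the ratio p_avg/etr_avg; whenever
    p_avg > etr_avg this yields ETr > P, which is physically doubtful for an
    actual-evapotranspiration estimate, so the default is the ``"inverted"``
    ratio etr_avg/p_avg (capped implicitly by P when etr_avg < p_avg). The
    as-printed orientation is retained for comparability and logs a warning
    when it inflates ETr beyond P.
    """
    if params.p_avg <= 0 or params.etr_avg <= 0:
        raise ParameterError("p_avg and etr_avg must be positive")
    if orientation == "as-printed":
        ratio = params.p_avg / params.etr_avg
        if ratio > 1:
            log.warning(
                "as-printed ETr orientation gives ETr = %.3f x P > P; "
                "consider orientation='inverted'", ratio,
            )
    elif orientation == "inverted":
        ratio = params.etr_avg / params.p_avg
    else:
        raise ParameterError(f"unknown ETr orientation: {orientation!r}")
    return ratio * np.asarray(params.p) if np.ndim(params.p) else ratio * params.p


def water_use_index(w6, w9):
    """W13 = W6/W9 clamped to [0, 1]; exhausted denominator means no use,
    hence full sustainability (W13 = 1)."""
    w6 = np.asarray(w6, dtype=float)
    w9 = np.asarray(w9, dtype=float)
    if np.any(w9 < 0):
        raise DomainError("W9 (total use) must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(w9 > 0, w6 / np.where(w9 > 0, w9, 1.0), 1.0)
    out = np.clip(ratio, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def combine_indices(use_index, health_index, combiner: str = "mean"):
    """Internal-unit-value combiner shared by the three accounts."""
    u = np.asarray(use_index, dtype=float)
    h = np.asarray(health_index, dtype=float)
    if np.any((u < 0) | (u > 1)) or np.any((h < 0) | (h > 1)):
        raise DomainError("index arguments must lie in [0, 1]")
    if combiner == "mean":
        out = (u + h) / 2.0
    elif combiner == "product":
        out = u * h
    else:
        raise ParameterError(f"unknown index combiner: {combiner!r}")
    return float(out) if out.ndim == 0 else out


def water_internal_value(w13, w14, combiner: str = "mean"):
    """W15: combine the use index W13 with the health index W14."""
    return combine_indices(w13, w14, combiner)


def totals_row(values: pd.Series, kind: str) -> float:
    """Total-column aggregation: volumes sum, indices average across SELUs."""
    if len(values) == 0:
        raise SchemaError("totals need at least one SELU")
    if kind == "volume":
        return float(values.sum())
    if kind == "index":
        return float(values.mean())
    raise ParameterError(f"unknown totals kind: {kind!r}")


def assemble_water_account(items: pd.DataFrame, combiner: str = "mean") -> pd.DataFrame:
    """Assemble the water account from per-SELU line items.

    Parameters
    ----------
    items : DataFrame
        Index = line-item codes, columns = SELU names, values in 1000 m3
        (W14 dimensionless). Optional codes default to 0.
    combiner : "mean" or "product"
        How W13 and W14 are combined into W15.

    Returns
    -------
    DataFrame with one row per code (line items then derived rows) and one
    column per SELU plus a Total column.
    """
    for selu in items.columns:
        for code in MANDATORY_CODES:
            if code not in items.index or pd.isna(items.loc[code, selu]):
                raise SchemaError(f"SELU {selu!r}: missing mandatory line item {code}")
    acct = items.astype(float).copy()

    def get(code):
        if code in acct.index:
            return acct.loc[code].fillna(0.0)
        return pd.Series(0.0, index=acct.columns)

    inflow_codes = [c for c in acct.index if re.fullmatch(r"W2_\d+", c)]
    outflow_codes = [c for c in acct.index if re.fullmatch(r"W3_\d+", c)]
    acct.loc["W2"] = acct.loc[inflow_codes].sum()
    acct.loc["W2a"] = get("W2_1") + get("W2_2") + get("W2_3")
    acct.loc["W2b"] = get("W2_4") + get("W2_5") + get("W2_6")
    acct.loc["W3"] = acct.loc[outflow_codes].sum()
    acct.loc["W4"] = acct.loc["W2"] - acct.loc["W3"]
    acct.loc["W4a"] = get("W2_1") - get("W3_1")
    acct.loc["W6"] = acct.loc["W2a"] + acct.loc["W2b"] - get("W3_2") - get("W3_3")
    acct.loc["W9"] = get("W3_1") + get("W3_4")
    acct.loc["W13"] = water_use_index(acct.loc["W6"], acct.loc["W9"])
    acct.loc["W15"] = water_internal_value(acct.loc["W13"], acct.loc["W14"], combiner)

    order = [c for c in ROW_LABELS if c in acct.index]
    extra = [c for c in acct.index if c not in ROW_LABELS]
    acct = acct.loc[order + extra]
    acct["Total"] = [
        totals_row(acct.loc[c, acct.columns != "Total"],
                   "index" if c in INDEX_ROWS else "volume")
        for c in acct.index
    ]
    return acct
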