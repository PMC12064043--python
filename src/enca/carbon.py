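"""The ecosystem carbon account.

Tracks biocarbon stocks (aboveground biomass, litter and deadwood, roots,
soil organic carbon, livestock), inflows (net primary production and other
gains), withdrawals (crops, grazing, roundwood), indirect losses
(fuel combustion), and the accessible surplus, all in tonnes of carbon:

C1  = sum of C1_x     opening stocks
C2  = sum of C2_x     total inflow of biocarbon
C3  = sum of C3_x     total withdrawals
C4  = sum of C4_x     net indirect anthropogenic losses
C5  = C3 + C4         total use and induced loss
C10 = C10_1 * C10_2   net ecosystem accessible carbon surplus (NEACS)
SCU  = min(1, C10/C5) sustainable intensity of carbon use
CIUV = combine(SCU, CEH)  ecosystem carbon internal unit value

C10_1 (net accessible inflow) is an input line; a helper equal to
max(0, C2 - C5) is available for synthetic data. Underground (root) carbon
is treated as static between accounting dates. CEH, the carbon health
index, is a diagnostic input defaulting to 1.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, SchemaError
from .nomenclature import Palette
from .raster import Raster
from .water import combine_indices, totals_row

MANDATORY_CODES = (
    "C1_1", "C1_2", "C1_31", "C1_32", "C1_4",
    "C2_3",
    "C3_3", "C3_4",
    "C4_33", "C4_34",
    "C10_1", "C10_2",
    "CEH",
)

ROW_LABELS = {
    "C1_1": "Aboveground living biomass carbon",
    "C1_2": "Litter and deadwood carbon",
    "C1_31": "Roots carbon",
    "C1_32": "Soil Organic Carbon",
    "C1_4": "Livestock carbon",
    "C1": "Opening Stocks Total",
    "C2_3": "NPP (Net Primary Production)",
    "C2_9": "Other biocarbon inflows (residual)",
    "C2": "Total inflow of biocarbon (total gains)",
    "C3_11": "Cereals",
    "C3_13": "Sugar canes",
    "C3_199": "Other crops",
    "C3_3": "Livestock grazing",
    "C3_4": "Roundwood net removals",
    "C3_9": "Other withdrawals (residual)",
    "C3": "Total withdrawals of biocarbon",
    "C4_33": "Combustion of wood fuel roundwood",
    "C4_34": "Combustion of other biocarbon fuel",
    "C4": "Net indirect anthropogenic losses of biocarbon",
    "C5": "Total use and induced loss of ecosystem biocarbon",
    "C10_1": "Net accessible biomass carbon inflow",
    "C10_2": "Index of limitations of use due to nature protection",
    "C10": "NEACS_Net Ecosystem Accessible Carbon Surplus",
    "SCU": "Sustainable intensity of carbon use index (C10/C5)",
    "CEH": "Ecosystem Carbon Health Index",
    "CIUV": "Ecosystem Carbon Internal Unit Value",
}

INDEX_ROWS = ("C10_2", "SCU", "CEH", "CIUV")


def stocks_from_landcover(
    class_raster: Raster,
    watershed_labels: np.ndarray,
    palette: Palette,
    selu_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Carbon stock lines C1_1/C1_2/C1_31/C1_32 per SELU from land cover.

    C1_1 sums per-class area x aboveground density; litter and root stocks
    scale off C1_1 through the per-class litter fraction and root:shoot
    ratio; C1_32 comes from the per-class soil organic carbon density.
    """
    valid = class_raster.valid
    ws = watershed_labels[valid].ravel()
    cls = class_raster.data[valid].ravel()
    missing = sorted({int(c) for c in np.unique(cls)} - set(palette.ids))
    if missing:
        raise ParameterError(f"no carbon parameters for classes {missing}")
    px = class_raster.pixel_area_ha

    out: dict[str, dict[str, float]] = {}
    for ws_id in np.unique(watershed_labels):
        sel = cls[ws == ws_id]
        ids, counts = np.unique(sel, return_counts=True)
        agb = litter = roots = soc = 0.0
        for cid, n in zip(ids, counts):
            c = palette[int(cid)]
            area = n * px
            agb += area * c.agb
            litter += area * c.agb * c.litter_frac
            roots += area * c.agb * c.root_shoot
            soc += area * c.soc
        name = selu_names[int(ws_id)] if selu_names else int(ws_id)
        out[name] = {"C1_1": agb, "C1_2": litter, "C1_31": roots, "C1_32": soc}
    return pd.DataFrame(out)


def accessible_surplus(c10_1, c10_2):
    """C10 = C10_1 x C10_2 (protection limits access to the surplus)."""
    c10_1 = np.asarray(c10_1, dtype=float)
    c10_2 = np.asarray(c10_2, dtype=float)
    if np.any(c10_1 < 0):
        raise DomainError("C10_1 must be non-negative")
    if np.any((c10_2 < 0) | (c10_2 > 1)):
        raise DomainError("C10_2 must lie in [0, 1]")
    out = c10_1 * c10_2
    return float(out) if out.ndim == 0 else out


def sustainable_use_index(c10, c5):
    """SCU = C10/C5 capped at 1; zero use means fully sustainable."""
    c10 = np.asarray(c10, dtype=float)
    c5 = np.asarray(c5, dtype=float)
    if np.any(c5 < 0):
        raise DomainError("C5 must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c5 > 0, c10 / np.where(c5 > 0, c5, 1.0), 1.0)
    out = np.clip(ratio, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def carbon_internal_value(scu, ceh, combiner: str = "mean"):
    """CIUV: combine the sustainable-use index with the health index."""
    return combine_indices(scu, ceh, combiner)


def helper_c10_1(c2, c5):
    """Optional helper: net accessible inflow as max(0, C2 - C5)."""
    out = np.maximum(0.0, np.asarray(c2, dtype=float) - np.asarray(c5, dtype=float))
    return float(out) if out.ndim == 0 else out


def assemble_carbon_account(items: pd.DataFrame, combiner: str = "mean") -> pd.DataFrame:
    """Assemble the carbon account from per-SELU line items.

    ``items``: index = codes, columns = SELUs, tonnes C (indices
    dimensionless). The component sums C1/C2/C3/C4 run over whatever C?_x
    lines are supplied; no fixed component list is assumed.
    """
    for selu in items.columns:
        for code in MANDATORY_CODES:
            if code not in items.index or pd.isna(items.loc[code, selu]):
                raise SchemaError(f"SELU {selu!r}: missing mandatory line item {code}")
    acct = items.astype(float).fillna(0.0).copy()

    def members(prefix):
        return [c for c in acct.index if re.fullmatch(rf"{prefix}_\w+", c)]

    acct.loc["C1"] = acct.loc[members("C1")].sum()
    acct.loc["C2"] = acct.loc[members("C2")].sum()
    acct.loc["C3"] = acct.loc[members("C3")].sum()
    acct.loc["C4"] = acct.loc[members("C4")].sum()
    acct.loc["C5"] = acct.loc["C3"] + acct.loc["C4"]
    acct.loc["C10"] = accessible_surplus(acct.loc["C10_1"], acct.loc["C10_2"])
    acct.loc["SCU"] = sustainable_use_index(acct.loc["C10"], acct.loc["C5"])
    acct.loc["CIUV"] = carbon_internal_value(acct.loc["SCU"], acct.loc["CEH"], combiner)

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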