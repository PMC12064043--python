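"""Bundled reference data: the published ecosystem accounts of the
Mahavavy-Kinkony Complex protected area (north-western Madagascar),
accounting period 2013-2018.

These tables are the published per-SELU line items and index inputs of the
land-cover, water, carbon, infrastructure and capability accounts; the
derived rows (balances, use indices, internal unit values, capabilities)
are *recomputed* by this package's assembly functions, which is what the
regression and acceptance tests exercise.

Two reconciliation lines appear in the carbon items (``C2_9``, ``C3_9``):
the published inflow and withdrawal totals exceed the sums of their
published components, so the gap is carried as an explicit residual line
rather than silently inflating a named component. The protection index
``C10_2`` is stored at the precision implied by the published C10/C10_1
ratio; its 2-decimal display value is recoverable by rounding.

SELU columns, in account order: Human footprint, Agricultural landscape,
Shrubland, Forest landscape, Mangrove Landscape, Wetland, Estuary.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

SELUS = (
    "Human footprint",
    "Agricultural landscape",
    "Shrubland",
    "Forest landscape",
    "Mangrove Landscape",
    "Wetland",
    "Estuary",
)

#: per-year TEIP calibration scalars of the published accounts
MKC_ADJUSTMENT = (1.12869, 1.08544)


def _read(name: str) -> pd.DataFrame:
    with resources.files("enca.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_mkc_landcover() -> pd.DataFrame:
    """Published land-cover stock/flow account (ha), classes as columns.

    Rows: opening, F_lf1..F_lf7, total_formation, C_lf1..C_lf7,
    total_consumption, closing. The printed per-flow cells carry a few
    hectares of rounding drift against the printed totals; the total rows
    are the published ones and are self-consistent with the closing stocks.
    """
    df = _read("mkc_landcover_account.csv")
    return df.set_index("row")


def _items(name: str, year: int | str) -> pd.DataFrame:
    df = _read(name)
    df = df[df.year.astype(str) == str(year)]
    if df.empty:
        raise KeyError(f"no line items for year {year}")
    wide = df.pivot(index="code", columns="selu", values="value")
    return wide[list(SELUS)].rename_axis(None).rename_axis(None, axis=1)


def load_mkc_water_items(year: int | str) -> pd.DataFrame:
    """Water line items (1000 m3; W14 dimensionless), codes x SELUs."""
    return _items("mkc_water_items.csv", year)


def load_mkc_carbon_items(year: int | str) -> pd.DataFrame:
    """Carbon line items (tC; indices dimensionless), codes x SELUs."""
    return _items("mkc_carbon_items.csv", year)


def load_mkc_infrastructure() -> dict[str, pd.DataFrame | pd.Series]:
    """Infrastructure account inputs, ready for ``assemble_infra_account``.

    Returns a dict with ``land_open``/``land_close`` (area_ha, GBLI, HNVI,
    FI, LEP, NLEP), ``river_open``/``river_close`` (RAWI, HNVI_riv,
    frag_riv, REP, NREP) and ``ehi``. LEP/REP composites are recomputed
    from the index inputs; NLEP/NREP are published inputs (the underlying
    per-pixel surfaces are not published).
    """
    df = _read("mkc_infrastructure.csv").set_index("selu").loc[list(SELUS)]
    out: dict[str, pd.DataFrame | pd.Series] = {}
    for side in ("open", "close"):
        land = pd.DataFrame(
            {
                "area_ha": df[f"area_{side}"],
                "GBLI": df[f"GBLI_{side}"],
                "HNVI": df[f"HNVI_{side}"],
                "FI": df[f"FI_{side}"],
                "NLEP": df[f"NLEP_{side}"],
            }
        )
        land["LEP"] = land["GBLI"] * land["HNVI"] * land["FI"]
        river = pd.DataFrame(
            {
                "RAWI": df[f"RAWI_{side}"],
                "HNVI_riv": df[f"HNVI_riv_{side}"],
                "frag_riv": df[f"frag_riv_{side}"],
            }
        )
        river["REP"] = river["RAWI"] * river["HNVI_riv"] * river["frag_riv"]
        river["NREP"] = df[f"NREP_{side}"]
        out[f"land_{side}"] = land
        out[f"river_{side}"] = river
    out["ehi"] = df["EHI"]
    return out


def load_mkc_capability(year: int | str) -> pd.DataFrame:
    """Published capability table for one date, codes x SELUs + Total.

    Only the resource/index inputs and the published capability rows are
    carried; the Total column holds the published totals where printed.
    """
    df = _read("mkc_capability.csv")
    df = df[df.year.astype(str) == str(year)]
    wide = df.pivot(index="code", columns="selu", values="value")
    cols = [s for s in SELUS if s in wide.columns]
    if "Total" in wide.columns:
        cols += ["Total"]
    return wide[cols].rename_axis(None).rename_axis(None, axis=1)
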