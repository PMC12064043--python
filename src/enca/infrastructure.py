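"""The ecosystem infrastructure (functional services) account.

Landscape side, per SELU and date:

* GBLI - green background landscape index: area-weighted mean of per-class
  greenness weights (0-100), the land-cover biomass potential.
* HNVI - high nature value index: mean protection multiplier (>= 1).
* FI - fragmentation index in [0, 1]: mean of three normalized components,
  effective mesh size / total area, 1 / number of patches, and the
  tree-cover : basin-area ratio. 1 means intact.
* LEP = GBLI x HNVI x FI (reported as the SELU mean composite);
  NLEP = sum over pixels of gbli x hnvi x fi / 100 x pixel area (index-ha).

River side:

* RAWI = sum over segments of length_km x log10(discharge m3/s);
* HNVI_riv - protection multiplier of the river network (the SELU HNVI);
* frag_riv = 1 / (1 + number of dams in the watershed);
* REP = RAWI x HNVI_riv x frag_riv; NREP = REP x SELU area / 100.

TEIP = NLEP + NREP per date; a declared per-year calibration scalar yields
the adjusted TEIPs, whose capped ratio is the use-intensity index EISU.
EIIUV combines EISU with the composite ecosystem health index EHI (input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError, DomainError, ParameterError
from .nomenclature import Palette
from .raster import Raster
from .water import combine_indices

DEFAULT_EHI = 0.94


def gbli(
    class_raster: Raster,
    watershed_labels: np.ndarray,
    greenness: dict[int, float],
) -> pd.Series:
    """Area-weighted mean greenness (0-100) per watershed/SELU."""
    valid = class_raster.valid
    cls = class_raster.data[valid].ravel()
    ws = watershed_labels[valid].ravel()
    missing = sorted({int(c) for c in np.unique(cls)} - set(greenness))
    if missing:
        raise ParameterError(f"no greenness weight for classes {missing}")
    w = np.array([greenness[int(c)] for c in cls], dtype=float)
    df = pd.DataFrame({"ws": ws, "w": w})
    return df.groupby("ws")["w"].mean()


def patch_areas(mask: np.ndarray, pixel_area: float) -> np.ndarray:
    """Areas (ha) of 4-connected patches of a boolean habitat mask."""
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.array([])
    counts = np.bincount(labels.ravel())[1:]
    return counts * pixel_area


def effective_mesh_size(patches: np.ndarray | list, total_area: float) -> float:
    """Jaeger's effective mesh size: sum(A_i^2) / A_total (ha).

    The expected area of the patch containing a randomly placed point;
    equals A_total for a single all-covering patch and A/n for n equal
    patches tiling A.
    """
    if total_area <= 0:
        raise DomainError("total_area must be positive")
    patches = np.asarray(patches, dtype=float)
    if np.any(patches < 0):
        raise DomainError("patch areas must be non-negative")
    if patches.sum() > total_area * (1 + 1e-9):
        raise DomainError("patch areas exceed total area")
    return float((patches**2).sum() / total_area)


def fragmentation_index(meff_norm: float, patch_count_norm: float, tree_ratio: float) -> float:
    """FI: mean of the three normalized components, each in [0, 1]."""
    comps = np.array([meff_norm, patch_count_norm, tree_ratio], dtype=float)
    if np.any((comps < 0) | (comps > 1)):
        raise DomainError(f"fragmentation components outside [0, 1]: {comps}")
    return float(comps.mean())


@dataclass
class RiverSegment:
    """A river reach: geometry in map units, length in km, discharge m3/s."""

    id: int
    geometry: object  # shapely LineString
    length_km: float
    discharge: float
    upstream_ws: int | None = None
    downstream_ws: int | None = None


def rawi(segments, polygon=None, log_base: float = 10.0) -> float:
    """River accessibility weighted index: sum of length x log(discharge).

    Segments are clipped to ``polygon`` (a SELU boundary) when given; a
    segment's length contribution scales with the clipped fraction.
    """
    total = 0.0
    for seg in segments:
        if seg.discharge <= 0:
            raise DataError(f"segment {seg.id}: non-positive discharge {seg.discharge}")
        length = seg.length_km
        if polygon is not None:
            if seg.geometry is None:
                raise DataError(f"segment {seg.id}: no geometry to clip")
            full = seg.geometry.length
            if full == 0:
                continue
            clipped = seg.geometry.intersection(polygon).length
            length = seg.length_km * clipped / full
        total += length * np.log(seg.discharge) / np.log(log_base)
    return float(total)


def landscape_indices(
    class_raster: Raster,
    watershed_labels: np.ndarray,
    palette: Palette,
    protection: Raster | None = None,
) -> pd.DataFrame:
    """Per-SELU landscape indices for one date.

    Returns a DataFrame indexed by watershed id with columns
    area_ha, GBLI, HNVI, FI, LEP, NLEP.
    """
    greenness = palette.greenness()
    habitat_ids = {c.id for c in palette if c.habitat}
    tree_ids = {c.id for c in palette if c.tree}
    px = class_raster.pixel_area_ha
    valid = class_raster.valid
    hnvi_grid = (
        protection.data.astype(float) if protection is not None
        else np.ones(class_raster.shape)
    )

    g = gbli(class_raster, watershed_labels, greenness)
    rows = {}
    for ws_id in np.unique(watershed_labels):
        sel = (watershed_labels == ws_id) & valid
        n = int(sel.sum())
        if n == 0:
            continue
        area = n * px
        data = class_raster.data
        habitat_mask = sel & np.isin(data, list(habitat_ids))
        patches = patch_areas(habitat_mask, px)
        if patches.size:
            meff_norm = effective_mesh_size(patches, area) / area
            patch_norm = 1.0 / patches.size
        else:
            meff_norm = 0.0
            patch_norm = 0.0
        tree_area = float((sel & np.isin(data, list(tree_ids))).sum()) * px
        tree_ratio = min(1.0, tree_area / area)
        fi = fragmentation_index(meff_norm, patch_norm, tree_ratio)
        hnvi = float(hnvi_grid[sel].mean())
        gb = float(g.loc[ws_id])
        gbli_px = np.vectorize(greenness.get)(data[sel])
        nlep = float((gbli_px * hnvi_grid[sel] * fi).sum()) / 100.0 * px
        rows[int(ws_id)] = {
            "area_ha": area,
            "GBLI": gb,
            "HNVI": hnvi,
            "FI": fi,
            "LEP": gb * hnvi * fi,
            "NLEP": nlep,
        }
    return pd.DataFrame(rows).T


def river_indices(
    segments: list[RiverSegment],
    polygons: dict[int, object],
    hnvi: pd.Series | dict | float = 1.0,
    dams: dict[int, int] | None = None,
    areas: pd.Series | dict | None = None,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Per-SELU river indices: RAWI, HNVI_riv, frag_riv, REP, NREP."""
    dams = dams or {}
    rows = {}
    for ws_id, poly in polygons.items():
        r = rawi(segments, poly, log_base)
        h = hnvi if np.isscalar(hnvi) else float(hnvi[ws_id])
        fr = 1.0 / (1.0 + dams.get(ws_id, 0))
        rep = r * h * fr
        area = float(areas[ws_id]) if areas is not None else (
            poly.area / 10_000.0 if poly is not None else 0.0
        )
        rows[int(ws_id)] = {
            "RAWI": r,
            "HNVI_riv": h,
            "frag_riv": fr,
            "REP": rep,
            "NREP": rep * area / 100.0,
        }
    return pd.DataFrame(rows).T


def lep_nlep(gbli_value, hnvi, fi, area_ha):
    """(LEP, NLEP) for a SELU of uniform indices; NLEP in index-ha.

    The per-pixel route in :func:`landscape_indices` is the reference for
    heterogeneous SELUs; this closed form matches it when gbli and hnvi are
    spatially constant.
    """
    lep = gbli_value * hnvi * fi
    return lep, lep * area_ha / 100.0


def use_intensity(teip_open_adj, teip_close_adj):
    """EISU = min(1, adjusted closing TEIP / adjusted opening TEIP)."""
    t1 = np.asarray(teip_open_adj, dtype=float)
    t2 = np.asarray(teip_close_adj, dtype=float)
    if np.any(t1 <= 0):
        raise DomainError("adjusted opening TEIP must be positive for EISU")
    out = np.clip(t2 / t1, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def assemble_infra_account(
    land_open: pd.DataFrame,
    land_close: pd.DataFrame,
    river_open: pd.DataFrame,
    river_close: pd.DataFrame,
    ehi: pd.Series | float = DEFAULT_EHI,
    adjustment: tuple[float, float] = (1.0, 1.0),
    combiner: str = "mean",
) -> pd.DataFrame:
    """Assemble the infrastructure account (SELUs as columns).

    ``land_*`` carry area_ha/GBLI/HNVI/FI/LEP/NLEP, ``river_*`` carry
    RAWI/HNVI_riv/frag_riv/REP/NREP, both indexed by SELU. ``adjustment``
    holds the (opening, closing) per-year TEIP calibration scalars;
    the neutral default applies no calibration.
    """
    selus = land_open.index
    ehi = pd.Series(ehi, index=selus) if np.isscalar(ehi) else pd.Series(ehi)
    a_open, a_close = adjustment

    rows = {
        "RC1 Opening stock of land cover": land_open["area_ha"],
        "GBLI_open": land_open["GBLI"],
        "HNVI_open": land_open["HNVI"],
        "FI_open": land_open["FI"],
        "LEP_open": land_open["LEP"],
        "NLEP_open": land_open["NLEP"],
        "RAWI_open": river_open["RAWI"],
        "HNVI_riv_open": river_open["HNVI_riv"],
        "frag_riv_open": river_open["frag_riv"],
        "REP_open": river_open["REP"],
        "NREP_open": river_open["NREP"],
        "RC2 Closing stock of land cover": land_close["area_ha"],
        "GBLI_close": land_close["GBLI"],
        "HNVI_close": land_close["HNVI"],
        "FI_close": land_close["FI"],
        "LEP_close": land_close["LEP"],
        "NLEP_close": land_close["NLEP"],
        "RAWI_close": river_close["RAWI"],
        "HNVI_riv_close": river_close["HNVI_riv"],
        "frag_riv_close": river_close["frag_riv"],
        "REP_close": river_close["REP"],
        "NREP_close": river_close["NREP"],
    }
    acct = pd.DataFrame(rows).T
    acct.loc["TEIP1"] = land_open["NLEP"] + river_open["NREP"]
    acct.loc["TEIP2"] = land_close["NLEP"] + river_close["NREP"]
    acct.loc["TEIP1_adj"] = acct.loc["TEIP1"] * a_open
    acct.loc["TEIP2_adj"] = acct.loc["TEIP2"] * a_close
    acct.loc["EISU"] = use_intensity(acct.loc["TEIP1_adj"], acct.loc["TEIP2_adj"])
    acct.loc["EHI"] = ehi
    acct.loc["EIIUV"] = combine_indices(acct.loc["EISU"], acct.loc["EHI"], combiner)
    return acct
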