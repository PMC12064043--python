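"""Socio-ecological landscape units (SELUs).

A SELU is a sub-watershed polygon labelled by its dominant land cover type
(DLT): the SELU group whose classes cover the largest area inside the
watershed. SELU geometry never changes between accounting dates; only the
label may flip when land cover changes the area ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .nomenclature import TIE_BREAK_PRIORITY
from .raster import Raster


def _areas_by_group(
    class_raster: Raster,
    watershed_labels: np.ndarray,
    grouping: dict[int, str],
) -> pd.DataFrame:
    """Area (ha) per (watershed, SELU group)."""
    valid = class_raster.valid
    ws = watershed_labels[valid].ravel()
    cls = class_raster.data[valid].ravel()
    missing = sorted({int(c) for c in np.unique(cls)} - set(grouping))
    if missing:
        raise ParameterError(f"grouping table has no entry for classes {missing}")
    groups = np.array([grouping[int(c)] for c in cls])
    df = pd.DataFrame({"ws": ws, "group": groups})
    counts = df.value_counts(["ws", "group"]).unstack(fill_value=0)
    return counts * class_raster.pixel_area_ha


def dominant_landcover(
    class_raster: Raster,
    watershed_labels: np.ndarray,
    grouping: dict[int, str],
    tie_break: tuple[str, ...] = TIE_BREAK_PRIORITY,
) -> dict[int, str | None]:
    """DLT per watershed: the group with maximal total area.

    Exact area ties are resolved by the declared priority order (natural
    classes first), making the result deterministic and independent of
    pixel ordering. Watersheds that are entirely nodata map to ``None``.
    """
    areas = _areas_by_group(class_raster, watershed_labels, grouping)
    rank = {g: k for k, g in enumerate(tie_break)}
    out: dict[int, str | None] = {}
    for ws_id in np.unique(watershed_labels):
        ws_id = int(ws_id)
        if ws_id not in areas.index:
            out[ws_id] = None  # empty (all-nodata) watershed: flagged
            continue
        row = areas.loc[ws_id]
        row = row[row > 0]
        best = max(row.index, key=lambda g: (row[g], -rank.get(g, len(rank))))
        out[ws_id] = best
    return out


@dataclass
class SeluMap:
    """One unit per watershed, labelled for one accounting date.

    ``units`` columns: selu_id, watershed_id, dlt, selu_type, area_ha,
    excluded (True for all-nodata watersheds).
    """

    units: pd.DataFrame
    date: str
    polygons: dict[int, object] = field(default_factory=dict)  # watershed_id -> shapely geometry

    @property
    def total_area(self) -> float:
        return float(self.units.loc[~self.units.excluded, "area_ha"].sum())

    def type_of(self, watershed_id: int) -> str | None:
        row = self.units[self.units.watershed_id == watershed_id]
        if row.empty or row.iloc[0].excluded:
            return None
        return row.iloc[0].selu_type


def build_selus(
    class_raster: Raster,
    watershed_labels: np.ndarray,
    grouping: dict[int, str],
    date: str,
    polygons: dict[int, object] | None = None,
    tie_break: tuple[str, ...] = TIE_BREAK_PRIORITY,
) -> SeluMap:
    """Build the SELU map for one accounting date.

    The SELU type equals the DLT group name (the grouping table is the
    declared class -> group function, so selu_type is a function of dlt).
    """
    dlt = dominant_landcover(class_raster, watershed_labels, grouping, tie_break)
    valid = class_raster.valid
    records = []
    for k, ws_id in enumerate(sorted(dlt)):
        n_pixels = int(((watershed_labels == ws_id) & valid).sum())
        records.append(
            {
                "selu_id": k + 1,
                "watershed_id": ws_id,
                "dlt": dlt[ws_id],
                "selu_type": dlt[ws_id],
                "area_ha": n_pixels * class_raster.pixel_area_ha,
                "excluded": dlt[ws_id] is None,
            }
        )
    return SeluMap(pd.DataFrame(records), date, polygons or {})
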