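"""Diachronic land-cover accounting.

Cross-tabulates two co-registered categorical rasters (opening and closing
dates), classifies every transition into one of seven causal land-cover flow
classes, and assembles the stock/flow account: opening stocks, formation and
consumption per flow class, net change and closing stocks, all in hectares.

Flow classes
------------
lf1 artificialisation; lf2 extension of agriculture; lf3 internal
conversions and rotations; lf4 management and alteration of forest areas;
lf5 habitat restoration and creation; lf6 changes due to natural and
multiple causes; lf7 other changes not elsewhere classified; lf0 no
observed change.

Internally everything is exact pixel counts; hectares appear only through
multiplication by the pixel area, and rounding is left to presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import NomenclatureError
from .nomenclature import AGRI, FOREST, HUMAN, MANGROVE, Palette, SHRUB, WETLAND
from .raster import Raster, require_aligned

FLOW_CODES = ("lf1", "lf2", "lf3", "lf4", "lf5", "lf6", "lf7")

FLOW_LABELS = {
    "lf1": "Artificial development",
    "lf2": "Agricultural extension",
    "lf3": "Internal conversions",
    "lf4": "Management and alteration of forest land",
    "lf5": "Restoration and development of habitats",
    "lf6": "Changes of land-cover due to natural and multiple causes",
    "lf7": "Other land cover changes",
    "lf0": "No observed change in land cover",
}


@dataclass
class TransitionMatrix:
    """Pixel-count cross-tabulation of opening (rows) vs closing (columns)."""

    classes: list[int]
    counts: pd.DataFrame  # square, integer, index/columns = classes
    pixel_area: float  # ha per pixel

    @property
    def total_pixels(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def opening_stock(self) -> pd.Series:
        """Opening area per class, ha."""
        return self.counts.sum(axis=1) * self.pixel_area

    @property
    def closing_stock(self) -> pd.Series:
        """Closing area per class, ha."""
        return self.counts.sum(axis=0) * self.pixel_area


class FlowRules:
    """Total mapping (from_class, to_class) -> flow code.

    The default rule set is destination-driven with origin overrides,
    evaluated in priority order:

    1. no change -> lf0
    2. to a Human-footprint class -> lf1
    3. crop to crop -> lf3 (rotation)
    4. to a crop class -> lf2
    5. within the forest density classes, or within the mangrove density
       classes -> lf3
    6. woody (forest/mangrove/shrubland) to savannah or shrubland -> lf4
    7. to any natural habitat class (forest, mangrove, shrub, wetland
       vegetation) -> lf5 (regeneration)
    8. to barren/tan/water -> lf6
    9. anything else -> lf7

    Any cell of the mapping can be overridden explicitly.
    """

    def __init__(self, mapping: dict[tuple[int, int], str], classes: list[int]):
        self.classes = list(classes)
        for i in self.classes:
            for j in self.classes:
                if (i, j) not in mapping:
                    raise NomenclatureError(
                        f"flow rules are not total: no rule for {i}->{j}"
                    )
        self.mapping = dict(mapping)

    def __call__(self, from_class: int, to_class: int) -> str:
        return self.mapping[(from_class, to_class)]

    @classmethod
    def default(cls, palette: Palette,
                overrides: dict[tuple[int, int], str] | None = None) -> "FlowRules":
        group = palette.grouping()
        crop = {c.id for c in palette if c.group == AGRI}
        human = {c.id for c in palette if c.group == HUMAN}
        forest = {c.id for c in palette if c.group == FOREST}
        mangrove = {c.id for c in palette if c.group == MANGROVE}
        shrubby = {c.id for c in palette if c.group == SHRUB}
        woody = forest | mangrove | {c.id for c in palette if c.group == SHRUB and not c.habitat} \
            | {c.id for c in palette if c.group == SHRUB}
        habitat = {c.id for c in palette if c.habitat}
        bare = {c.id for c in palette if not c.habitat and c.group not in (HUMAN, AGRI)}

        mapping: dict[tuple[int, int], str] = {}
        for i in palette.ids:
            for j in palette.ids:
                if i == j:
                    code = "lf0"
                elif j in human:
                    code = "lf1"
                elif i in crop and j in crop:
                    code = "lf3"
                elif j in crop:
                    code = "lf2"
                elif (i in forest and j in forest) or (i in mangrove and j in mangrove):
                    code = "lf3"
                elif i in (forest | mangrove) and j in shrubby:
                    code = "lf4"
                elif j in habitat:
                    code = "lf5"
                elif j in bare:
                    code = "lf6"
                else:
                    code = "lf7"
                mapping[(i, j)] = code
        if overrides:
            mapping.update(overrides)
        return cls(mapping, palette.ids)

    @classmethod
    def from_yaml(cls, path: str | Path, palette: Palette) -> "FlowRules":
        """Load overrides from YAML: a list of {from:, to:, flow:} entries."""
        doc = yaml.safe_load(Path(path).read_text()) or []
        overrides = {(int(e["from"]), int(e["to"])): str(e["flow"]) for e in doc}
        return cls.default(palette, overrides)


@dataclass
class FlowAccount:
    """Stock/flow account: areas in hectares, classes as columns."""

    opening_stock: pd.Series
    formation: pd.DataFrame  # index lf1..lf7, columns classes
    consumption: pd.DataFrame

    @property
    def total_formation(self) -> pd.Series:
        return self.formation.sum(axis=0)

    @property
    def total_consumption(self) -> pd.Series:
        return self.consumption.sum(axis=0)

    @property
    def net_change(self) -> pd.Series:
        return self.total_formation - self.total_consumption

    @property
    def closing_stock(self) -> pd.Series:
        return self.opening_stock + self.net_change


def cross_tabulate(
    opening: Raster | np.ndarray,
    closing: Raster | np.ndarray,
    pixel_area: float | None = None,
    palette: Palette | None = None,
) -> TransitionMatrix:
    """Cross-tabulate opening vs closing class rasters.

    A pixel that is nodata at either date is excluded at both, keeping the
    opening and closing universes identical.
    """
    if isinstance(opening, np.ndarray):
        opening = Raster(opening)
    if isinstance(closing, np.ndarray):
        closing = Raster(closing, cellsize=opening.cellsize, origin=opening.origin)
    require_aligned(opening, closing)
    if pixel_area is None:
        pixel_area = opening.pixel_area_ha

    valid = opening.valid & closing.valid
    a = opening.data[valid].astype(np.int64)
    b = closing.data[valid].astype(np.int64)

    observed = np.union1d(np.unique(a), np.unique(b)) if a.size else np.array([], dtype=np.int64)
    if palette is not None:
        alien = [int(c) for c in observed if int(c) not in palette]
        if alien:
            raise NomenclatureError(f"raster contains class codes outside palette: {alien}")
        classes = palette.ids
    else:
        classes = [int(c) for c in observed]

    index = {c: k for k, c in enumerate(classes)}
    n = len(classes)
    ai = np.array([index[int(v)] for v in a], dtype=np.int64)
    bi = np.array([index[int(v)] for v in b], dtype=np.int64)
    counts = np.bincount(ai * n + bi, minlength=n * n).reshape(n, n)
    df = pd.DataFrame(counts, index=classes, columns=classes)
    return TransitionMatrix(classes, df, pixel_area)


def classify_flows(tm: TransitionMatrix, rules: FlowRules) -> FlowAccount:
    """Assign every changed hectare to one flow class.

    Each off-diagonal cell is recorded once as formation of the destination
    class and once as consumption of the origin class; the diagonal (lf0)
    contributes to stocks only.
    """
    classes = tm.classes
    formation = pd.DataFrame(0.0, index=list(FLOW_CODES), columns=classes)
    consumption = pd.DataFrame(0.0, index=list(FLOW_CODES), columns=classes)
    for i in classes:
        for j in classes:
            if i == j:
                continue
            area = tm.counts.loc[i, j] * tm.pixel_area
            if area == 0:
                continue
            code = rules(i, j)
            if code == "lf0":
                continue
            formation.loc[code, j] += area
            consumption.loc[code, i] += area
    return FlowAccount(tm.opening_stock, formation, consumption)


def assemble_account(fa: FlowAccount, names: dict[int, str] | None = None) -> pd.DataFrame:
    """Emit the stock/flow account table (classes as columns, plus Total).

    Row order: opening stock, F_lf1..F_lf7, total formation, C_lf1..C_lf7,
    total consumption, net change, closing stock.
    """
    cols = list(fa.opening_stock.index)
    rows: dict[str, pd.Series] = {"Opening stock": fa.opening_stock}
    for code in FLOW_CODES:
        rows[f"F_{code} {FLOW_LABELS[code]}"] = fa.formation.loc[code]
    rows["Total formation of land cover"] = fa.total_formation
    for code in FLOW_CODES:
        rows[f"C_{code} {FLOW_LABELS[code]}"] = fa.consumption.loc[code]
    rows["Total consumption of land cover"] = fa.total_consumption
    rows["Net change in land cover = F - C"] = fa.net_change
    rows["Closing stock"] = fa.closing_stock
    table = pd.DataFrame(rows).T[cols]
    if names:
        table.columns = [names.get(c, str(c)) for c in table.columns]
    table["Total"] = table.sum(axis=1)
    return table
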