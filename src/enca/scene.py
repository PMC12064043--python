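"""Synthetic study areas with known ground truth.

Generates a fully self-contained landscape — paired opening/closing land
cover rasters, a sub-watershed partition, a river network, a protection
zoning layer and per-SELU account line items — so that every downstream
account can be tested without satellite or field inputs.

Construction:

* land cover: seeded region growing from random seed points, giving the
  contiguous class patches that fragmentation metrics need;
* watersheds: Voronoi cells of random seed points snapped to pixel
  boundaries — an exact partition with irregular shapes and no DEM;
* rivers: a random spanning tree over watershed centroids draining to a
  single outlet, with discharge accumulating downstream (so it decreases
  upstream);
* line items: deterministic functions of land cover composition, river
  geometry and climate, in the coded structure the water and carbon
  accounts expect. Determinism here is what makes a no-change scenario
  close to an exactly zero ecological balance.

Default conditions emulate a dry-tropical protected-area landscape:
15 m pixels (0.0225 ha), a 16-class nomenclature, 7 sub-watersheds,
1554 mm/yr average precipitation.
"""

from __future__ import annotations

import hashlib
import heapq
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString

from .errors import ConfigurationError, ScenarioError
from .landcover import FlowRules, classify_flows, cross_tabulate
from .nomenclature import AGRI, HUMAN, SHRUB, Palette, default_palette
from .raster import Raster, read_ascii_grid, write_ascii_grid
from .vector import pixel_polygon, read_geojson, write_geojson
from .infrastructure import RiverSegment
from .water import EtrParams, estimate_etr


@dataclass
class Climate:
    """Climate drivers: long-term averages and per-period precipitation (mm)."""

    p_avg: float = 1554.0
    etr_avg: float = 1300.0
    p_series: dict[str, float] = field(
        default_factory=lambda: {"2013": 1554.0, "2018": 1453.0}
    )


@dataclass
class ProtectionZone:
    """A rectangular high-nature-value zone in fractional grid coordinates.

    ``bounds`` = (row0, col0, row1, col1) as fractions of the grid; pixels
    inside get the protection ``weight`` (a multiplier >= 1).
    """

    bounds: tuple[float, float, float, float] = (0.5, 0.0, 1.0, 0.5)
    weight: float = 1.14


@dataclass
class SceneConfig:
    """Everything needed to generate a synthetic scene deterministically."""

    grid_shape: tuple[int, int] = (96, 96)
    pixel_area_ha: float = 0.0225  # 15 m pixels
    palette: Palette = field(default_factory=default_palette)
    n_watersheds: int = 7
    protection_zones: list[ProtectionZone] = field(
        default_factory=lambda: [ProtectionZone()]
    )
    climate: Climate = field(default_factory=Climate)
    dates: tuple[str, str] = ("2013", "2018")
    seed: int = 0
    patches_per_class: int = 3
    base_discharge: float = 8.0  # m3/s at the outlet-most reach unit
    dams: dict[int, int] = field(default_factory=dict)

    @property
    def cellsize(self) -> float:
        return float(np.sqrt(self.pixel_area_ha * 10_000.0))

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ConfigurationError(f"invalid grid shape {self.grid_shape}")
        if len(self.palette) == 0:
            raise ConfigurationError("empty class palette")
        if self.pixel_area_ha <= 0:
            raise ConfigurationError("pixel_area_ha must be positive")
        if not 1 <= self.n_watersheds <= rows * cols:
            raise ConfigurationError(
                f"n_watersheds={self.n_watersheds} not in [1, {rows * cols}]"
            )
        if self.climate.p_avg <= 0 or self.climate.etr_avg <= 0:
            raise ConfigurationError("climate averages must be positive")
        for z in self.protection_zones:
            if z.weight < 1:
                raise ConfigurationError("protection weight must be >= 1")
        if len(self.dates) != 2:
            raise ConfigurationError("exactly two accounting dates required")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "grid_shape": list(self.grid_shape),
            "pixel_area_ha": self.pixel_area_ha,
            "palette": self.palette.to_records(),
            "n_watersheds": self.n_watersheds,
            "protection_zones": [
                {"bounds": list(z.bounds), "weight": z.weight}
                for z in self.protection_zones
            ],
            "climate": asdict(self.climate),
            "dates": list(self.dates),
            "seed": self.seed,
            "patches_per_class": self.patches_per_class,
            "base_discharge": self.base_discharge,
            "dams": {int(k): int(v) for k, v in self.dams.items()},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(
            grid_shape=tuple(d["grid_shape"]),
            pixel_area_ha=d["pixel_area_ha"],
            palette=Palette.from_records(d["palette"]),
            n_watersheds=d["n_watersheds"],
            protection_zones=[
                ProtectionZone(tuple(z["bounds"]), z["weight"])
                for z in d["protection_zones"]
            ],
            climate=Climate(**d["climate"]),
            dates=tuple(d["dates"]),
            seed=d["seed"],
            patches_per_class=d["patches_per_class"],
            base_discharge=d["base_discharge"],
            dams={int(k): int(v) for k, v in d.get("dams", {}).items()},
        )


@dataclass
class SyntheticScene:
    """A generated study area plus its ground truth."""

    config: SceneConfig
    opening: Raster
    closing: Raster
    watershed_labels: np.ndarray
    watershed_polygons: dict[int, object]
    rivers: list[RiverSegment]
    protection: Raster
    truth_transitions: pd.DataFrame  # pixel counts, palette x palette
    truth_flow_totals: pd.Series  # ha per lf code
    line_items: dict[tuple[str, str], pd.DataFrame]  # (account, date) -> items

    @property
    def watershed_ids(self) -> list[int]:
        return sorted(int(i) for i in np.unique(self.watershed_labels))

    def discharge_factor(self, date: str) -> float:
        """Per-date scaling of river discharge with precipitation."""
        return self.config.climate.p_series[date] / self.config.climate.p_avg

    def rivers_at(self, date: str) -> list[RiverSegment]:
        s = self.discharge_factor(date)
        return [
            RiverSegment(r.id, r.geometry, r.length_km, r.discharge * s,
                         r.upstream_ws, r.downstream_ws)
            for r in self.rivers
        ]

    def equals(self, other: "SyntheticScene") -> bool:
        if not (
            self.opening.equals(other.opening)
            and self.closing.equals(other.closing)
            and np.array_equal(self.watershed_labels, other.watershed_labels)
            and self.truth_transitions.equals(other.truth_transitions)
        ):
            return False
        if len(self.rivers) != len(other.rivers):
            return False
        for a, b in zip(self.rivers, other.rivers):
            if not (
                a.id == b.id
                and np.isclose(a.length_km, b.length_km)
                and np.isclose(a.discharge, b.discharge)
                and a.upstream_ws == b.upstream_ws
                and a.downstream_ws == b.downstream_ws
            ):
                return False
        for key, df in self.line_items.items():
            odf = other.line_items.get(key)
            if odf is None or not np.allclose(
                df.sort_index().to_numpy(), odf.sort_index().to_numpy()
            ):
                return False
        return True


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _grow_patches(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Randomized multi-source flood fill: contiguous class patches."""
    rows, cols = config.grid_shape
    ids = config.palette.ids
    n_seeds = max(len(ids), config.patches_per_class * len(ids))
    n_seeds = min(n_seeds, rows * cols)
    flat = rng.choice(rows * cols, size=n_seeds, replace=False)
    seed_classes = list(ids) + [int(rng.choice(ids)) for _ in range(n_seeds - len(ids))]
    seed_classes = seed_classes[:n_seeds]

    grid = np.full((rows, cols), -1, dtype=np.int64)
    heap: list[tuple[float, int, int, int, int]] = []
    tick = 0
    for pix, cls in zip(flat, seed_classes):
        r, c = divmod(int(pix), cols)
        heapq.heappush(heap, (rng.random(), tick, r, c, cls))
        tick += 1
    while heap:
        _, _, r, c, cls = heapq.heappop(heap)
        if grid[r, c] != -1:
            continue
        grid[r, c] = cls
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and grid[rr, cc] == -1:
                heapq.heappush(heap, (rng.random(), tick, rr, cc, cls))
                tick += 1
    return grid


def _watershed_partition(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Pixel-snapped Voronoi cells of random seed points (exact partition)."""
    rows, cols = config.grid_shape
    flat = rng.choice(rows * cols, size=config.n_watersheds, replace=False)
    seeds = np.array([divmod(int(p), cols) for p in flat], dtype=float)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1).reshape(rows, cols) + 1
    return labels.astype(np.int64)


def _centroid_xy(labels: np.ndarray, ws_id: int, cellsize: float) -> tuple[float, float]:
    rows = labels.shape[0]
    r, c = np.nonzero(labels == ws_id)
    x = (c.mean() + 0.5) * cellsize
    y = (rows - 1 - r.mean() + 0.5) * cellsize
    return float(x), float(y)


def _build_rivers(config: SceneConfig, labels: np.ndarray,
                  rng: np.random.Generator) -> list[RiverSegment]:
    """Random spanning tree over watershed centroids, draining to one outlet."""
    ids = sorted(int(i) for i in np.unique(labels))
    if len(ids) < 2:
        return []
    cell = config.cellsize
    xy = {i: _centroid_xy(labels, i, cell) for i in ids}
    g = nx.Graph()
    for k, i in enumerate(ids):
        for j in ids[k + 1:]:
            dist = float(np.hypot(xy[i][0] - xy[j][0], xy[i][1] - xy[j][1]))
            # jittered weights make the spanning tree random but seeded
            g.add_edge(i, j, weight=dist * (1.0 + 0.2 * rng.random()), dist=dist)
    tree = nx.minimum_spanning_tree(g)
    outlet = min(ids, key=lambda i: xy[i][1])  # drains toward the lowest edge
    parent = {outlet: None}
    for u, v in nx.bfs_edges(tree, outlet):
        parent[v] = u
    # subtree size = number of watersheds draining through a node
    size = {i: 1 for i in ids}
    for node in reversed(list(nx.bfs_tree(tree, outlet))):
        if parent[node] is not None:
            size[parent[node]] += size[node]
    segments = []
    for k, node in enumerate(sorted(i for i in ids if parent[i] is not None)):
        par = parent[node]
        geom = LineString([xy[node], xy[par]])
        length_km = tree[node][par]["dist"] / 1000.0
        discharge = config.base_discharge * size[node]
        segments.append(
            RiverSegment(k + 1, geom, length_km, discharge,
                         upstream_ws=node, downstream_ws=par)
        )
    return segments


def _upstream_areas(scene_labels: np.ndarray, rivers: list[RiverSegment],
                    pixel_area: float) -> dict[int, float]:
    """Total area (ha) strictly upstream of each watershed along the tree."""
    ids = sorted(int(i) for i in np.unique(scene_labels))
    area = {i: float((scene_labels == i).sum()) * pixel_area for i in ids}
    children: dict[int, list[int]] = {i: [] for i in ids}
    for seg in rivers:
        if seg.downstream_ws is not None:
            children[seg.downstream_ws].append(seg.upstream_ws)

    up: dict[int, float] = {}

    def total(node: int) -> float:
        # area of node plus everything upstream of it
        if node not in up:
            up[node] = area[node] + sum(total(ch) for ch in children[node])
        return up[node]

    for i in ids:
        total(i)
    return {i: up[i] - area[i] for i in ids}


def _class_areas(raster: Raster, labels: np.ndarray) -> pd.DataFrame:
    """Area (ha) per (watershed, class id)."""
    valid = raster.valid
    df = pd.DataFrame(
        {"ws": labels[valid].ravel(), "cls": raster.data[valid].ravel()}
    )
    counts = df.value_counts(["ws", "cls"]).unstack(fill_value=0)
    return counts * raster.pixel_area_ha


def _protection_raster(config: SceneConfig) -> Raster:
    rows, cols = config.grid_shape
    grid = np.ones((rows, cols), dtype=float)
    for z in config.protection_zones:
        r0 = int(np.floor(z.bounds[0] * rows))
        c0 = int(np.floor(z.bounds[1] * cols))
        r1 = int(np.ceil(z.bounds[2] * rows))
        c1 = int(np.ceil(z.bounds[3] * cols))
        grid[r0:r1, c0:c1] = np.maximum(grid[r0:r1, c0:c1], z.weight)
    return Raster(grid, cellsize=config.cellsize, nodata=-9999.0)


# line-item synthesis coefficients (per-ha rates; see docs/methods.md)
_LAKE_DEPTH_M = 2.0
_RIVER_STOCK_PER_KM = 50.0  # 1000 m3 per km of reach
_GROUNDWATER_PER_HA = 5.0
_SOILWATER_PER_HA = 3.0
_RUNOFF_COEF = 0.35
_ABSTR_VILLAGE = 25.0
_ABSTR_AGRI = 8.0
_ABSTR_BASE = 0.05
_LIVESTOCK_TC_HA = 0.02
_OTHER_INFLOW_FRAC = 0.3
_CEREAL_TC_HA = 2.0
_SUGAR_TC_HA = 8.0
_CROPS_TC_HA = 1.5
_GRAZING_TC_HA = 3.0
_ROUNDWOOD_TC_HA = 1.2
_WOOD_PER_VILLAGE_HA = 30.0
_FUELWOOD_PER_VILLAGE_HA = 20.0


def _water_items(scene_cfg: SceneConfig, raster: Raster, labels: np.ndarray,
                 rivers: list[RiverSegment], date: str) -> pd.DataFrame:
    """Per-watershed water line items (1000 m3), deterministic."""
    palette = scene_cfg.palette
    areas = _class_areas(raster, labels)
    clim = scene_cfg.climate
    p = clim.p_series[date]
    etr = estimate_etr(EtrParams(clim.p_avg, clim.etr_avg, p), "inverted")
    up = _upstream_areas(labels, rivers, raster.pixel_area_ha)
    s = p / clim.p_avg

    water_ids = [c.id for c in palette if c.water]
    veg_ids = [c.id for c in palette if c.habitat]
    village_ids = [c.id for c in palette if c.group == HUMAN]
    agri_ids = [c.id for c in palette if c.group == AGRI]

    def area_of(ws, ids):
        return float(sum(areas.loc[ws, i] for i in ids if i in areas.columns))

    river_len = {int(i): 0.0 for i in np.unique(labels)}
    cell = scene_cfg.cellsize
    rows = labels.shape[0]
    for seg in rivers:
        # apportion reach length by sampling points along the geometry
        npts = max(2, int(seg.geometry.length / cell))
        for f in np.linspace(0.0, 1.0, npts, endpoint=False) + 0.5 / npts:
            pt = seg.geometry.interpolate(f, normalized=True)
            r = int(np.clip(rows - 1 - pt.y / cell, 0, rows - 1))
            c = int(np.clip(pt.x / cell, 0, labels.shape[1] - 1))
            river_len[int(labels[r, c])] += seg.length_km / npts

    cols = {}
    for ws in areas.index:
        ws = int(ws)
        area = float(areas.loc[ws].sum())
        w2_1 = p * area * 0.01
        w3_1 = etr * area * 0.01
        w2_3 = 0.01 * p * _RUNOFF_COEF * up[ws]
        w3_3 = 0.01 * p * _RUNOFF_COEF * (up[ws] + area)
        w3_4 = (
            _ABSTR_VILLAGE * area_of(ws, village_ids)
            + _ABSTR_AGRI * area_of(ws, agri_ids)
            + _ABSTR_BASE * area
        )
        cols[ws] = {
            "W1_1": area_of(ws, water_ids) * _LAKE_DEPTH_M * 10.0 * s,
            "W1_2": river_len[ws] * _RIVER_STOCK_PER_KM * s,
            "W1_4": _GROUNDWATER_PER_HA * area,
            "W1_5": _SOILWATER_PER_HA * area_of(ws, veg_ids),
            "W2_1": w2_1,
            "W2_2": -(0.25 * w2_3 + 0.02 * w2_1),
            "W2_3": w2_3,
            "W2_4": 0.10 * w3_4,
            "W2_5": 0.01 * w3_4,
            "W2_6": 0.25 * w3_4,
            "W3_1": w3_1,
            "W3_3": w3_3,
            "W3_4": w3_4,
            "W3_8": 0.02 * w3_4,
            "W14": 0.95,
        }
    return pd.DataFrame(cols)


def _carbon_items(scene_cfg: SceneConfig, raster: Raster, labels: np.ndarray,
                  protection: Raster) -> pd.DataFrame:
    """Per-watershed carbon line items (tonnes C), deterministic."""
    palette = scene_cfg.palette
    areas = _class_areas(raster, labels)

    def area_of(ws, ids):
        return float(sum(areas.loc[ws, i] for i in ids if i in areas.columns))

    rice = [c.id for c in palette if c.name.lower().startswith("rice")]
    sugar = [c.id for c in palette if "sugar" in c.name.lower()]
    crops = [
        c.id for c in palette
        if c.group == AGRI and c.id not in rice and c.id not in sugar
    ]
    grazing = [c.id for c in palette if c.group in (SHRUB, AGRI)]
    trees = [c.id for c in palette if c.tree]
    village = [c.id for c in palette if c.group == HUMAN]

    cols = {}
    for ws in areas.index:
        ws = int(ws)
        sel = labels == ws
        agb = litter = roots = soc = npp = 0.0
        for cid in areas.columns:
            a = float(areas.loc[ws, cid])
            if a == 0:
                continue
            c = palette[int(cid)]
            agb += a * c.agb
            litter += a * c.agb * c.litter_frac
            roots += a * c.agb * c.root_shoot
            soc += a * c.soc
            npp += a * c.npp
        c2_9 = _OTHER_INFLOW_FRAC * npp
        c3_11 = _CEREAL_TC_HA * area_of(ws, rice)
        c3_13 = _SUGAR_TC_HA * area_of(ws, sugar)
        c3_199 = _CROPS_TC_HA * area_of(ws, crops)
        c3_3 = _GRAZING_TC_HA * area_of(ws, grazing)
        c3_4 = _ROUNDWOOD_TC_HA * area_of(ws, trees) + _WOOD_PER_VILLAGE_HA * area_of(ws, village)
        c4_33 = _FUELWOOD_PER_VILLAGE_HA * area_of(ws, village)
        c4_34 = 0.3 * c4_33
        c2 = npp + c2_9
        c5 = c3_11 + c3_13 + c3_199 + c3_3 + c3_4 + c4_33 + c4_34
        protected = float((protection.data[sel] > 1.0).mean()) if sel.any() else 0.0
        cols[ws] = {
            "C1_1": agb,
            "C1_2": litter,
            "C1_31": roots,
            "C1_32": soc,
            "C1_4": _LIVESTOCK_TC_HA * area_of(ws, grazing),
            "C2_3": npp,
            "C2_9": c2_9,
            "C3_11": c3_11,
            "C3_13": c3_13,
            "C3_199": c3_199,
            "C3_3": c3_3,
            "C3_4": c3_4,
            "C4_33": c4_33,
            "C4_34": c4_34,
            "C10_1": max(0.0, c2 - c5),
            "C10_2": 0.7 - 0.6 * protected,
            "CEH": 1.0,
        }
    return pd.DataFrame(cols)


def _truths(config: SceneConfig, opening: Raster, closing: Raster):
    tm = cross_tabulate(opening, closing, palette=config.palette)
    fa = classify_flows(tm, FlowRules.default(config.palette))
    return tm.counts, fa.formation.sum(axis=1)


def _make_scene(config: SceneConfig, opening: Raster, closing: Raster,
                labels: np.ndarray, polygons, rivers, protection) -> SyntheticScene:
    transitions, flow_totals = _truths(config, opening, closing)
    items = {}
    d_open, d_close = config.dates
    items[("water", d_open)] = _water_items(config, opening, labels, rivers, d_open)
    items[("water", d_close)] = _water_items(config, closing, labels, rivers, d_close)
    items[("carbon", d_open)] = _carbon_items(config, opening, labels, protection)
    items[("carbon", d_close)] = _carbon_items(config, closing, labels, protection)
    return SyntheticScene(
        config, opening, closing, labels, polygons, rivers, protection,
        transitions, flow_totals, items,
    )


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate a scene; bit-identical for a fixed config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = _grow_patches(config, rng)
    cell = config.cellsize
    opening = Raster(grid, cellsize=cell)
    closing = opening.copy()
    labels = _watershed_partition(config, rng)
    polygons = {
        int(i): pixel_polygon(labels, int(i), cell)
        for i in np.unique(labels)
    }
    rivers = _build_rivers(config, labels, rng)
    protection = _protection_raster(config)
    return _make_scene(config, opening, closing, labels, polygons, rivers, protection)


def apply_change_scenario(
    scene: SyntheticScene,
    scenario: list[tuple[int, int, int]],
) -> SyntheticScene:
    """Apply (from_class, to_class, n_pixels) conversions to the closing raster.

    Pixel choice is seeded by the scene seed and the scenario itself, so a
    given scenario is reproducible. Oversubscribing a class raises a
    :class:`ScenarioError` listing the shortfall.
    """
    closing = scene.closing.copy()
    digest = hashlib.sha256(json.dumps(sorted(scenario)).encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    rng = np.random.default_rng([scene.config.seed % (2**31), sub])

    shortfalls = []
    for from_cls, to_cls, n in scenario:
        if from_cls not in scene.config.palette or to_cls not in scene.config.palette:
            raise ScenarioError(f"scenario classes {from_cls}->{to_cls} outside palette")
        rows, cols = np.nonzero((closing.data == from_cls) & closing.valid)
        if len(rows) < n:
            shortfalls.append((from_cls, to_cls, n, len(rows)))
            continue
        pick = rng.choice(len(rows), size=n, replace=False)
        closing.data[rows[pick], cols[pick]] = to_cls
    if shortfalls:
        msg = "; ".join(
            f"{f}->{t}: requested {n}, only {have} pixels available"
            for f, t, n, have in shortfalls
        )
        raise ScenarioError(f"oversubscribed change scenario: {msg}")

    return _make_scene(
        scene.config, scene.opening, closing, scene.watershed_labels,
        scene.watershed_polygons, scene.rivers, scene.protection,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_scene(scene: SyntheticScene, directory: str | Path) -> dict[str, str]:
    """Write a scene to ``directory``; returns the file manifest.

    Rasters go to ESRI ASCII grids, vectors to GeoJSON, line items and the
    transition truth to CSV, the configuration to YAML. ``read_scene`` on
    the directory reproduces the scene exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def put(name, path):
        manifest[name] = str(Path(path).name)

    put("config", directory / "config.yml")
    (directory / "config.yml").write_text(yaml.safe_dump(scene.config.to_dict()))

    for name, raster in (
        ("opening", scene.opening),
        ("closing", scene.closing),
        ("protection", scene.protection),
    ):
        put(name, write_ascii_grid(raster, directory / f"{name}.asc"))
    ws_raster = Raster(scene.watershed_labels, cellsize=scene.config.cellsize)
    put("watersheds_raster", write_ascii_grid(ws_raster, directory / "watersheds.asc"))

    put("watersheds", write_geojson(
        [
            (scene.watershed_polygons[i], {"id": i, "type": "watershed"})
            for i in scene.watershed_ids
        ],
        directory / "watersheds.geojson",
    ))
    put("rivers", write_geojson(
        [
            (seg.geometry, {
                "id": seg.id, "type": "river",
                "length_km": seg.length_km, "discharge": seg.discharge,
                "upstream_ws": seg.upstream_ws, "downstream_ws": seg.downstream_ws,
            })
            for seg in scene.rivers
        ],
        directory / "rivers.geojson",
    ))

    tr = scene.truth_transitions.stack()
    tr = tr[tr > 0].rename("pixels").reset_index()
    tr.columns = ["from_class", "to_class", "pixels"]
    tr.to_csv(directory / "transitions.csv", index=False)
    put("transitions", directory / "transitions.csv")

    for (account, date), items in scene.line_items.items():
        long = items.stack().rename("value").reset_index()
        long.columns = ["code", "selu_id", "value"]
        fname = f"{account}_items_{date}.csv"
        long[["selu_id", "code", "value"]].to_csv(directory / fname, index=False)
        put(f"{account}_items_{date}", directory / fname)

    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["manifest"] = "manifest.json"
    return manifest


def read_scene(directory: str | Path) -> SyntheticScene:
    """Read back a scene written by :func:`write_scene`."""
    directory = Path(directory)
    config = SceneConfig.from_dict(
        yaml.safe_load((directory / "config.yml").read_text())
    )
    opening = read_ascii_grid(directory / "opening.asc", dtype=np.int64)
    closing = read_ascii_grid(directory / "closing.asc", dtype=np.int64)
    protection = read_ascii_grid(directory / "protection.asc", dtype=np.float64)
    labels = read_ascii_grid(directory / "watersheds.asc", dtype=np.int64).data

    polygons = {
        int(props["id"]): geom
        for geom, props in read_geojson(directory / "watersheds.geojson")
    }
    rivers = [
        RiverSegment(
            int(p["id"]), geom, float(p["length_km"]), float(p["discharge"]),
            p.get("upstream_ws"), p.get("downstream_ws"),
        )
        for geom, p in read_geojson(directory / "rivers.geojson")
    ]

    tr = pd.read_csv(directory / "transitions.csv")
    ids = config.palette.ids
    transitions = pd.DataFrame(0, index=ids, columns=ids)
    for _, row in tr.iterrows():
        transitions.loc[int(row.from_class), int(row.to_class)] = int(row.pixels)

    items = {}
    for path in sorted(directory.glob("*_items_*.csv")):
        account, _, date = path.stem.rpartition("_items_")
        long = pd.read_csv(path)
        items[(account, date)] = long.pivot(
            index="code", columns="selu_id", values="value"
        ).rename_axis(None).rename_axis(None, axis=1)

    fa = classify_flows(
        cross_tabulate(opening, closing, palette=config.palette),
        FlowRules.default(config.palette),
    )
    return SyntheticScene(
        config, opening, closing, labels, polygons, rivers, protection,
        transitions, fa.formation.sum(axis=1), items,
    )
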