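"""GeoJSON helpers built on shapely.

Watersheds/SELUs are polygons, rivers are line strings; both round-trip
through standard GeoJSON FeatureCollections.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


def write_geojson(
    features: Iterable[tuple[BaseGeometry, dict[str, Any]]], path: str | Path
) -> Path:
    path = Path(path)
    collection = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    path.write_text(json.dumps(collection))
    return path


def read_geojson(path: str | Path) -> list[tuple[BaseGeometry, dict[str, Any]]]:
    doc = json.loads(Path(path).read_text())
    return [
        (shape(feat["geometry"]), feat.get("properties") or {})
        for feat in doc["features"]
    ]


def pixel_polygon(labels: np.ndarray, value: int, cellsize: float,
                  origin: tuple[float, float] = (0.0, 0.0)) -> BaseGeometry:
    """Polygon covering all cells of ``labels`` equal to ``value``.

    Row 0 is the top row of the grid (image convention); y increases upward
    from ``origin`` (map convention).
    """
    rows, cols = np.nonzero(labels == value)
    if rows.size == 0:
        return shapely.Polygon()
    nrows = labels.shape[0]
    x0 = origin[0] + cols * cellsize
    y0 = origin[1] + (nrows - 1 - rows) * cellsize
    boxes = shapely.box(x0, y0, x0 + cellsize, y0 + cellsize)
    return shapely.union_all(boxes)
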