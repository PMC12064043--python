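"""Minimal single-band raster container with ESRI ASCII grid I/O.

Rasters here are categorical land-cover grids or small floating-point
multiplier grids on a regular square-pixel grid. The ESRI ASCII grid format
(``.asc``) is used for persistence: it is plain text, self-describing and
readable by QGIS/GDAL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AlignmentError

INT_NODATA = -9999


@dataclass
class Raster:
    """A single-band raster on a square-pixel grid.

    Parameters
    ----------
    data : ndarray, shape (rows, cols)
        Cell values; integer class codes or floats.
    cellsize : float
        Pixel edge length in metres.
    origin : (float, float)
        (xllcorner, yllcorner) of the grid in map units.
    nodata : int or float
        Sentinel marking invalid cells.
    """

    data: np.ndarray
    cellsize: float = 15.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = INT_NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pixel_area_ha(self) -> float:
        return self.cellsize * self.cellsize / 10_000.0

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata."""
        if np.issubdtype(self.data.dtype, np.floating):
            return ~np.isclose(self.data, self.nodata) & ~np.isnan(self.data)
        return self.data != self.nodata

    def copy(self) -> "Raster":
        return Raster(self.data.copy(), self.cellsize, self.origin, self.nodata)

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cellsize, other.cellsize)
            and np.allclose(self.origin, other.origin)
        )

    def equals(self, other: "Raster") -> bool:
        return self.same_grid(other) and np.array_equal(self.data, other.data)


def require_aligned(a: Raster, b: Raster) -> None:
    if not a.same_grid(b):
        raise AlignmentError(
            f"rasters are not co-registered: shapes {a.shape} vs {b.shape}, "
            f"cellsize {a.cellsize} vs {b.cellsize}, origin {a.origin} vs {b.origin}"
        )


def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write an ESRI ASCII grid. Integer arrays are written without decimals."""
    path = Path(path)
    data = raster.data
    is_int = np.issubdtype(data.dtype, np.integer)
    fmt = "%d" if is_int else "%.10g"
    header = (
        f"ncols {data.shape[1]}\n"
        f"nrows {data.shape[0]}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cellsize:.6f}\n"
        f"NODATA_value {raster.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)
    return path


def read_ascii_grid(path: str | Path, dtype=None) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", INT_NODATA)
    if dtype is None:
        # integer grid if every value is integral
        if np.all(np.mod(data, 1) == 0):
            dtype = np.int64
        else:
            dtype = np.float64
    data = data.astype(dtype)
    if np.issubdtype(np.dtype(dtype), np.integer):
        nodata = int(nodata)
    return Raster(
        data,
        cellsize=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=nodata,
    )
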