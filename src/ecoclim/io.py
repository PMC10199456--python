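"""Raster and tabular I/O on geographic grids.

Rasters are stored as plain-text ASCII grids (an ESRI-ASCII-style header
followed by one row of values per line).  The header is extended with
separate ``dx``/``dy`` keys because cells that are square in kilometres are
not square in degrees away from the equator; when ``dx == dy`` the file is
also a valid classic ESRI ASCII grid.  Values are written with 9 significant
digits, which round-trips float32 bit-exactly.

Grid convention: row 0 is the northernmost row, column 0 the westernmost
column; ``origin_lon``/``origin_lat`` name the lower-left (south-west)
corner of the grid, as in the ESRI format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError

NODATA = -9999.0

__all__ = ["GridGeometry", "read_ascii_grid", "write_ascii_grid", "NODATA"]


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular lon/lat grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (positive).
    origin_lon, origin_lat
        Lower-left (south-west) corner, decimal degrees WGS84.
    dlon, dlat
        Cell size in degrees of longitude / latitude (positive).
    nodata
        Sentinel for missing cells in files; in memory NaN is used.
    """

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    dlon: float
    dlat: float
    nodata: float = NODATA

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_rows", int(self.n_rows))
        object.__setattr__(self, "n_cols", int(self.n_cols))
        for name in ("origin_lon", "origin_lat", "dlon", "dlat", "nodata"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise DataError(f"grid dimensions must be positive, got {self.n_rows}x{self.n_cols}")
        if self.dlon <= 0 or self.dlat <= 0:
            raise DataError(f"cell sizes must be positive, got dlon={self.dlon}, dlat={self.dlat}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_center(self, col) -> np.ndarray:
        return self.origin_lon + (np.asarray(col) + 0.5) * self.dlon

    def lat_center(self, row) -> np.ndarray:
        return self.origin_lat + (self.n_rows - np.asarray(row) - 0.5) * self.dlat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lon, lat) arrays of shape (n_rows, n_cols) of cell centers."""
        lon = self.lon_center(np.arange(self.n_cols))[None, :]
        lat = self.lat_center(np.arange(self.n_rows))[:, None]
        return np.broadcast_to(lon, self.shape).copy(), np.broadcast_to(lat, self.shape).copy()

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col); -1 marks out-of-bounds points."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.dlon).astype(int)
        row = self.n_rows - 1 - np.floor((lat - self.origin_lat) / self.dlat).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def matches(self, other: "GridGeometry") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_lon, other.origin_lon, abs_tol=1e-9)
            and math.isclose(self.origin_lat, other.origin_lat, abs_tol=1e-9)
            and math.isclose(self.dlon, other.dlon, rel_tol=1e-9)
            and math.isclose(self.dlat, other.dlat, rel_tol=1e-9)
        )

    def require_match(self, other: "GridGeometry", what: str = "layer") -> None:
        if not self.matches(other):
            raise DataError(
                f"grid geometry mismatch on {what}: "
                f"{self.shape}@({self.origin_lon},{self.origin_lat},{self.dlon},{self.dlat}) vs "
                f"{other.shape}@({other.origin_lon},{other.origin_lat},{other.dlon},{other.dlat})"
            )


def write_ascii_grid(path: str | Path, array: np.ndarray, geom: GridGeometry) -> None:
    """Write a 2-D raster as a text ASCII grid; NaN becomes the no-data value."""
    array = np.asarray(array, dtype=np.float32)
    if array.shape != geom.shape:
        raise DataError(f"array shape {array.shape} does not match geometry {geom.shape}")
    out = np.where(np.isnan(array), np.float32(geom.nodata), array)
    header = (
        f"ncols {geom.n_cols}\n"
        f"nrows {geom.n_rows}\n"
        f"xllcorner {geom.origin_lon!r}\n"
        f"yllcorner {geom.origin_lat!r}\n"
        f"dx {geom.dlon!r}\n"
        f"dy {geom.dlat!r}\n"
        f"nodata_value {geom.nodata!r}\n"
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.9g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Read a text ASCII grid; no-data cells come back as NaN, dtype float32."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "dx", "dy",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=np.float32, ndmin=2)
    if "cellsize" in header:
        header.setdefault("dx", header["cellsize"])
        header.setdefault("dy", header["cellsize"])
    try:
        geom = GridGeometry(
            n_rows=int(header["nrows"]),
            n_cols=int(header["ncols"]),
            origin_lon=header["xllcorner"],
            origin_lat=header["yllcorner"],
            dlon=header["dx"],
            dlat=header["dy"],
            nodata=header.get("nodata_value", NODATA),
        )
    except KeyError as exc:
        raise DataError(f"{path}: missing header key {exc}") from exc
    if data.shape != geom.shape:
        raise DataError(f"{path}: data shape {data.shape} does not match header {geom.shape}")
    data = data.copy()
    data[data == np.float32(geom.nodata)] = np.nan
    return data, geom
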