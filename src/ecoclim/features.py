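"""Predictor stack construction and point extraction.

A :class:`PredictorStack` is a set of named, co-registered single-band
rasters on one :class:`~ecoclim.io.GridGeometry` (monthly climate slices,
DEM, distance-to-conifer).  This module builds the derived distance layer,
filters collinear candidates with a Pearson threshold, and extracts layer
values at labelled points into a feature table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DataError
from .io import GridGeometry, read_ascii_grid, write_ascii_grid
from .occurrence import EARTH_RADIUS_KM

logger = logging.getLogger(__name__)

#: Default layer names, in retention-priority order for the collinearity
#: filter: monthly maximum temperature (tx), minimum temperature (tn), total
#: precipitation (rr), global radiation (qq), relative humidity (hu) slices
#: keyed by month number, plus elevation (DEM) and distance to the nearest
#: coniferous/mixed-forest cell (Di).
DEFAULT_LAYERS = ("tx3", "tx5", "tn8", "tn12", "rr4", "rr5", "rr8", "rr9",
                  "rr10", "qq5", "qq12", "hu4", "hu12", "DEM", "Di")

__all__ = ["PredictorStack", "DEFAULT_LAYERS", "correlation_filter",
           "distance_to_conifer", "extract_at_points"]


@dataclass
class PredictorStack:
    """Named co-registered rasters sharing one grid geometry."""

    geom: GridGeometry
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if np.asarray(arr).shape != self.geom.shape:
                raise DataError(
                    f"layer {name!r} has shape {np.asarray(arr).shape}, "
                    f"expected {self.geom.shape}")

    def add(self, name: str, array: np.ndarray) -> None:
        array = np.asarray(array, dtype=float)
        if array.shape != self.geom.shape:
            raise DataError(f"layer {name!r} has shape {array.shape}, expected {self.geom.shape}")
        self.layers[name] = array

    def subset(self, names) -> "PredictorStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise DataError(f"missing layers: {missing}")
        return PredictorStack(self.geom, {n: self.layers[n] for n in names})

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(path / f"{name}.asc", arr, self.geom)

    @classmethod
    def from_dir(cls, path: str | Path, names=None) -> "PredictorStack":
        path = Path(path)
        files = sorted(path.glob("*.asc")) if names is None else [path / f"{n}.asc" for n in names]
        if not files:
            raise DataError(f"no raster layers found in {path}")
        geom = None
        layers: dict[str, np.ndarray] = {}
        for f in files:
            arr, g = read_ascii_grid(f)
            if geom is None:
                geom = g
            else:
                geom.require_match(g, what=f.stem)
            layers[f.stem] = arr
        return cls(geom, layers)


def correlation_filter(samples: pd.DataFrame, threshold: float = 0.8,
                       priority: list[str] | None = None) -> list[str]:
    """Greedy collinearity filter on layer values sampled at points.

    Walks the candidate layers in ``priority`` order (default: column
    order); a candidate is retained iff its absolute Pearson correlation
    with every already-retained layer is <= ``threshold``.  Zero-variance
    layers are dropped with a warning.  Returns retained names in priority
    order.
    """
    if priority is None:
        priority = list(samples.columns)
    unknown = [n for n in priority if n not in samples.columns]
    if unknown:
        raise DataError(f"priority names not in samples: {unknown}")
    if len(samples) < 3:
        raise DataError("need at least 3 samples to estimate correlations")
    retained: list[str] = []
    for name in priority:
        x = samples[name].to_numpy(dtype=float)
        if np.std(x) == 0.0:
            warnings.warn(f"layer {name!r} is constant at the sample points; dropped",
                          stacklevel=2)
            continue
        ok = True
        for kept in retained:
            r = np.corrcoef(x, samples[kept].to_numpy(dtype=float))[0, 1]
            if abs(r) > threshold:
                logger.info("dropping %s (|r|=%.3f with %s > %.2f)", name, abs(r), kept, threshold)
                ok = False
                break
        if ok:
            retained.append(name)
    return retained


def _unit_sphere(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lon = np.radians(lon)
    lat = np.radians(lat)
    return np.column_stack([np.cos(lat) * np.cos(lon),
                            np.cos(lat) * np.sin(lon),
                            np.sin(lat)])


def distance_to_conifer(conifer_mask: np.ndarray, geom: GridGeometry) -> np.ndarray:
    """Great-circle distance (km) from each cell center to the nearest
    conifer-class cell center; 0 on conifer cells.

    Exact nearest-neighbour search via a k-d tree on unit-sphere
    coordinates (chord distance is monotone in great-circle distance, so
    the nearest chord neighbour is the nearest great-circle neighbour).
    """
    conifer_mask = np.asarray(conifer_mask, dtype=bool)
    if conifer_mask.shape != geom.shape:
        raise DataError(f"conifer mask shape {conifer_mask.shape} does not match grid {geom.shape}")
    if not conifer_mask.any():
        raise DataError("no conifer cells in land-cover raster; distance layer undefined")
    lon, lat = geom.cell_centers()
    xyz_all = _unit_sphere(lon.ravel(), lat.ravel())
    xyz_conifer = xyz_all[conifer_mask.ravel()]
    tree = cKDTree(xyz_conifer)
    chord, _ = tree.query(xyz_all, k=1)
    arc = 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    di = (EARTH_RADIUS_KM * arc).reshape(geom.shape)
    di[conifer_mask] = 0.0
    return di


def extract_at_points(stack: PredictorStack, points: pd.DataFrame) -> pd.DataFrame:
    """Nearest-cell lookup of every stack layer at labelled points.

    Returns a feature table with a ``label`` column followed by one column
    per layer.  Rows falling outside the grid or on a no-data cell in any
    layer are dropped; the drop count is logged and available via
    ``result.attrs["n_dropped"]``.
    """
    row, col = stack.geom.cell_of(points["lon"].to_numpy(), points["lat"].to_numpy())
    inb = row >= 0
    data = {"label": points["label"].to_numpy()[inb]}
    for name, arr in stack.layers.items():
        data[name] = np.asarray(arr, dtype=float)[row[inb], col[inb]]
    table = pd.DataFrame(data)
    complete = ~table.drop(columns="label").isna().any(axis=1)
    n_dropped = int((~inb).sum() + (~complete).sum())
    if n_dropped:
        logger.info("extract_at_points: dropped %d of %d points (out of bounds or no-data)",
                    n_dropped, len(points))
    out = table[complete].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out
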