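"""Inverse distance weighted (IDW) interpolation.

A value at an unsampled location is the convex combination of the values at
the m nearest sampled points, weighted by

    lambda_i = D_i**(-a) / sum_j D_j**(-a)

where D_i is the distance to point i and a >= 0 the power. a = 0 degenerates
to the arithmetic mean of the neighbourhood; large a converges to
nearest-neighbour. Coinciding with a data point returns that point's value
exactly (the mean, if several points coincide there).

Distances are planar by default (adequate over a study extent of a fraction
of a degree); a haversine great-circle metric (km) is available for larger
lon/lat extents. Surfaces are regular grids evaluated at cell centres and
serialise as ESRI ASCII grids.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "NODATA",
    "SpatialPoint",
    "IDWConfig",
    "Surface",
    "idw_weights",
    "idw_predict",
    "idw_grid",
    "write_asc",
    "read_points_csv",
    "read_points_geojson",
]

logger = logging.getLogger(__name__)

#: No-data sentinel used in surfaces and returned when a cutoff leaves no neighbours.
NODATA = -9999.0

_EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class SpatialPoint:
    x: float
    y: float
    value: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.y, self.value))):
            raise InputError("SpatialPoint fields must be finite")


@dataclass(frozen=True)
class IDWConfig:
    """Interpolation settings: distance power a, neighbourhood size m,
    optional search cutoff, and the distance metric."""

    power: float = 2.0
    max_neighbors: int = 12
    cutoff_distance: Optional[float] = None
    distance_metric: str = "planar"

    def __post_init__(self) -> None:
        if self.power < 0:
            raise InputError("power must be >= 0")
        if self.max_neighbors < 1:
            raise InputError("max_neighbors must be >= 1")
        if self.cutoff_distance is not None and self.cutoff_distance <= 0:
            raise InputError("cutoff_distance must be > 0")
        if self.distance_metric not in ("planar", "haversine"):
            raise InputError(f"unknown distance metric {self.distance_metric!r}")


@dataclass
class Surface:
    """Row-major grid of interpolated values; row 0 is the top (max y) row,
    matching the ESRI ASCII layout."""

    bbox: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    ncols: int
    nrows: int
    cellsize: float
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.bbox
        if not (xmin < xmax and ymin < ymax):
            raise InputError("invalid bbox: require xmin < xmax and ymin < ymax")
        if self.cellsize <= 0:
            raise InputError("cellsize must be > 0")
        self.values = np.asarray(self.values, dtype=float).reshape(self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of shape (nrows, ncols)."""
        xmin, ymin, _, _ = self.bbox
        xs = xmin + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = ymin + (np.arange(self.nrows) + 0.5) * self.cellsize
        # top row first
        return np.meshgrid(xs, ys[::-1])


def _distances(points_xy: np.ndarray, target: Sequence[float], metric: str) -> np.ndarray:
    tx, ty = float(target[0]), float(target[1])
    if metric == "planar":
        return np.hypot(points_xy[:, 0] - tx, points_xy[:, 1] - ty)
    # haversine: coordinates are lon/lat degrees, distance in km
    lon1, lat1 = np.radians(points_xy[:, 0]), np.radians(points_xy[:, 1])
    lon2, lat2 = math.radians(tx), math.radians(ty)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * math.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def idw_weights(distances: Sequence[float], power: float) -> np.ndarray:
    """Normalised weights lambda_i = D_i**(-a) / sum_j D_j**(-a).

    If any distance is zero the formula is singular: all weight is spread
    uniformly over the zero-distance entries (exact interpolation).
    Weights always sum to 1.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise InputError("distances must be non-empty")
    if np.any(d < 0):
        raise InputError("distances must be >= 0")
    zero = d == 0
    if zero.any():
        w = np.where(zero, 1.0, 0.0)
        return w / w.sum()
    w = d ** (-power)
    return w / w.sum()


def _as_point_array(points: Iterable[SpatialPoint]) -> np.ndarray:
    arr = np.array([(p.x, p.y, p.value) for p in points], dtype=float)
    if arr.size == 0:
        raise InputError("points must be non-empty")
    return arr


def idw_predict(
    points: Iterable[SpatialPoint] | np.ndarray,
    target: Sequence[float],
    config: IDWConfig = IDWConfig(),
) -> float:
    """IDW prediction at one location.

    Candidate points within the cutoff (all points if none is set) are ranked
    by distance; the nearest ``max_neighbors`` are used, with ties at the m-th
    distance all included so the result is independent of input order. Returns
    :data:`NODATA` when a cutoff excludes every point.
    """
    arr = points if isinstance(points, np.ndarray) else _as_point_array(points)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InputError("points array must have shape (n, 3): x, y, value")
    if arr.shape[0] == 0:
        raise InputError("points must be non-empty")

    d = _distances(arr[:, :2], target, config.distance_metric)
    vals = arr[:, 2]
    if config.cutoff_distance is not None:
        keep = d <= config.cutoff_distance
        if not keep.any():
            return NODATA
        d, vals = d[keep], vals[keep]

    if d.min() == 0.0:
        coincident = vals[d == 0.0]
        if coincident.size > 1 and not np.all(coincident == coincident[0]):
            logger.warning(
                "coincident data points with differing values at %s; returning their mean",
                tuple(target),
            )
        return float(coincident.mean())

    m = min(config.max_neighbors, d.size)
    # include every point tied with the m-th nearest distance
    mth = np.partition(d, m - 1)[m - 1]
    keep = d <= mth
    w = idw_weights(d[keep], config.power)
    return float(np.dot(w, vals[keep]))


def idw_grid(
    points: Iterable[SpatialPoint],
    bbox: tuple[float, float, float, float],
    ncols: int,
    nrows: int,
    config: IDWConfig = IDWConfig(),
) -> Surface:
    """Evaluate IDW at every cell centre of a regular grid over ``bbox``.

    The cell size is set by the x extent (``(xmax - xmin)/ncols``), the ESRI
    ASCII convention of square cells; the grid's y extent is
    ``nrows * cellsize`` upwards from ``ymin``.
    """
    xmin, ymin, xmax, ymax = bbox
    if not (xmin < xmax and ymin < ymax):
        raise InputError("invalid bbox")
    if ncols < 1 or nrows < 1:
        raise InputError("ncols and nrows must be >= 1")
    arr = _as_point_array(points)
    cellsize = (xmax - xmin) / ncols
    grid = np.empty((nrows, ncols), dtype=float)
    for i in range(nrows):  # row 0 = top
        cy = ymin + (nrows - i - 0.5) * cellsize
        for j in range(ncols):
            cx = xmin + (j + 0.5) * cellsize
            grid[i, j] = idw_predict(arr, (cx, cy), config)
    return Surface(bbox=(xmin, ymin, xmax, ymax), ncols=ncols, nrows=nrows,
                   cellsize=cellsize, values=grid)


def write_asc(surface: Surface, path: os.PathLike | str) -> None:
    """Write a surface as an ESRI ASCII grid (.asc)."""
    xmin, ymin, _, _ = surface.bbox
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {surface.ncols}\n")
        fh.write(f"nrows {surface.nrows}\n")
        fh.write(f"xllcorner {xmin!r}\n")
        fh.write(f"yllcorner {ymin!r}\n")
        fh.write(f"cellsize {surface.cellsize!r}\n")
        fh.write(f"NODATA_value {surface.nodata!r}\n")
        for row in surface.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_points_csv(
    path: os.PathLike | str, value_column: str, x_column: str = "x", y_column: str = "y"
) -> list[SpatialPoint]:
    """Read points from a CSV with coordinate columns and one value column."""
    frame = pd.read_csv(path, comment="#")
    for col in (x_column, y_column, value_column):
        if col not in frame.columns:
            raise InputError(f"{path}: missing column {col!r}")
    frame = frame.dropna(subset=[x_column, y_column, value_column])
    return [
        SpatialPoint(float(r[x_column]), float(r[y_column]), float(r[value_column]))
        for _, r in frame.iterrows()
    ]


def read_points_geojson(path: os.PathLike | str, value_property: str) -> list[SpatialPoint]:
    """Read Point features from a GeoJSON FeatureCollection."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise InputError(f"{path}: expected a GeoJSON FeatureCollection")
    points = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            continue
        x, y = geom["coordinates"][:2]
        props = feat.get("properties") or {}
        if value_property not in props:
            raise InputError(f"{path}: feature missing property {value_property!r}")
        points.append(SpatialPoint(float(x), float(y), float(props[value_property])))
    if not points:
        raise InputError(f"{path}: no Point features found")
    return points
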