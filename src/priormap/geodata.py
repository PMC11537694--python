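"""Raster/vector data model shared by every pipeline stage.

All layers in one analysis live on a single :class:`Grid` — an equal-area
projected, north-up, square-cell raster. Cell (0, 0) is the top-left cell;
the center of cell (row, col) sits at::

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y - (row + 0.5) * cell_size

Every point-in-cell test (rasterization, buffering) uses cell centers.

Rasters are stored on disk as ESRI ASCII grid (``.asc``) — a plain-text,
single-band georeferenced format readable by every GIS. Polygons are GeoJSON.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon, shape

__all__ = [
    "Grid",
    "ContinuousLayer",
    "CategoricalLayer",
    "PolygonSet",
    "read_raster",
    "write_raster",
    "read_polygons",
    "write_polygons",
    "rasterize",
    "buffer_mask",
]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Geometry of a north-up, square-cell raster.

    ``origin_x, origin_y`` is the outer corner of the top-left cell
    (x increases east, y increases north, rows run south).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.origin_x, other.origin_x)
            and math.isclose(self.origin_y, other.origin_y)
        )


def _require_same_grid(*layers: "_Layer") -> None:
    g0 = layers[0].grid
    for lyr in layers[1:]:
        if not g0.same_geometry(lyr.grid):
            raise ValueError("layers do not share a grid; resample explicitly first")


@dataclass
class _Layer:
    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return self.values != self.grid.nodata


class ContinuousLayer(_Layer):
    """Real-valued raster (environmental covariate, suitability, quality...)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(float)
        v = self.values[self.values != self.grid.nodata]
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("non-nodata cells must be finite")


class CategoricalLayer(_Layer):
    """Integer-coded raster (land use, class maps, binary masks)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.round(self.values)
            if not np.allclose(self.values, rounded, atol=0, rtol=0):
                raise ValueError("categorical layer requires integer codes")
            self.values = rounded.astype(np.int64)
        else:
            self.values = self.values.astype(np.int64)


@dataclass
class PolygonSet:
    """Named polygons (protected areas and similar vector overlays)."""

    polygons: list[tuple[int, str, Polygon, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [pid for pid, *_ in self.polygons]
        if len(ids) != len(set(ids)):
            raise ValueError("polygon ids must be unique")
        for pid, name, geom, _ in self.polygons:
            if geom.is_empty:
                raise ValueError(f"polygon {pid} ({name}) is empty")

    def __len__(self) -> int:
        return len(self.polygons)

    def ids(self) -> list[int]:
        return [pid for pid, *_ in self.polygons]


# ---------------------------------------------------------------------------
# I/O — ESRI ASCII grid and GeoJSON
# ---------------------------------------------------------------------------

def read_raster(path: str | Path) -> ContinuousLayer | CategoricalLayer:
    """Read a single-band ESRI ASCII grid.

    Returns a :class:`CategoricalLayer` when every value is integral,
    else a :class:`ContinuousLayer`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"missing {key} in ASCII grid header of {path}")
        values = np.loadtxt(fh, dtype=float)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.atleast_2d(values).reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    grid = Grid(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        nodata=nodata,
    )
    valid = values != nodata
    if np.all(values[valid] == np.round(values[valid])):
        return CategoricalLayer(grid, values.astype(np.int64))
    return ContinuousLayer(grid, values)


def write_raster(layer: _Layer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (full float precision)."""
    g = layer.grid
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin_x!r}\n")
        fh.write(f"yllcorner {g.origin_y - g.n_rows * g.cell_size!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"nodata_value {g.nodata!r}\n")
        if np.issubdtype(layer.values.dtype, np.integer):
            np.savetxt(fh, layer.values, fmt="%d")
        else:
            np.savetxt(fh, layer.values, fmt="%.17g")


def read_polygons(path: str | Path) -> PolygonSet:
    """Read a GeoJSON FeatureCollection of (Multi)Polygons."""
    with open(path) as fh:
        gj = json.load(fh)
    polys = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = shape(feat["geometry"])
        props = dict(feat.get("properties") or {})
        pid = int(props.pop("id", i + 1))
        name = str(props.pop("name", f"PA{pid}"))
        polys.append((pid, name, geom, props))
    return PolygonSet(polys)


def write_polygons(pset: PolygonSet, path: str | Path) -> None:
    feats = []
    for pid, name, geom, props in pset.polygons:
        feats.append(
            {
                "type": "Feature",
                "geometry": geom.__geo_interface__,
                "properties": {"id": pid, "name": name, **props},
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# Geometry operations
# ---------------------------------------------------------------------------

def rasterize(pset: PolygonSet, grid: Grid) -> CategoricalLayer:
    """Burn polygon ids into a grid: a cell takes a polygon's id when its
    center lies inside (or on the boundary of) the polygon; 0 elsewhere.
    Later polygons overwrite earlier ones where they overlap.
    """
    out = np.zeros(grid.shape, dtype=np.int64)
    if len(pset) == 0:
        warnings.warn("rasterize: empty polygon set, returning all-zero layer")
        return CategoricalLayer(grid, out)
    xs, ys = grid.cell_centers()
    flat_pts = np.column_stack([xs.ravel(), ys.ravel()])
    for pid, _name, geom, _props in pset.polygons:
        minx, miny, maxx, maxy = geom.bounds
        candidate = (
            (flat_pts[:, 0] >= minx)
            & (flat_pts[:, 0] <= maxx)
            & (flat_pts[:, 1] >= miny)
            & (flat_pts[:, 1] <= maxy)
        )
        idx = np.nonzero(candidate)[0]
        if idx.size == 0:
            continue
        inside = np.fromiter(
            (geom.intersects(Point(x, y)) for x, y in flat_pts[idx]),
            dtype=bool,
            count=idx.size,
        )
        flat = out.ravel()
        flat[idx[inside]] = pid
    return CategoricalLayer(grid, out)


def buffer_mask(
    layer: CategoricalLayer, target_codes: Iterable[int], radius: float
) -> CategoricalLayer:
    """Binary mask of cells whose center lies within Euclidean ``radius``
    (map units) of the center of any cell holding a target code.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    codes = set(int(c) for c in target_codes)
    target = np.isin(layer.values, sorted(codes))
    if not target.any():
        return CategoricalLayer(layer.grid, np.zeros(layer.grid.shape, dtype=np.int64))
    # distance (in cells) from each cell center to the nearest target center
    dist = ndimage.distance_transform_edt(~target) * layer.grid.cell_size
    mask = (dist <= radius + 1e-9).astype(np.int64)
    return CategoricalLayer(layer.grid, mask)


def binary_layer(grid: Grid, values: np.ndarray) -> CategoricalLayer:
    """Helper: coerce a boolean/0-1 array into a binary CategoricalLayer."""
    return CategoricalLayer(grid, np.asarray(values).astype(np.int64))
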