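"""Landscape metrics on classified 30-m land-cover grids.

Two metrics summarize grassland amount and configuration inside a
buffered survey-route footprint:

* percent grassland — share of valid (non-nodata) cells classified as
  grassland, in percent;
* edge density — total length of grassland/non-grassland cell faces
  (rook adjacency, each shared face contributing one cell-size of
  length) divided by the grassland area in hectares, in m/ha.  Faces
  against nodata cells, or across the mask boundary, are not edges.

The edge-density denominator follows the grassland-area convention; the
more common total-landscape-area normalization is available through
``denominator="landscape"``.

Coordinates are plain projected meters: cell (row, col) has its center
at ``x = (col + 0.5) * cell_size``, ``y = (row + 0.5) * cell_size`` with
row 0 at the grid's lower edge.  No map-projection handling is done —
inputs are assumed already projected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "LandCoverRaster",
    "BufferMask",
    "buffer_mask",
    "percent_grassland",
    "edge_density",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_routes_csv",
    "route_metrics_table",
    "CLASS_CODES",
]

# default legend: integer codes in the grid -> class names
CLASS_CODES = {1: "grassland", 2: "cropland", 3: "urban", 4: "water", 0: "nodata"}


@dataclass
class LandCoverRaster:
    """A rectangular classified grid with square cells of known size (m)."""

    classes: np.ndarray  # integer class codes, shape (nrows, ncols)
    cell_size: float = 30.0
    legend: dict = field(default_factory=lambda: dict(CLASS_CODES))

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValueError("raster must be a 2-D grid")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self):
        return self.classes.shape

    def code_of(self, name: str) -> int:
        for code, label in self.legend.items():
            if label == name:
                return code
        raise KeyError(name)

    def is_class(self, name: str) -> np.ndarray:
        return self.classes == self.code_of(name)

    def cell_centers(self):
        """(x, y) coordinate arrays of every cell center, row 0 at the bottom."""
        nrows, ncols = self.shape
        xs = (np.arange(ncols) + 0.5) * self.cell_size
        ys = (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    @property
    def extent(self):
        """(xmin, ymin, xmax, ymax) of the grid in meters."""
        nrows, ncols = self.shape
        return (0.0, 0.0, ncols * self.cell_size, nrows * self.cell_size)


@dataclass
class BufferMask:
    """Boolean inclusion grid for one route x radius."""

    include: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if not self.include.any():
            raise ValueError("buffer mask is empty")


def buffer_mask(route_xy: np.ndarray, radius: float, raster: LandCoverRaster) -> BufferMask:
    """Cells whose center lies within ``radius`` meters of the route polyline.

    ``route_xy`` is an (k, 2) array of polyline vertices in the raster's
    meter coordinates (a single vertex is a point route).  Raises when
    the polyline lies entirely outside the raster extent.
    """
    route_xy = np.atleast_2d(np.asarray(route_xy, dtype=float))
    if route_xy.shape[0] < 1 or route_xy.shape[1] != 2:
        raise ValueError("route must have at least one (x, y) vertex")
    if radius <= 0:
        raise ValueError("radius must be positive")

    xmin, ymin, xmax, ymax = raster.extent
    bx0, by0 = route_xy.min(axis=0)
    bx1, by1 = route_xy.max(axis=0)
    if bx1 < xmin or bx0 > xmax or by1 < ymin or by0 > ymax:
        raise ValueError("route polyline lies entirely outside the raster extent")

    geom = (
        shapely.Point(route_xy[0])
        if route_xy.shape[0] == 1
        else shapely.LineString(route_xy)
    )
    gx, gy = raster.cell_centers()
    pts = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
    dist = shapely.distance(pts, geom).reshape(raster.shape)
    return BufferMask(include=dist <= radius, radius=radius)


def percent_grassland(raster: LandCoverRaster, mask: BufferMask) -> float:
    """Percent of valid masked cells classified as grassland, in [0, 100]."""
    inc = mask.include
    valid = inc & ~raster.is_class("nodata")
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("all masked cells are nodata")
    n_grass = int((valid & raster.is_class("grassland")).sum())
    return 100.0 * n_grass / n_valid


def edge_density(
    raster: LandCoverRaster, mask: BufferMask, denominator: str = "grassland"
) -> float:
    """Grassland edge length per unit area (m/ha) within the mask.

    An edge face is a rook-adjacent pair of in-mask cells where exactly
    one is grassland and the other is a valid non-grassland class.
    With ``denominator="grassland"`` the length is divided by the
    grassland area inside the mask (NaN when no grassland is present);
    ``"landscape"`` divides by the total valid masked area instead.
    """
    if denominator not in ("grassland", "landscape"):
        raise ValueError(f"unknown denominator {denominator!r}")
    inc = mask.include
    grass = raster.is_class("grassland")
    valid = ~raster.is_class("nodata")
    other = valid & ~grass

    def faces(a, b):
        # horizontal neighbours
        h = np.sum(a[:, :-1] & b[:, 1:] & inc[:, :-1] & inc[:, 1:])
        h += np.sum(b[:, :-1] & a[:, 1:] & inc[:, :-1] & inc[:, 1:])
        # vertical neighbours
        v = np.sum(a[:-1, :] & b[1:, :] & inc[:-1, :] & inc[1:, :])
        v += np.sum(b[:-1, :] & a[1:, :] & inc[:-1, :] & inc[1:, :])
        return int(h + v)

    n_faces = faces(grass, other)
    edge_len_m = n_faces * raster.cell_size

    if denominator == "grassland":
        n_area_cells = int((inc & grass).sum())
        if n_area_cells == 0:
            return float("nan")
    else:
        n_area_cells = int((inc & valid).sum())
        if n_area_cells == 0:
            raise ValueError("all masked cells are nodata")
    area_ha = n_area_cells * raster.cell_size**2 / 1e4
    return edge_len_m / area_ha


# ---------------------------------------------------------------------------
# plain-text I/O


def read_ascii_grid(path: str | Path, cell_size: float | None = None) -> LandCoverRaster:
    """Read an ESRI ASCII grid of integer class codes.

    The header's ``cellsize`` is used unless ``cell_size`` overrides it.
    Rows in the file run north to south; they are flipped so row 0 is
    the grid's southern edge.
    """
    lines = Path(path).read_text().splitlines()
    header = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    grid = np.loadtxt(lines[body_start:], dtype=int, ndmin=2)
    if "nrows" in header and grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid body does not match the declared nrows/ncols")
    cs = cell_size if cell_size is not None else header.get("cellsize", 30.0)
    return LandCoverRaster(classes=grid[::-1], cell_size=cs)


def write_ascii_grid(raster: LandCoverRaster, path: str | Path) -> None:
    nrows, ncols = raster.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner 0\nyllcorner 0\n"
        f"cellsize {raster.cell_size:g}\nnodata_value 0\n"
    )
    body = "\n".join(" ".join(str(v) for v in row) for row in raster.classes[::-1])
    Path(path).write_text(header + body + "\n")


def read_routes_csv(path: str | Path) -> dict:
    """Route polylines from CSV (route_id, vertex_index, x_m, y_m) -> arrays."""
    df = pd.read_csv(path)
    routes = {}
    for rid, grp in df.groupby("route_id"):
        grp = grp.sort_values("vertex_index")
        routes[rid] = grp[["x_m", "y_m"]].to_numpy(dtype=float)
    return routes


def route_metrics_table(
    raster: LandCoverRaster, routes: dict, radii_m: dict | None = None
) -> pd.DataFrame:
    """Percent grassland and edge density per route and buffer radius.

    ``radii_m`` maps a buffer label to meters; defaults to the 3/5/10-km
    home-range scales.
    """
    if radii_m is None:
        radii_m = {"3km": 3000.0, "5km": 5000.0, "10km": 10000.0}
    rows = []
    for rid, xy in routes.items():
        for label, radius in radii_m.items():
            mask = buffer_mask(xy, radius, raster)
            rows.append(
                {
                    "route_id": rid,
                    "radius_m": radius,
                    "buffer": label,
                    "grass_pct": percent_grassland(raster, mask),
                    "edge_density": edge_density(raster, mask),
                }
            )
    return pd.DataFrame(rows)
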