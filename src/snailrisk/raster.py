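"""Raster data model and geometry shared by every pipeline stage.

A :class:`Grid` is a single co-registered raster layer: a dense matrix of
values plus the geotransform of its top-left corner. Row 0 is the
northernmost row and column 0 the westernmost column; cells are square.
Nodata cells are held as NaN in memory and written back with the grid's
sentinel value.

Cell centers sit at ``(xmin + (col + 0.5) * cell_size,
ymax - (row + 0.5) * cell_size)`` and every point-in-cell test uses the
half-open interval ``[edge, edge + cell_size)`` so a point on a shared
edge belongs to exactly one cell.

Distances are planar Euclidean in map units; the package treats map units
opaquely (degrees on geographic rasters, meters on projected ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Grid",
    "GridStack",
    "OccurrenceSet",
    "GridFormatError",
    "GeometryError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_occurrences",
    "write_occurrences",
    "rescale01",
    "proximity_component",
    "latitude_band_counts",
]

#: Sentinel written for nodata cells unless the grid carries its own.
DEFAULT_NODATA = -9999.0

#: Keys of the Esri ASCII grid header, in canonical write order.
_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                      "nodata_value")


class GridFormatError(ValueError):
    """Raised for malformed Esri ASCII grid files."""


class GeometryError(ValueError):
    """Raised when grids that must share a geometry do not."""


@dataclass(frozen=True)
class Grid:
    """A single raster layer with geotransform and nodata handling.

    Parameters
    ----------
    values
        ``(nrows, ncols)`` float array; nodata cells are NaN.
    xmin, ymax
        Map coordinates of the outer top-left corner.
    cell_size
        Map units per (square) cell.
    nodata
        Sentinel used when the grid is written to disk.
    crs_label
        Free-text coordinate-system tag; not interpreted.
    """

    values: np.ndarray
    xmin: float = 0.0
    ymax: float = 0.0
    cell_size: float = 1.0
    nodata: float = DEFAULT_NODATA
    crs_label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 1:
            raise ValueError("grid values must be a non-empty 2-D matrix")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if np.isinf(vals).any():
            raise ValueError("non-nodata grid values must be finite")
        object.__setattr__(self, "values", vals)

    # -- shape & geometry -------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cell_size

    @property
    def ymin(self) -> float:
        return self.ymax - self.nrows * self.cell_size

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return ~np.isnan(self.values)

    def same_geometry(self, other: "Grid", *, tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.xmin - other.xmin) <= tol
            and abs(self.ymax - other.ymax) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def require_alignment(self, other: "Grid") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"grids are not aligned: {self.values.shape} @"
                f" ({self.xmin},{self.ymax},{self.cell_size}) vs"
                f" {other.values.shape} @"
                f" ({other.xmin},{other.ymax},{other.cell_size})"
            )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate arrays of shape (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xmin + (cols + 0.5) * self.cell_size
        y = self.ymax - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.xmin + (col + 0.5) * self.cell_size,
            self.ymax - (row + 0.5) * self.cell_size,
        )

    def point_to_cell(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Cell (row, col) containing a point, or None when outside.

        Half-open intervals: a point on the west/north edge of a cell is in
        that cell; a point on the east/south outer boundary is outside.
        """
        col = int(np.floor((lon - self.xmin) / self.cell_size))
        row = int(np.floor((self.ymax - lat) / self.cell_size))
        # the north/west edges are inclusive, so ymax itself maps to row 0
        if lat == self.ymax:
            row = 0
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            return None
        return row, col

    def with_values(self, values: np.ndarray) -> "Grid":
        """A copy of this grid carrying different cell values."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class GridStack:
    """An ordered, geometry-aligned collection of named layers.

    All layers must share shape, geotransform and nodata mask; the common
    mask is intersected on construction so downstream per-cell math never
    mixes data and fill values.
    """

    layers: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            return
        grids = list(self.layers.values())
        ref = grids[0]
        for g in grids[1:]:
            ref.require_alignment(g)
        common = np.logical_and.reduce([g.mask for g in grids])
        if not all(np.array_equal(g.mask, common) for g in grids):
            self.layers = {
                name: g.with_values(np.where(common, g.values, np.nan))
                for name, g in self.layers.items()
            }

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def ref(self) -> Grid:
        return next(iter(self.layers.values()))

    @property
    def mask(self) -> np.ndarray:
        return self.ref.mask

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def subset(self, names: Sequence[str]) -> "GridStack":
        return GridStack({n: self.layers[n] for n in names})

    def matrix(self, cells: np.ndarray | None = None) -> np.ndarray:
        """Layer values as an ``(n_cells, n_layers)`` matrix.

        ``cells`` is an array of flat indices into the grid; by default all
        cells carrying data, in row-major order.
        """
        if cells is None:
            cells = np.flatnonzero(self.mask.ravel())
        out = np.empty((len(cells), len(self.layers)))
        for j, g in enumerate(self.layers.values()):
            out[:, j] = g.values.ravel()[cells]
        return out

    def data_cells(self) -> np.ndarray:
        """Flat indices of cells carrying data, row-major."""
        return np.flatnonzero(self.mask.ravel())


@dataclass
class OccurrenceSet:
    """Species occurrence points in geographic coordinates."""

    species: str
    points: list[tuple[float, float]]

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float).reshape(-1, 2)

    def to_cells(self, grid: Grid, *, thin: bool = True) -> np.ndarray:
        """Flat cell indices of the points that fall inside ``grid``.

        Points outside the extent or on nodata cells are dropped with a
        warning. With ``thin`` (the default) duplicates collapse to one
        record per cell, the standard per-cell thinning of presence data.
        """
        inside: list[int] = []
        n_out = 0
        for lon, lat in self.points:
            rc = grid.point_to_cell(lon, lat)
            if rc is None or not grid.mask[rc]:
                n_out += 1
                continue
            inside.append(rc[0] * grid.ncols + rc[1])
        if n_out:
            warnings.warn(
                f"{n_out} occurrence point(s) outside the grid or on nodata"
                " were dropped", stacklevel=2)
        cells = np.asarray(inside, dtype=np.intp)
        if thin and cells.size:
            cells = np.unique(cells)
        return cells


# ---------------------------------------------------------------------------
# Esri ASCII grid I/O
# ---------------------------------------------------------------------------

def _format_value(v: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    if np.isnan(v):
        v = np.nan  # formatted by caller; never reached for data cells
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(float(v))


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an Esri ASCII grid file.

    The header carries ``ncols, nrows, xllcorner, yllcorner, cellsize`` and
    optionally ``NODATA_value``; the body is row-major north to south.
    Cells equal to the nodata sentinel come back as NaN.
    """
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0].lower()
        if key in _ASCII_HEADER_KEYS:
            if len(parts) != 2:
                raise GridFormatError(f"malformed header line for '{key}'")
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(
                    f"non-numeric value for header key '{key}'") from exc
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GridFormatError(f"missing header key '{key}'")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if ncols < 1 or nrows < 1:
        raise GridFormatError("ncols/nrows must be positive")
    if header["cellsize"] <= 0:
        raise GridFormatError("cellsize must be positive")
    nodata = header.get("nodata_value", DEFAULT_NODATA)

    for line in lines[i:]:
        parts = line.split()
        if not parts:
            continue
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise GridFormatError(
                f"non-numeric cell value in data row {len(rows)}") from exc
    if len(rows) != nrows:
        raise GridFormatError(
            f"expected {nrows} data rows, found {len(rows)}")
    for r, row in enumerate(rows):
        if len(row) != ncols:
            raise GridFormatError(
                f"row {r} has {len(row)} values, expected {ncols}")
    values = np.asarray(rows, dtype=float)
    values[values == nodata] = np.nan
    cell = header["cellsize"]
    return Grid(
        values=values,
        xmin=header["xllcorner"],
        ymax=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        nodata=nodata,
    )


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write ``grid`` as an Esri ASCII file.

    Values are formatted with the shortest exact decimal representation so
    ``read_ascii_grid(write_ascii_grid(g))`` reproduces the file byte for
    byte on a second round trip.
    """
    path = Path(path)
    nd = _format_value(grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {_format_value(grid.xmin)}\n")
        fh.write(f"yllcorner {_format_value(grid.ymin)}\n")
        fh.write(f"cellsize {_format_value(grid.cell_size)}\n")
        fh.write(f"NODATA_value {nd}\n")
        for row in grid.values:
            fh.write(" ".join(
                nd if np.isnan(v) else _format_value(v) for v in row))
            fh.write("\n")


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read delimited occurrence text with header ``species,lon,lat``."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    for need in ("species", "lon", "lat"):
        if need not in cols:
            raise ValueError(f"occurrence file missing column '{need}'")
    species = str(df[cols["species"]].iloc[0]) if len(df) else ""
    pts = list(zip(df[cols["lon"]].astype(float), df[cols["lat"]].astype(float)))
    return OccurrenceSet(species=species, points=pts)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    pd.DataFrame(
        {"species": occ.species,
         "lon": [p[0] for p in occ.points],
         "lat": [p[1] for p in occ.points]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Grid arithmetic
# ---------------------------------------------------------------------------

def rescale01(g: Grid) -> Grid:
    """Linearly rescale data cells onto [0, 1].

    The minimum maps to 0 and the maximum to 1; nodata cells are preserved.
    A constant grid maps every data cell to 0 (with a warning) so batch
    pipelines survive degenerate layers.
    """
    vals = g.values
    data = vals[g.mask]
    if data.size == 0:
        raise ValueError("cannot rescale an all-nodata grid")
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        warnings.warn("rescale01: constant grid, all data cells set to 0",
                      stacklevel=2)
        out = np.where(g.mask, 0.0, np.nan)
    else:
        out = (vals - lo) / (hi - lo)
    return g.with_values(out)


def proximity_component(target_mask: Grid, occ: OccurrenceSet) -> Grid:
    """Rescaled inverse distance from masked cells to the nearest occurrence.

    For every cell of ``target_mask`` equal to 1, the planar Euclidean
    distance (map units, cell center to point) to the nearest occurrence is
    computed; the result is ``1 - rescale01(distance)`` so the closest cell
    scores 1 and the farthest 0. Cells with mask 0 become nodata.
    """
    if len(occ) == 0:
        raise ValueError("proximity_component requires at least one occurrence")
    sel = target_mask.mask & (target_mask.values == 1)
    out = np.full(target_mask.values.shape, np.nan)
    if sel.any():
        xs, ys = target_mask.cell_centers()
        centers = np.column_stack([xs[sel], ys[sel]])
        tree = cKDTree(occ.as_array())
        dist, _ = tree.query(centers)
        lo, hi = dist.min(), dist.max()
        if hi == lo:
            warnings.warn(
                "proximity_component: constant distance, cells set to 0",
                stacklevel=2)
            out[sel] = 0.0
        else:
            out[sel] = 1.0 - (dist - lo) / (hi - lo)
    return target_mask.with_values(out)


def latitude_band_counts(g: Grid, band_width: float = 1.0) -> pd.DataFrame:
    """Count cells per value within latitude bands.

    Each data cell is assigned to the band containing its cell-center
    latitude (bands are ``[k*w, (k+1)*w)``). Returns a tidy table with
    columns ``band_south``, ``band_north``, ``value``, ``count``; the counts
    partition the data cells.
    """
    if band_width <= 0:
        raise ValueError("band_width must be positive")
    mask = g.mask
    _, ys = g.cell_centers()
    lat = ys[mask]
    vals = g.values[mask]
    band = np.floor(lat / band_width).astype(int)
    df = pd.DataFrame({"band": band, "value": vals})
    counts = (df.groupby(["band", "value"]).size()
              .rename("count").reset_index())
    counts["band_south"] = counts.pop("band") * band_width
    counts["band_north"] = counts["band_south"] + band_width
    return counts[["band_south", "band_north", "value", "count"]].sort_values(
        ["band_south", "value"], ignore_index=True)
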