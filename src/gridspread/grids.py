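"""Regular raster lattices and per-cell value surfaces.

The whole analysis lives on planar regular grids (units of km): a fine
grid on which dispersal is simulated and species ranges are predicted,
and a coarse grid on which richness is counted and regressions are run.
Projection handling (the analysis assumes an equal-area projection) is
treated as preprocessing and is out of scope here.

Conventions
-----------
* Cell indexing is row-major and 0-based with row 0 at the top of the
  grid; the centre of cell (i, j) is at
  ``(x_origin + (j + 0.5) * cell_size, y_origin + (i + 0.5) * cell_size)``.
* Missing values are carried as NaN in memory and mapped to a nodata
  sentinel on disk; missingness propagates through arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LatticeGrid",
    "Surface",
    "zonal_mean",
    "zonal_range",
    "climate_anomaly",
    "land_filter",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_tiff",
    "write_tiff",
    "read_surface",
    "write_surface",
    "cell_table",
    "surfaces_from_cell_table",
]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class LatticeGrid:
    """A regular planar lattice with an optional per-cell land fraction.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both at least 1.
    cell_size
        Cell edge length in km.
    x_origin, y_origin
        Planar coordinates (km) of the grid's top-left corner.
    land_fraction
        Optional ``(n_rows, n_cols)`` array of per-cell land fractions
        in [0, 1]; used by :func:`land_filter` and by land masking.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 10.0
    x_origin: float = 0.0
    y_origin: float = 0.0
    land_fraction: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.land_fraction is not None:
            lf = np.asarray(self.land_fraction, dtype=float)
            if lf.shape != (self.n_rows, self.n_cols):
                raise ValueError(
                    f"land_fraction shape {lf.shape} != {(self.n_rows, self.n_cols)}"
                )
            if np.nanmin(lf) < 0 or np.nanmax(lf) > 1:
                raise ValueError("land_fraction must lie in [0, 1]")
            lf.flags.writeable = False
            object.__setattr__(self, "land_fraction", lf)

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) centres in row-major order."""
        ii, jj = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        x = self.x_origin + (jj + 0.5) * self.cell_size
        y = self.y_origin + (ii + 0.5) * self.cell_size
        return np.column_stack([x.ravel(), y.ravel()])

    def same_geometry(self, other: "LatticeGrid") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
        )

    def coarsen(self, factor: int) -> "LatticeGrid":
        """The coarse grid obtained by block-aggregating by ``factor``.

        Ragged final blocks are kept (ceil division); the land fraction,
        if present, is block-averaged.
        """
        if factor < 1:
            raise ValueError("factor must be >= 1")
        nr = -(-self.n_rows // factor)
        nc = -(-self.n_cols // factor)
        lf = None
        if self.land_fraction is not None:
            lf = _block_reduce(self.land_fraction, factor, np.nanmean)
        return LatticeGrid(
            n_rows=nr,
            n_cols=nc,
            cell_size=self.cell_size * factor,
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            land_fraction=lf,
        )


@dataclass(frozen=True)
class Surface:
    """One numeric value per cell of a :class:`LatticeGrid`.

    Values are floats with NaN marking missing cells; ``missing_marker``
    is the on-disk sentinel used by the writers.
    """

    grid: LatticeGrid
    values: np.ndarray = field(repr=False)
    name: str = ""
    missing_marker: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.shape:
            raise ValueError(f"values shape {vals.shape} != grid shape {self.grid.shape}")
        vals = vals.copy()
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Surface":
        return Surface(
            grid=self.grid,
            values=values,
            name=self.name if name is None else name,
            missing_marker=self.missing_marker,
        )

    def rename(self, name: str) -> "Surface":
        return replace(self, name=name)


def _check_same_grid(*surfaces: Surface) -> None:
    first = surfaces[0].grid
    for s in surfaces[1:]:
        if not first.same_geometry(s.grid):
            raise ValueError("surfaces are not on the same grid")


def _block_reduce(values: np.ndarray, factor: int, reducer) -> np.ndarray:
    """Apply ``reducer`` over factor x factor blocks, NaN-aware, ragged OK."""
    nr, nc = values.shape
    pr = -(-nr // factor) * factor
    pc = -(-nc // factor) * factor
    padded = np.full((pr, pc), np.nan)
    padded[:nr, :nc] = values
    blocks = padded.reshape(pr // factor, factor, pc // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(pr // factor, pc // factor, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return reducer(blocks, axis=2)


# ---------------------------------------------------------------------
# Aggregation and anomalies
# ---------------------------------------------------------------------


def zonal_mean(fine: Surface, factor: int) -> Surface:
    """Block-average a fine surface onto the coarse grid.

    Each coarse cell holds the arithmetic mean of the non-missing fine
    cells in its ``factor`` x ``factor`` block; a block with no observed
    cells is missing. A final ragged block (when ``factor`` does not
    divide the dimensions) is averaged over the cells available.
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    if fine.grid.n_cells == 0:
        raise ValueError("empty surface")
    coarse_vals = _block_reduce(fine.values, factor, np.nanmean)
    return Surface(grid=fine.grid.coarsen(factor), values=coarse_vals, name=fine.name)


def zonal_range(fine: Surface, factor: int) -> Surface:
    """Block range (max minus min of observed cells); the conventional
    summary for topographic heterogeneity on the analysis grid."""
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    hi = _block_reduce(fine.values, factor, np.nanmax)
    lo = _block_reduce(fine.values, factor, np.nanmin)
    return Surface(grid=fine.grid.coarsen(factor), values=hi - lo, name=fine.name)


def climate_anomaly(current: Surface, past: Surface | Sequence[Surface]) -> Surface:
    """Contemporary-minus-paleo anomaly, cellwise.

    When several paleo layers are given (e.g. two LGM circulation-model
    reconstructions) they are averaged first. The sign convention is
    positive where the present is warmer/wetter than the past.
    """
    past_list = [past] if isinstance(past, Surface) else list(past)
    if not past_list:
        raise ValueError("at least one past surface is required")
    _check_same_grid(current, *past_list)
    past_mean = np.mean([p.values for p in past_list], axis=0)
    return current.with_values(current.values - past_mean)


def land_filter(grid: LatticeGrid, threshold: float = 0.5) -> np.ndarray:
    """Flat (row-major) indices of cells with land fraction strictly
    above ``threshold`` — the analysis cell set (default: >50% land)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if grid.land_fraction is None:
        raise ValueError("grid has no land_fraction")
    return np.flatnonzero(grid.land_fraction.ravel() > threshold)


# ---------------------------------------------------------------------
# Raster I/O: ESRI ASCII grid (text) and plain TIFF
# ---------------------------------------------------------------------


def write_ascii_grid(surface: Surface, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc).

    Rows are written top-first; ``xllcorner``/``yllcorner`` carry the
    grid origin as stored (this package's y axis increases with row
    index). Nodata cells are written as the surface's sentinel.
    """
    g = surface.grid
    vals = np.where(surface.missing, surface.missing_marker, surface.values)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.x_origin:.10g}\n"
        f"yllcorner {g.y_origin:.10g}\n"
        f"cellsize {g.cell_size:.10g}\n"
        f"NODATA_value {surface.missing_marker:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path, name: str = "") -> Surface:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(val)
            else:  # optional NODATA line absent
                fh.seek(pos)
                break
        vals = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    grid = LatticeGrid(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        x_origin=header.get("xllcorner", 0.0),
        y_origin=header.get("yllcorner", 0.0),
    )
    return Surface(grid=grid, values=vals, name=name or Path(path).stem, missing_marker=nodata)


def write_tiff(surface: Surface, path: str | Path) -> None:
    """Write surface values as a single-band float TIFF (NaN = nodata).

    Grid geometry is stored in the image description so a round trip
    restores it; no georeferencing tags are written.
    """
    import tifffile

    g = surface.grid
    desc = f"cell_size={g.cell_size:.10g};x_origin={g.x_origin:.10g};y_origin={g.y_origin:.10g}"
    tifffile.imwrite(path, surface.values.astype(np.float64), description=desc)


def read_tiff(path: str | Path, name: str = "") -> Surface:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        vals = tif.asarray().astype(float)
        desc = tif.pages[0].description or ""
    meta = dict(
        item.split("=", 1) for item in desc.split(";") if "=" in item
    )
    grid = LatticeGrid(
        n_rows=vals.shape[0],
        n_cols=vals.shape[1],
        cell_size=float(meta.get("cell_size", 1.0)),
        x_origin=float(meta.get("x_origin", 0.0)),
        y_origin=float(meta.get("y_origin", 0.0)),
    )
    return Surface(grid=grid, values=vals, name=name or Path(path).stem)


def write_surface(surface: Surface, path: str | Path) -> None:
    """Dispatch on extension: ``.asc`` text grid or ``.tif``/``.tiff``."""
    suffix = Path(path).suffix.lower()
    if suffix == ".asc":
        write_ascii_grid(surface, path)
    elif suffix in {".tif", ".tiff"}:
        write_tiff(surface, path)
    else:
        raise ValueError(f"unsupported raster extension: {suffix!r}")


def read_surface(path: str | Path, name: str = "") -> Surface:
    suffix = Path(path).suffix.lower()
    if suffix == ".asc":
        return read_ascii_grid(path, name=name)
    if suffix in {".tif", ".tiff"}:
        return read_tiff(path, name=name)
    raise ValueError(f"unsupported raster extension: {suffix!r}")


# ---------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------


def cell_table(grid: LatticeGrid, surfaces: Mapping[str, Surface] | Iterable[Surface] = ()) -> pd.DataFrame:
    """Row-major cell table: cell_id, row, col, x, y, land_fraction plus
    one column per surface. The exchange format between pipeline stages."""
    if not isinstance(surfaces, Mapping):
        surfaces = {s.name or f"surface_{k}": s for k, s in enumerate(surfaces)}
    ii, jj = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    centers = grid.cell_centers()
    table = pd.DataFrame(
        {
            "cell_id": np.arange(grid.n_cells),
            "row": ii.ravel(),
            "col": jj.ravel(),
            "x": centers[:, 0],
            "y": centers[:, 1],
            "land_fraction": (
                grid.land_fraction.ravel() if grid.land_fraction is not None else np.nan
            ),
        }
    )
    for name, surf in surfaces.items():
        if not grid.same_geometry(surf.grid):
            raise ValueError(f"surface {name!r} is not on the table's grid")
        table[name] = surf.values.ravel()
    return table


def surfaces_from_cell_table(table: pd.DataFrame, grid: LatticeGrid) -> dict[str, Surface]:
    """Rebuild surfaces from a cell table produced by :func:`cell_table`."""
    reserved = {"cell_id", "row", "col", "x", "y", "land_fraction"}
    out: dict[str, Surface] = {}
    for col in table.columns:
        if col in reserved:
            continue
        vals = np.full(grid.n_cells, np.nan)
        vals[table["cell_id"].to_numpy()] = table[col].to_numpy(dtype=float)
        out[col] = Surface(grid=grid, values=vals.reshape(grid.shape), name=col)
    return out
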