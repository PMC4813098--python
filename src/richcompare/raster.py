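"""Single-band raster grids on a shared planar geometry.

All grids in this package live on an abstract planar coordinate system in
kilometres.  The grid is indexed row-major with the origin at the lower-left
corner; cell ``(row, col)`` covers the half-open square
``[col*cs, (col+1)*cs) x [row*cs, (row+1)*cs)`` where ``cs`` is the cell
size.  Array storage follows the numpy convention (``values[row, col]``,
row 0 at the *bottom*), so writing to the ESRI ASCII dialect — which puts
the top row first — flips the row axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass(frozen=True)
class GridGeometry:
    """Shared geometry of a raster stack: shape, origin and cell size (km)."""

    ncols: int
    nrows: int
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map planar km coordinates to (row, col) under the half-open rule.

        Points exactly on a cell boundary belong to the higher-index cell.
        """
        col = np.floor((np.asarray(x, float) - self.xllcorner) / self.cellsize).astype(int)
        row = np.floor((np.asarray(y, float) - self.yllcorner) / self.cellsize).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates of every cell as two (nrows, ncols) arrays."""
        cx = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize
        cy = self.yllcorner + (np.arange(self.nrows) + 0.5) * self.cellsize
        return np.meshgrid(cx, cy)


@dataclass
class RasterGrid:
    """A single-band gridded surface; ``values[row, col]``, row 0 at bottom."""

    geometry: GridGeometry
    values: np.ndarray
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.geometry, np.asarray(values, float), self.nodata)

    def mask(self) -> np.ndarray:
        """Boolean array, True where data are valid."""
        valid = np.isfinite(self.values)
        if self.nodata is not None:
            valid &= self.values != self.nodata
        return valid


def same_geometry(*grids: RasterGrid) -> bool:
    first = grids[0].geometry
    return all(g.geometry == first for g in grids[1:])


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc). NaN cells become NODATA."""
    nodata = grid.nodata if grid.nodata is not None else -9999.0
    g = grid.geometry
    vals = np.where(np.isfinite(grid.values), grid.values, nodata)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.xllcorner!r}\n")
        fh.write(f"yllcorner {g.yllcorner!r}\n")
        fh.write(f"cellsize {g.cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        # top row first
        for row in vals[::-1]:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid; NODATA cells come back as NaN."""
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _HEADER_KEYS + ("nodata_value",):
                if len(parts) != 2:
                    raise ValueError(f"malformed header line for key '{parts[0]}'")
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for key in _HEADER_KEYS:
        if key not in header:
            raise ValueError(f"missing required header key '{key}'")
    geom = GridGeometry(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
    )
    values = np.loadtxt(data_lines, dtype=float)
    values = np.atleast_2d(values)
    if values.shape != geom.shape:
        raise ValueError(f"data shape {values.shape} does not match header {geom.shape}")
    values = values[::-1]  # back to row 0 = bottom
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return RasterGrid(geom, values, nodata=None)
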