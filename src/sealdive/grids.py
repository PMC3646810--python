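"""Regular lon/lat grids in the ESRI ASCII raster dialect.

A :class:`HabitatRaster` carries either charted water depth (metres,
positive down) or an integer seabed sediment code on a regular
geographic grid. Row 0 of ``values`` is the northernmost row, matching
the on-disk layout of ``.asc`` files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HabitatRaster",
    "GridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: Sediment integer codes used throughout the package.
SEDIMENT_CODES = {0: "unclassified", 1: "fine", 2: "coarse", 3: "rock"}

DEFAULT_NODATA = -9999.0


class GridFormatError(ValueError):
    """Raised when an ASCII grid file violates the expected layout."""


@dataclass(frozen=True)
class HabitatRaster:
    """A regular lon/lat grid of depth or sediment values.

    Parameters
    ----------
    ncols, nrows
        Grid dimensions (>= 1).
    xll, yll
        Longitude/latitude of the lower-left corner of the lower-left
        cell, in decimal degrees.
    cellsize
        Cell edge length in decimal degrees (> 0).
    nodata
        Sentinel value marking missing cells.
    values
        ``(nrows, ncols)`` array, row 0 = northernmost row.
    """

    ncols: int
    nrows: int
    xll: float
    yll: float
    cellsize: float
    nodata: float = DEFAULT_NODATA
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be > 0")
        if self.values is None:
            raise ValueError("values array is required")
        arr = np.asarray(self.values)
        if arr.shape != (self.nrows, self.ncols):
            raise ValueError(
                f"values shape {arr.shape} does not match "
                f"(nrows, ncols)=({self.nrows}, {self.ncols})"
            )
        object.__setattr__(self, "values", arr)

    # -- geometry -----------------------------------------------------
    @property
    def xmax(self) -> float:
        return self.xll + self.ncols * self.cellsize

    @property
    def ymax(self) -> float:
        return self.yll + self.nrows * self.cellsize

    def same_geometry(self, other: "HabitatRaster", tol: float = 1e-12) -> bool:
        """True when both grids share dimensions, origin and cellsize."""
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def contains(self, lon: float, lat: float) -> bool:
        """Point-in-extent test using the half-open [min, max) convention."""
        return (self.xll <= lon < self.xmax) and (self.yll <= lat < self.ymax)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Lon/lat of the centre of cell ``(row, col)`` (row 0 = north)."""
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat

    def is_nodata(self, value: float) -> bool:
        return value == self.nodata or (isinstance(value, float) and np.isnan(value))


def read_ascii_grid(path: str | Path) -> HabitatRaster:
    """Read an ESRI ASCII grid (.asc).

    The header must provide ``ncols``, ``nrows``, ``xllcorner``,
    ``yllcorner`` and ``cellsize``; ``NODATA_value`` is optional and
    defaults to -9999. Each data row must contain exactly ``ncols``
    whitespace-separated numbers and the file exactly ``nrows`` rows.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[tuple[int, str]] = []
    with open(path) as fh:
        lines = fh.readlines()

    header_keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in header_keys:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(
                    f"{path}: line {i + 1}: bad header value {parts[1]!r}"
                ) from exc
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GridFormatError(f"{path}: missing header field {key!r}")

    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)

    for lineno in range(i, len(lines)):
        if lines[lineno].strip():
            data_lines.append((lineno + 1, lines[lineno]))
    if len(data_lines) != nrows:
        raise GridFormatError(
            f"{path}: header declares nrows={nrows} but file has "
            f"{len(data_lines)} data rows"
        )
    rows = []
    for lineno, line in data_lines:
        tokens = line.split()
        if len(tokens) != ncols:
            raise GridFormatError(
                f"{path}: line {lineno}: expected {ncols} values, got {len(tokens)}"
            )
        try:
            rows.append(np.array(tokens, dtype=float))
        except ValueError as exc:
            raise GridFormatError(f"{path}: line {lineno}: non-numeric value") from exc

    return HabitatRaster(
        ncols=ncols,
        nrows=nrows,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=nodata,
        values=np.vstack(rows),
    )


def write_ascii_grid(raster: HabitatRaster, path: str | Path) -> Path:
    """Write ``raster`` as an ESRI ASCII grid; returns the path written."""
    path = Path(path)
    is_int = np.issubdtype(raster.values.dtype, np.integer)
    fmt = "%d" if is_int else "%.10g"
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:.10g}\n")
        fh.write(f"yllcorner {raster.yll:.10g}\n")
        fh.write(f"cellsize {raster.cellsize:.10g}\n")
        nodata = int(raster.nodata) if is_int else raster.nodata
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, raster.values, fmt=fmt)
    return path
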