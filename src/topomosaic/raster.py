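"""Gridded-data container and I/O.

A :class:`Raster` is a single-band 2-D grid in a projected local frame with a
constant cell size in metres.  Row 0 is the top of the grid; the centre of
pixel ``(0, 0)`` sits half a cell in from ``origin`` (the upper-left corner).
Cells flagged in ``nodata_mask`` are excluded from every statistic downstream.

Two on-disk formats are supported:

* single-band TIFF (via :mod:`tifffile`), with cell size, origin and nodata
  value stored as JSON in the ImageDescription tag;
* a headered plain-text grid (ESRI ASCII-grid dialect, ``.asc``/``.grd``),
  used for small human-readable fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Raster",
    "RasterFormatError",
    "AlignmentError",
    "read_raster",
    "write_raster",
    "align_nearest",
    "apply_mask",
]


class RasterFormatError(ValueError):
    """Raised when a file cannot be interpreted as a single-band raster."""


class AlignmentError(ValueError):
    """Raised when two rasters cannot be placed on a common grid."""


@dataclass
class Raster:
    """Single-band grid with cell size (m), nodata mask and UL-corner origin."""

    values: np.ndarray
    cell_size: float = 30.0
    nodata_mask: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got shape {self.values.shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("values and nodata_mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        """1-D array of the values on valid (unmasked) cells."""
        return self.values[~self.nodata_mask]

    def copy(self) -> "Raster":
        return Raster(
            self.values.copy(),
            self.cell_size,
            self.nodata_mask.copy(),
            tuple(self.origin),
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre; y decreases down rows."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


_ASC_NODATA = -99999.0


def write_raster(raster: Raster, path: str | Path, nodata: float = _ASC_NODATA) -> None:
    """Write ``raster`` to ``path``; format chosen by suffix (.tif or text grid)."""
    path = Path(path)
    vals = np.array(raster.values, dtype=np.float64, copy=True)
    vals[raster.nodata_mask] = nodata
    if path.suffix.lower() in {".tif", ".tiff"}:
        meta = {
            "cell_size": raster.cell_size,
            "origin": list(raster.origin),
            "nodata": nodata,
        }
        tifffile.imwrite(path, vals.astype(np.float32), description=json.dumps(meta))
    else:
        x0, y0 = raster.origin
        rows, cols = raster.shape
        header = (
            f"ncols {cols}\nnrows {rows}\n"
            f"xllcorner {x0!r}\nyllcorner {y0 - rows * raster.cell_size!r}\n"
            f"cellsize {raster.cell_size!r}\nNODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.9g")


def read_raster(path: str | Path) -> Raster:
    """Read a single-band raster (TIFF or ASCII grid); nodata goes to the mask."""
    path = Path(path)
    if not path.exists():
        raise RasterFormatError(f"no such raster file: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_tiff(path)
    return _read_ascii_grid(path)


def _read_tiff(path: Path) -> Raster:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    if arr.ndim != 2:
        raise RasterFormatError(f"{path}: expected a single band, got shape {arr.shape}")
    if "cell_size" not in meta:
        raise RasterFormatError(f"{path}: missing georeferencing metadata (cell_size)")
    nodata = float(meta.get("nodata", _ASC_NODATA))
    vals = arr.astype(np.float64)
    mask = np.isclose(vals, nodata) | ~np.isfinite(vals)
    vals = vals.copy()
    vals[mask] = 0.0
    return Raster(vals, float(meta["cell_size"]), mask, tuple(meta.get("origin", (0.0, 0.0))))


def _read_ascii_grid(path: Path) -> Raster:
    header: dict[str, float] = {}
    lines = path.read_text().splitlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"{path}: malformed grid header, missing {key}")
    vals = np.loadtxt(lines[n_header:], ndmin=2, dtype=np.float64)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (rows, cols):
        raise RasterFormatError(
            f"{path}: header says {rows}x{cols} but data is {vals.shape[0]}x{vals.shape[1]}"
        )
    nodata = header.get("nodata_value", _ASC_NODATA)
    mask = np.isclose(vals, nodata) | ~np.isfinite(vals)
    vals = vals.copy()
    vals[mask] = 0.0
    cell = header["cellsize"]
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", -rows * cell) + rows * cell)
    return Raster(vals, cell, mask, origin)


def align_nearest(source: Raster, template: Raster) -> Raster:
    """Resample ``source`` onto ``template``'s grid by nearest-cell-centre lookup.

    Each output cell takes the value of the source cell whose centre is
    nearest to the output cell's centre; nodata propagates.  Raises
    :class:`AlignmentError` when the extents do not overlap.
    """
    sx0, sy0 = source.origin
    tx0, ty0 = template.origin
    s_rows, s_cols = source.shape
    t_rows, t_cols = template.shape
    # extents: x in [x0, x0 + cols*cell], y in [y0 - rows*cell, y0]
    if (
        tx0 >= sx0 + s_cols * source.cell_size
        or tx0 + t_cols * template.cell_size <= sx0
        or ty0 <= sy0 - s_rows * source.cell_size
        or ty0 - t_rows * template.cell_size >= sy0
    ):
        raise AlignmentError("source and template extents are disjoint")

    tx = tx0 + (np.arange(t_cols) + 0.5) * template.cell_size
    ty = ty0 - (np.arange(t_rows) + 0.5) * template.cell_size
    # nearest source cell indices (clipped to the source grid)
    col_idx = np.clip(np.round((tx - sx0) / source.cell_size - 0.5).astype(int), 0, s_cols - 1)
    row_idx = np.clip(np.round((sy0 - ty) / source.cell_size - 0.5).astype(int), 0, s_rows - 1)
    rr, cc = np.meshgrid(row_idx, col_idx, indexing="ij")
    return Raster(
        source.values[rr, cc],
        template.cell_size,
        source.nodata_mask[rr, cc],
        tuple(template.origin),
    )


def apply_mask(target: Raster, mask: Raster) -> Raster:
    """Return ``target`` with ``mask``'s nodata/true cells added to its mask.

    ``mask`` may be a boolean raster (true/nonzero = mask out) or any raster,
    in which case its nodata cells and nonzero cells are masked.
    """
    if mask.shape != target.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match target shape {target.shape}"
        )
    extra = mask.nodata_mask | (mask.values.astype(bool))
    return Raster(
        target.values.copy(),
        target.cell_size,
        target.nodata_mask | extra,
        tuple(target.origin),
    )
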