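"""Raster file I/O for categorical grids.

Two dialects:

* ESRI ASCII grid (``.asc``) — plain text, carries the cell size in its
  header; the canonical interchange format here because fixtures stay
  human-readable and diffable.
* Single-band integer TIFF (``.tif``/``.tiff``) via :mod:`tifffile`. The
  cell size is stored in the ImageDescription tag as JSON on write; when
  a file carries no such tag a 30 m Landsat-style cell is assumed.

Round-trips are bit-exact on values, nodata mask, and cell size.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from lucc.grids import ClassLegend, LandCoverGrid, ZoneMap

DEFAULT_CELL_SIZE_M = 30.0

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def _read_asc(path: Path) -> tuple[np.ndarray, float, int]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} missing header field {key!r}")
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"ASCII grid {path}: data shape {data.shape} does not match header"
        )
    nodata = int(header.get("nodata_value", -9999))
    return data, float(header["cellsize"]), nodata


def _write_asc(path: Path, values: np.ndarray, cell_size_m: float, nodata: int) -> None:
    rows, cols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size_m:g}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, values, fmt="%d")


def _read_tif(path: Path) -> tuple[np.ndarray, float]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        cell = DEFAULT_CELL_SIZE_M
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                cell = float(meta.get("cell_size_m", cell))
            except (ValueError, TypeError, AttributeError):
                pass
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    if data.ndim != 2:
        raise ValueError(f"{path} is not a single-band raster (shape {data.shape})")
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path} is not an integer raster (dtype {data.dtype})")
    return data.astype(np.int64), cell


def _write_tif(path: Path, values: np.ndarray, cell_size_m: float) -> None:
    tifffile.imwrite(
        path,
        values.astype(np.int32),
        description=json.dumps({"cell_size_m": cell_size_m}),
    )


def load_landcover(
    path: str | Path,
    legend: ClassLegend,
    date_label: str = "",
) -> LandCoverGrid:
    """Read a categorical land-cover raster and validate it against a legend.

    Any code in the file that is neither a legend class nor the legend's
    nodata code is an error (codes are never silently remapped). For ASCII
    grids whose declared nodata differs from the legend's, nodata cells
    are rewritten to ``legend.nodata_code`` — a relabelling of "outside
    the map", not of a class.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".asc":
        data, cell, file_nodata = _read_asc(path)
        if file_nodata != legend.nodata_code:
            data = np.where(data == file_nodata, legend.nodata_code, data)
    elif path.suffix.lower() in (".tif", ".tiff"):
        data, cell = _read_tif(path)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")
    allowed = set(legend.codes) | {legend.nodata_code}
    unknown = sorted(set(np.unique(data).tolist()) - allowed)
    if unknown:
        raise ValueError(
            f"{path} contains class codes not in the legend: {unknown}"
        )
    return LandCoverGrid(values=data, cell_size_m=cell, legend=legend, date_label=date_label)


def write_landcover(grid: LandCoverGrid, path: str | Path) -> None:
    """Write a land-cover grid; format chosen by extension (.asc/.tif)."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        _write_asc(path, grid.values, grid.cell_size_m, grid.legend.nodata_code)
    elif path.suffix.lower() in (".tif", ".tiff"):
        _write_tif(path, grid.values, grid.cell_size_m)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")


def load_zones(path: str | Path, nodata_id: int = -1) -> ZoneMap:
    """Read a zone raster (.asc or .tif)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".asc":
        data, _, file_nodata = _read_asc(path)
        if file_nodata != nodata_id:
            data = np.where(data == file_nodata, nodata_id, data)
    elif path.suffix.lower() in (".tif", ".tiff"):
        data, _ = _read_tif(path)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")
    return ZoneMap(values=data, nodata_id=nodata_id)


def write_zones(zones: ZoneMap, path: str | Path, cell_size_m: float = DEFAULT_CELL_SIZE_M) -> None:
    path = Path(path)
    if path.suffix.lower() == ".asc":
        _write_asc(path, zones.values, cell_size_m, zones.nodata_id)
    elif path.suffix.lower() in (".tif", ".tiff"):
        _write_tif(path, zones.values, cell_size_m)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")
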