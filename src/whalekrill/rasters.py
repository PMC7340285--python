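"""Plain-text raster I/O (ESRI ASCII grid).

All pipeline rasters are single-band grids on the planar km study grid;
the ASCII grid format keeps every artifact diff-able and dependency-free.
Arrays are stored row 0 = northernmost row, matching the format's top-down
row order.
"""

from __future__ import annotations

import numpy as np

NODATA = -9999.0


def write_ascii_grid(
    path,
    values: np.ndarray,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float = 1.0,
    nodata: float = NODATA,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid. NaN cells become nodata."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"raster must be 2-D, got shape {arr.shape}")
    out = np.where(np.isnan(arr), nodata, arr)
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        f"xllcorner {xllcorner:.6f}\n"
        f"yllcorner {yllcorner:.6f}\n"
        f"cellsize {cellsize:.6f}\n"
        f"NODATA_value {nodata:.1f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; nodata cells become NaN.

    Returns (array, header) with header keys ncols, nrows, xllcorner,
    yllcorner, cellsize, nodata_value.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    nodata = header.get("nodata_value", NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    expect = (int(header["nrows"]), int(header["ncols"]))
    if arr.shape != expect:
        raise ValueError(f"grid shape {arr.shape} does not match header {expect}")
    return arr, header
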