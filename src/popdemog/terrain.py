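"""Topographic-variance raster metric.

Per cell, the elevation range (max - min) in a centered odd-sized moving
window (default 9 x 9), log-transformed as ``10 * log10(range + 1)`` — a
decibel-like reading where flat terrain maps to 0.  Edge cells use the
truncated window; nodata cells are excluded from window statistics and
propagate only when a window contains no valid cell.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

__all__ = ["RasterGrid", "topo_variance", "read_esri_ascii", "write_esri_ascii"]


@dataclasses.dataclass
class RasterGrid:
    """Rectangular elevation grid (metres) with ESRI-ASCII style metadata."""

    values: np.ndarray
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster must be 2-D")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata


def topo_variance(r: RasterGrid, window: int = 9) -> RasterGrid:
    """Windowed elevation range on a log10 scale (x10).

    The max/min filters use edge replication, which for order statistics is
    exactly the truncated-window rule.  Raises on an all-nodata raster.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    valid = r.valid_mask
    if not valid.any():
        raise ValueError("raster has no valid cells")
    hi_in = np.where(valid, r.values, -np.inf)
    lo_in = np.where(valid, r.values, np.inf)
    hi = ndimage.maximum_filter(hi_in, size=window, mode="nearest")
    lo = ndimage.minimum_filter(lo_in, size=window, mode="nearest")
    rng = hi - lo
    ok = np.isfinite(rng)
    out = np.full(r.values.shape, r.nodata)
    out[ok] = 10.0 * np.log10(rng[ok] + 1.0)
    return RasterGrid(out, r.cellsize, r.xllcorner, r.yllcorner, r.nodata)


def read_esri_ascii(path: str) -> RasterGrid:
    """Read an ESRI ASCII grid (ncols/nrows/xll/yll/cellsize/NODATA header)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    values = values.reshape(nrows, ncols)
    return RasterGrid(
        values,
        cellsize=header.get("cellsize", 1.0),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_esri_ascii(r: RasterGrid, path: str) -> None:
    nrows, ncols = r.values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {r.xllcorner}\n")
        fh.write(f"yllcorner {r.yllcorner}\n")
        fh.write(f"cellsize {r.cellsize}\n")
        fh.write(f"NODATA_value {r.nodata}\n")
        for row in r.values:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
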