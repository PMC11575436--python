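"""Plain-text raster and table I/O.

Rasters use the ESRI ASCII grid format: a six-line header (ncols, nrows,
xllcorner, yllcorner, cellsize, NODATA_value) followed by nrows rows of
ncols values, **top row first** (north-up). Internally rows are stored
bottom-up, so reading/writing flips the row order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .familiarity import GridSpec, RasterGrid
from .trajectory import Track

__all__ = ["write_ascii_grid", "read_ascii_grid", "write_track_csv", "read_track_csv"]

NODATA = -9999.0


def write_ascii_grid(raster: RasterGrid, path, nodata: float = NODATA, fmt: str = "%.10g") -> None:
    spec = raster.spec
    vals = np.where(np.isnan(raster.values), nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.x0:.10g}\n")
        fh.write(f"yllcorner {spec.y0:.10g}\n")
        fh.write(f"cellsize {spec.res:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in vals[::-1]:  # top row first
            fh.write(" ".join(fmt % v for v in row) + "\n")


def read_ascii_grid(path) -> RasterGrid:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    spec = GridSpec(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        res=header["cellsize"],
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
    )
    vals = np.atleast_2d(vals)[::-1]  # back to bottom-up storage
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    return RasterGrid(spec=spec, values=vals)


def write_track_csv(track: Track, path, float_format: str = "%.10g") -> None:
    df = pd.DataFrame(
        {
            "id": track.id,
            "t": [p.t for p in track.locations],
            "x": [p.x for p in track.locations],
            "y": [p.y for p in track.locations],
        }
    )
    df.to_csv(path, index=False, float_format=float_format)


def read_track_csv(path) -> Track:
    from .trajectory import read_track

    return read_track(path, column_map={"time": "t"})
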