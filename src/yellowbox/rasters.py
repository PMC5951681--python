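"""Gridded environmental layers and region masks.

Layers live on a shared north-up grid described by the lower-left corner,
a square cell size, and a CRS tag.  Two CRS conventions are supported:

* ``"EPSG:4326"`` — origin/cell size in decimal degrees; between-cell
  distances are great-circle km;
* ``"local-km"`` — a projected plane with coordinates directly in km;
  distances are Euclidean.

I/O is the plain-text ESRI ASCII grid format (one file per layer) with a
JSON sidecar carrying layer names, CRS and the scenario tag.  Row 0 of
the in-memory arrays is the SOUTH row (y increases with row index); the
ASCII format stores north-first and the reader/writer flips accordingly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import shape

NODATA = -9999.0


@dataclass
class EnvRasterStack:
    layers: dict[str, np.ndarray]  # name -> (n_rows, n_cols), row 0 = south
    x_origin: float  # west edge (lower-left corner) of the grid
    y_origin: float  # south edge
    cell_size: float  # degrees (EPSG:4326) or km (local-km)
    crs: str = "local-km"
    scenario: str = "current"
    nodata: float = NODATA

    def __post_init__(self):
        shapes = {v.shape for v in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers are not co-registered: shapes {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of cell centres, each shaped like a layer."""
        nr, nc = self.shape
        xs = self.x_origin + (np.arange(nc) + 0.5) * self.cell_size
        ys = self.y_origin + (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def valid_mask(self) -> np.ndarray:
        m = np.ones(self.shape, dtype=bool)
        for v in self.layers.values():
            m &= (v != self.nodata) & np.isfinite(v)
        return m

    def sample(self, name: str, x, y) -> np.ndarray:
        """Bilinear sample of one layer at point coordinates."""
        from scipy.ndimage import map_coordinates

        scalar = np.isscalar(x) or np.ndim(x) == 0
        col = (np.atleast_1d(np.asarray(x, float)) - self.x_origin) / self.cell_size - 0.5
        row = (np.atleast_1d(np.asarray(y, float)) - self.y_origin) / self.cell_size - 0.5
        out = map_coordinates(self.layers[name], [row, col], order=1, mode="nearest")
        return float(out[0]) if scalar else out

    # -- I/O -------------------------------------------------------------

    def write_dir(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(
                directory / f"{name}.asc", arr, self.x_origin, self.y_origin,
                self.cell_size, self.nodata,
            )
        meta = {
            "layers": self.names,
            "crs": self.crs,
            "scenario": self.scenario,
            "cell_size": self.cell_size,
            "nodata": self.nodata,
        }
        (directory / "stack.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def read_dir(cls, directory) -> "EnvRasterStack":
        directory = Path(directory)
        meta = json.loads((directory / "stack.json").read_text())
        layers, x0, y0, cs = {}, None, None, None
        for name in meta["layers"]:
            arr, x0, y0, cs, _ = read_ascii_grid(directory / f"{name}.asc")
            layers[name] = arr
        return cls(
            layers=layers, x_origin=x0, y_origin=y0, cell_size=cs,
            crs=meta["crs"], scenario=meta["scenario"], nodata=meta["nodata"],
        )


def write_ascii_grid(path, arr: np.ndarray, x0: float, y0: float, cell: float,
                     nodata: float = NODATA) -> None:
    arr = np.asarray(arr, float)
    nr, nc = arr.shape
    body = "\n".join(
        " ".join(f"{v:.10g}" for v in row) for row in np.flipud(arr)  # north first
    )
    Path(path).write_text(
        f"ncols {nc}\nnrows {nr}\nxllcorner {x0:.10g}\nyllcorner {y0:.10g}\n"
        f"cellsize {cell:.10g}\nNODATA_value {nodata:.10g}\n{body}\n"
    )


def read_ascii_grid(path):
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        k, v = lines[i].split()
        hdr[k.lower()] = float(v)
        i += 1
    arr = np.loadtxt(lines[i:]).reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    arr = np.flipud(arr)  # back to south-first rows
    return (
        arr, hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"],
        hdr.get("nodata_value", NODATA),
    )


@dataclass
class RegionMask:
    grid: np.ndarray  # boolean, same shape as the stack's layers
    polygon: object | None = None

    def __post_init__(self):
        if not self.grid.any():
            raise ValueError("mask contains no cells")

    @classmethod
    def full(cls, stack: EnvRasterStack) -> "RegionMask":
        return cls(grid=np.ones(stack.shape, dtype=bool))

    @classmethod
    def from_polygon(cls, polygon, stack: EnvRasterStack) -> "RegionMask":
        """Rasterize a shapely polygon (in the stack CRS) by cell-centre test."""
        xs, ys = stack.cell_centers()
        inside = shapely.contains_xy(polygon, xs.ravel(), ys.ravel())
        return cls(grid=inside.reshape(stack.shape), polygon=polygon)

    @classmethod
    def from_geojson(cls, path, stack: EnvRasterStack) -> "RegionMask":
        doc = json.loads(Path(path).read_text())
        if doc.get("type") == "FeatureCollection":
            geom = shape(doc["features"][0]["geometry"])
        elif doc.get("type") == "Feature":
            geom = shape(doc["geometry"])
        else:
            geom = shape(doc)
        return cls.from_polygon(geom, stack)

    def contains_point(self, stack: EnvRasterStack, x: float, y: float) -> bool:
        col = int((x - stack.x_origin) / stack.cell_size)
        row = int((y - stack.y_origin) / stack.cell_size)
        nr, nc = self.grid.shape
        return 0 <= row < nr and 0 <= col < nc and bool(self.grid[row, col])
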