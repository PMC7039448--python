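"""Grid geometry, raster containers and plain-format raster I/O.

All rasters in the package share one planar-meter geometry convention:
``x_origin``/``y_origin`` is the *top-left corner* of the grid, columns run
east (+x) and rows run south (-y).  Cell (row, col) has its center at
``(x_origin + (col + 0.5) * cell_size_m, y_origin - (row + 0.5) * cell_size_m)``.

Two on-disk formats are supported: ESRI ASCII grid (text, written with the
conventional lower-left-corner header) and single-band GeoTIFF carrying the
minimal georeferencing tags (ModelPixelScale + ModelTiepoint).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

ASCII_NODATA = -9999.0

#: GeoTIFF tag codes for pixel scale and the (0,0) tie point.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922

SCALE_0_1000 = "0-1000"
SCALE_0_1 = "0-1"


@dataclass(frozen=True)
class GridGeometry:
    """Shape, resolution and placement of a raster grid (planar meters)."""

    n_rows: int
    n_cols: int
    cell_size_m: float
    x_origin: float = 0.0
    y_origin: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("zero-sized raster: n_rows and n_cols must be positive")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def width_m(self) -> float:
        return self.n_cols * self.cell_size_m

    @property
    def height_m(self) -> float:
        return self.n_rows * self.cell_size_m

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        cs = self.cell_size_m
        return (self.x_origin + (col + 0.5) * cs, self.y_origin - (row + 0.5) * cs)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of every cell-center coordinate, shaped like the grid."""
        cs = self.cell_size_m
        x = self.x_origin + (np.arange(self.n_cols) + 0.5) * cs
        y = self.y_origin - (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(x, y)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing planar point (x, y); no bound check."""
        cs = self.cell_size_m
        col = int(np.floor((x - self.x_origin) / cs))
        row = int(np.floor((self.y_origin - y) / cs))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        row, col = self.cell_of(x, y)
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


@dataclass
class LandCoverRaster:
    """Categorical land-cover grid: integer class codes plus a code->name map."""

    grid: np.ndarray
    class_names: dict[int, str]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int64)
        if self.grid.shape != self.geometry.shape:
            raise ValueError("grid shape does not match geometry")
        present = set(np.unique(self.grid).tolist())
        missing = present - set(self.class_names)
        if missing:
            raise ValueError(f"grid contains codes with no name: {sorted(missing)}")

    def code_of(self, name: str) -> int:
        for code, nm in self.class_names.items():
            if nm == name:
                return code
        raise KeyError(f"unknown land-cover class {name!r}")

    def mask_of(self, name: str) -> np.ndarray:
        return self.grid == self.code_of(name)

    def realized_fraction(self, name: str, where: np.ndarray | None = None) -> float:
        sel = self.mask_of(name)
        if where is not None:
            return float(sel[where].mean()) if where.any() else 0.0
        return float(sel.mean())


@dataclass
class SuitabilityRaster:
    """Continuous habitat suitability on a declared 0-1000 or 0-1 scale.

    Missing cells are NaN and survive every transformation in the chain.
    """

    grid: np.ndarray
    scale: str
    geometry: GridGeometry
    provenance: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != self.geometry.shape:
            raise ValueError("grid shape does not match geometry")
        if self.scale not in (SCALE_0_1000, SCALE_0_1):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        hi = 1000.0 if self.scale == SCALE_0_1000 else 1.0
        vals = self.grid[np.isfinite(self.grid)]
        if vals.size and (vals.min() < -1e-9 or vals.max() > hi + 1e-9):
            raise ValueError(f"values outside declared {self.scale} range")

    def copy_with(self, grid: np.ndarray, scale: str | None = None,
                  provenance: str | None = None) -> "SuitabilityRaster":
        return SuitabilityRaster(
            grid=grid, scale=self.scale if scale is None else scale,
            geometry=self.geometry,
            provenance=self.provenance if provenance is None else provenance)


@dataclass
class ResistanceRaster:
    """Per-cell traversal cost, >= 1 everywhere traversable; NaN = untraversable."""

    grid: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != self.geometry.shape:
            raise ValueError("grid shape does not match geometry")
        vals = self.grid[np.isfinite(self.grid)]
        if vals.size and vals.min() < 1.0 - 1e-9:
            raise ValueError("resistance values must be >= 1")


@dataclass
class PathDensityRaster:
    """Accumulated least-cost-path counts or resistant-kernel mass per cell."""

    grid: np.ndarray
    geometry: GridGeometry
    scenario: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != self.geometry.shape:
            raise ValueError("grid shape does not match geometry")
        vals = self.grid[np.isfinite(self.grid)]
        if vals.size and vals.min() < -1e-12:
            raise ValueError("path density must be nonnegative")


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def write_ascii_grid(path: str | Path, grid: np.ndarray, geometry: GridGeometry,
                     nodata: float = ASCII_NODATA) -> None:
    grid = np.asarray(grid, dtype=float)
    out = np.where(np.isfinite(grid), grid, nodata)
    yll = geometry.y_origin - geometry.n_rows * geometry.cell_size_m
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.x_origin!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {geometry.cell_size_m!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    with open(path) as fh:
        head: dict[str, float] = {}
        while len(head) < 5 or (len(head) == 5 and "nodata_value" not in head):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "xllcenter", "yllcenter", "nodata_value"):
                head[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    n_rows, n_cols = int(head["nrows"]), int(head["ncols"])
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"grid body {data.shape} disagrees with header "
                         f"({n_rows}, {n_cols})")
    cs = head["cellsize"]
    if "xllcorner" in head:
        x0, yll = head["xllcorner"], head["yllcorner"]
    else:  # center-registered variant
        x0, yll = head["xllcenter"] - cs / 2, head["yllcenter"] - cs / 2
    geom = GridGeometry(n_rows=n_rows, n_cols=n_cols, cell_size_m=cs,
                        x_origin=x0, y_origin=yll + n_rows * cs)
    nodata = head.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, geom


# ---------------------------------------------------------------------------
# GeoTIFF (minimal georeferencing: pixel scale + top-left tie point)
# ---------------------------------------------------------------------------

def write_geotiff(path: str | Path, grid: np.ndarray, geometry: GridGeometry) -> None:
    cs = geometry.cell_size_m
    scale = (cs, cs, 0.0)
    tiepoint = (0.0, 0.0, 0.0, geometry.x_origin, geometry.y_origin, 0.0)
    tifffile.imwrite(
        str(path), np.asarray(grid),
        extratags=[(_TAG_PIXEL_SCALE, "d", 3, scale, True),
                   (_TAG_TIEPOINT, "d", 6, tiepoint, True)])


def read_geotiff(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        grid = page.asarray()
        tags = {t.code: t.value for t in page.tags.values()}
    try:
        sx = tags[_TAG_PIXEL_SCALE][0]
        tp = tags[_TAG_TIEPOINT]
    except KeyError as exc:
        raise ValueError(f"{path}: missing GeoTIFF georeferencing tags") from exc
    geom = GridGeometry(n_rows=grid.shape[0], n_cols=grid.shape[1],
                        cell_size_m=float(sx), x_origin=float(tp[3]),
                        y_origin=float(tp[4]))
    return np.asarray(grid), geom


def write_landcover(raster: LandCoverRaster, path: str | Path,
                    fmt: str = "ascii") -> None:
    """Write a land-cover raster plus a ``<path>.classes.json`` code map."""
    path = Path(path)
    if fmt == "ascii":
        write_ascii_grid(path, raster.grid.astype(float), raster.geometry)
    elif fmt == "geotiff":
        write_geotiff(path, raster.grid.astype(np.int32), raster.geometry)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")
    sidecar = path.with_suffix(path.suffix + ".classes.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in raster.class_names.items()},
                                  indent=0, sort_keys=True))


def read_landcover(path: str | Path, fmt: str = "ascii") -> LandCoverRaster:
    path = Path(path)
    if fmt == "ascii":
        grid, geom = read_ascii_grid(path)
    elif fmt == "geotiff":
        grid, geom = read_geotiff(path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")
    sidecar = path.with_suffix(path.suffix + ".classes.json")
    names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return LandCoverRaster(grid=np.asarray(grid, dtype=np.int64),
                           class_names=names, geometry=geom)
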