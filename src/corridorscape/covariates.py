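"""Buffer fractional-cover covariates and collinearity screening.

A covariate is the fraction of a fixed-radius buffer occupied by one
land-cover class. The cell-inclusion rule is declared and exact: a cell
belongs to the buffer iff its *center* lies within ``radius_m`` of the
point. With cells much smaller than the buffer this converges to the
area-weighted fraction, and it is exactly reproducible by brute-force cell
enumeration, which the tests exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import convolve

from .rasters import LandCoverRaster
from .synthetic import CLASS_CODES, CLASS_NAMES, OccurrenceSet

#: Non-covariate columns of a covariate table.
META_COLUMNS = ("label", "study_area")


def covariate_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def area_classes(area: str, exclusive_classes: dict[str, str],
                 classes: tuple[str, ...] = CLASS_NAMES) -> list[str]:
    """Model covariates for one study area: all classes except the other
    areas' exclusive covers (e.g. the plain table keeps rice paddies but
    lacks vineyards)."""
    return [c for c in classes
            if exclusive_classes.get(c) in (None, area)]


def _disc_offsets(radius_m: float, cell_size_m: float) -> np.ndarray:
    """Boolean kernel of cell offsets whose center-to-center distance from
    the kernel center is <= radius_m."""
    k = int(np.floor(radius_m / cell_size_m))
    d = np.arange(-k, k + 1)
    dj, di = np.meshgrid(d, d)
    return (np.hypot(di, dj) * cell_size_m) <= radius_m + 1e-12


def fractional_cover(landcover: LandCoverRaster, point: tuple[float, float],
                     radius_m: float, class_code: int) -> float:
    """Fraction of in-buffer cells (centers within radius of the point)
    carrying ``class_code``; cells outside the raster do not count."""
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    x, y = point
    geom = landcover.geometry
    if not geom.contains(x, y):
        raise ValueError(f"point ({x}, {y}) is outside the raster")
    cs = geom.cell_size_m
    r0, c0 = geom.cell_of(x, y)
    k = int(np.ceil(radius_m / cs)) + 1
    rows = np.arange(max(0, r0 - k), min(geom.n_rows, r0 + k + 1))
    cols = np.arange(max(0, c0 - k), min(geom.n_cols, c0 + k + 1))
    cx = geom.x_origin + (cols + 0.5) * cs
    cy = geom.y_origin - (rows + 0.5) * cs
    dist = np.hypot(cx[None, :] - x, cy[:, None] - y)
    inside = dist <= radius_m + 1e-12
    total = int(inside.sum())
    if total == 0:
        raise ValueError("buffer contains no cell centers; increase radius_m")
    sub = landcover.grid[np.ix_(rows, cols)]
    return float((sub[inside] == class_code).sum()) / total


def cover_stack(landcover: LandCoverRaster, radius_m: float,
                classes: list[str] | None = None) -> np.ndarray:
    """Per-cell-center fractional covers for every class, via exact disc
    convolution — identical to calling :func:`fractional_cover` at every cell
    center (counts of 0/1 integers, so no floating-point drift)."""
    if classes is None:
        classes = list(CLASS_NAMES)
    kernel = _disc_offsets(radius_m, landcover.geometry.cell_size_m).astype(float)
    denom = convolve(np.ones(landcover.grid.shape), kernel,
                     mode="constant", cval=0.0)
    out = np.empty((len(classes),) + landcover.grid.shape)
    for k, cls in enumerate(classes):
        onehot = (landcover.grid == CLASS_CODES[cls]).astype(float)
        out[k] = convolve(onehot, kernel, mode="constant", cval=0.0) / denom
    return out


def build_covariate_table(landcover: LandCoverRaster,
                          occurrences: OccurrenceSet, radius_m: float,
                          classes: list[str] | None = None) -> pd.DataFrame:
    """One covariate row per occurrence record, fixed column order.

    Raises on the first off-raster point, reporting its row index.
    """
    if classes is None:
        classes = list(CLASS_NAMES)
    codes = [CLASS_CODES[c] for c in classes]
    rows = []
    for i, rec in occurrences.records.iterrows():
        if not landcover.geometry.contains(rec["x"], rec["y"]):
            raise ValueError(f"occurrence row {i} at ({rec['x']}, {rec['y']}) "
                             "is off the raster")
        pt = (rec["x"], rec["y"])
        rows.append([fractional_cover(landcover, pt, radius_m, code)
                     for code in codes])
    table = pd.DataFrame(rows, columns=classes, dtype=float)
    table["label"] = occurrences.records["label"].to_numpy() if rows else \
        pd.Series(dtype=object)
    table["study_area"] = occurrences.records["study_area"].to_numpy() if rows \
        else pd.Series(dtype=object)
    return table


@dataclass
class CollinearityReport:
    """Pairwise Pearson correlations of covariates, with |r| > threshold
    flagged and zero-variance columns excluded from pairing."""

    pairs: pd.DataFrame      # columns: class_a, class_b, pearson_r
    flagged: pd.DataFrame    # subset with |r| > threshold
    threshold: float
    zero_variance: list[str]

    def to_csv(self, path: str | Path) -> None:
        out = self.pairs.copy()
        out["flagged"] = out["pearson_r"].abs() > self.threshold
        out.to_csv(path, index=False)


def collinearity_screen(table: pd.DataFrame,
                        threshold: float = 0.60) -> CollinearityReport:
    cols = covariate_columns(table)
    if len(table) < 3:
        raise ValueError("need at least 3 rows to screen correlations")
    if len(cols) < 2:
        raise ValueError("need at least 2 covariate columns")
    X = table[cols].to_numpy(dtype=float)
    spread = X.max(axis=0) - X.min(axis=0)
    zero_var = [c for c, s in zip(cols, spread) if s == 0.0]
    if zero_var:
        warnings.warn(f"zero-variance covariates excluded from screen: "
                      f"{zero_var}")
    keep = [c for c in cols if c not in zero_var]
    recs = []
    for a, b in combinations(keep, 2):
        xa = table[a].to_numpy(dtype=float)
        xb = table[b].to_numpy(dtype=float)
        xa = xa - xa.mean()
        xb = xb - xb.mean()
        r = float((xa @ xb) / np.sqrt((xa @ xa) * (xb @ xb)))
        recs.append((a, b, r))
    pairs = pd.DataFrame(recs, columns=["class_a", "class_b", "pearson_r"])
    flagged = pairs[pairs["pearson_r"].abs() > threshold].reset_index(drop=True)
    return CollinearityReport(pairs=pairs, flagged=flagged,
                              threshold=threshold, zero_variance=zero_var)
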