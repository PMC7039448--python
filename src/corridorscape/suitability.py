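"""Landscape-wide suitability projection, merging and normalisation.

The two area ensembles are projected over the whole landscape on the
declared 0-1000 scale, area-exclusive covers are zeroed in the map of the
area that never sees them, the two maps are merged by per-pixel maximum,
and the merged map is normalised to 0-1 by dividing by the fixed 1000
ceiling (not by the observed maximum, which would let the empirical range
redefine the scale and break comparability between maps).
"""

from __future__ import annotations

import numpy as np

from .covariates import cover_stack
from .rasters import (SCALE_0_1, SCALE_0_1000, LandCoverRaster,
                      SuitabilityRaster)


def project(model, landcover: LandCoverRaster, radius_m: float,
            provenance: str = "") -> SuitabilityRaster:
    """Predict suitability at every cell from its buffer fractional covers,
    scaled to 0-1000. ``model`` is an :class:`~corridorscape.sdm.EnsembleModel`
    or a single fit; its covariate columns must all be landscape classes."""
    columns = (model.members[0].columns if hasattr(model, "members")
               else model.columns)
    known = set(landcover.class_names.values())
    missing = [c for c in columns if c not in known]
    if missing:
        raise ValueError(f"model covariates not in the landscape: {missing}")
    covers = cover_stack(landcover, radius_m, list(columns))
    X = covers.reshape(len(columns), -1).T
    p = np.asarray(model.predict(X), dtype=float)
    grid = np.clip(p, 0.0, 1.0).reshape(landcover.grid.shape) * 1000.0
    return SuitabilityRaster(grid=grid, scale=SCALE_0_1000,
                             geometry=landcover.geometry,
                             provenance=provenance)


def mask_exclusive_covers(suit: SuitabilityRaster, landcover: LandCoverRaster,
                          excluded_classes: list[str]) -> SuitabilityRaster:
    """Zero the suitability of cells whose land cover was never a covariate
    of this map's model (e.g. vineyards in the plain-area map)."""
    if suit.geometry != landcover.geometry:
        raise ValueError("geometry mismatch between suitability and land cover")
    grid = suit.grid.copy()
    for cls in excluded_classes:
        grid[landcover.mask_of(cls)] = 0.0  # raises KeyError on unknown class
    return suit.copy_with(grid=grid)


def merge_max(a: SuitabilityRaster, b: SuitabilityRaster) -> SuitabilityRaster:
    """Per-pixel maximum of two same-geometry, same-scale maps."""
    if a.geometry != b.geometry:
        raise ValueError("geometry mismatch")
    if a.scale != b.scale:
        raise ValueError("scale mismatch")
    return a.copy_with(grid=np.fmax(a.grid, b.grid),
                       provenance=f"max({a.provenance},{b.provenance})")


def normalize(suit: SuitabilityRaster) -> SuitabilityRaster:
    """0-1000 -> 0-1 by division by the declared 1000 ceiling."""
    if suit.scale != SCALE_0_1000:
        raise ValueError("normalize expects a 0-1000 scaled raster")
    return suit.copy_with(grid=suit.grid / 1000.0, scale=SCALE_0_1)


def suitable_fraction(suit: SuitabilityRaster, threshold: float = 0.5) -> float:
    """Percent of non-missing cells with suitability strictly above the
    threshold (occurrence probability higher than 0.5 by default)."""
    if suit.scale != SCALE_0_1:
        raise ValueError("suitable_fraction expects a 0-1 scaled raster")
    valid = np.isfinite(suit.grid)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("all-missing raster")
    return 100.0 * float((suit.grid[valid] > threshold).sum()) / n
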