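"""Synthetic landscapes and virtual-species occurrence data.

The generator emulates the structure the downstream analysis assumes: a
three-stratum landscape (a forested massif in the north, an intensively
cultivated central plain, vineyard-and-woodland hills in the south), two
rectangular study sub-areas with partly disjoint land-cover class sets
(rice paddies only in the plain sub-area, vineyards only in the hills
sub-area), one or more north-south rivers crossing the plain, presence
points drawn from a known logistic function of 100-m fractional covers, and
uniformly random pseudo-absence points per sub-area.

Patch structure comes from smoothed independent Gaussian fields, one per
land-cover class: within each stratum every field is rank-transformed to
Uniform(0,1) and the cell takes the class minimising ``-log(u) / target
fraction`` — independent Exponential(rate = fraction) races, so each cell's
marginal class probability equals its target fraction exactly, while the
smoothing scale controls patch size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from scipy.stats import rankdata

from .rasters import GridGeometry, LandCoverRaster

PRESENCE = "presence"
PSEUDO_ABSENCE = "pseudo_absence"

#: The nine land-cover classes used throughout, in fixed code order.
CLASS_NAMES: tuple[str, ...] = (
    "urban", "arable", "rice_paddies", "vineyards", "complex_cultivations",
    "meadows", "transitional_woodland", "woodland", "water")
CLASS_CODES: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}

TICINO = "ticino"      # plain sub-area analogue (rice paddies exclusive)
APENNINE = "apennine"  # hills sub-area analogue (vineyards exclusive)

DEFAULT_STRATA: tuple[tuple[str, float], ...] = (
    ("north_massif", 1 / 3), ("central_plain", 1 / 3), ("south_hills", 1 / 3))

DEFAULT_CLASS_MIX: dict[str, dict[str, float]] = {
    "north_massif": {"woodland": 0.55, "transitional_woodland": 0.15,
                     "meadows": 0.15, "urban": 0.03, "arable": 0.07,
                     "water": 0.05},
    "central_plain": {"arable": 0.55, "rice_paddies": 0.15, "urban": 0.12,
                      "complex_cultivations": 0.08, "woodland": 0.05,
                      "meadows": 0.03, "water": 0.02},
    "south_hills": {"woodland": 0.30, "vineyards": 0.25, "arable": 0.15,
                    "complex_cultivations": 0.10,
                    "transitional_woodland": 0.10, "meadows": 0.05,
                    "urban": 0.05},
}

DEFAULT_EXCLUSIVE: dict[str, str] = {"rice_paddies": TICINO,
                                     "vineyards": APENNINE}

#: Sub-area rectangles: name -> (stratum, col_lo_frac, col_hi_frac).
DEFAULT_SUBAREAS: dict[str, tuple[str, float, float]] = {
    TICINO: ("central_plain", 0.35, 0.75),
    APENNINE: ("south_hills", 0.0, 1.0),
}

#: True log-odds coefficients of the default virtual species on fractional
#: covers (signs follow wolf habitat selection: forest and riparian cover
#: favoured, open intensive agriculture and urban areas avoided).
DEFAULT_BETAS: dict[str, float] = {
    "urban": -3.0, "arable": -2.0, "rice_paddies": -3.0, "vineyards": -1.0,
    "complex_cultivations": -0.5, "meadows": 0.0,
    "transitional_woodland": 1.5, "woodland": 4.0, "water": 4.0}
DEFAULT_BETA0 = -1.5


@dataclass
class LandscapeConfig:
    width_cells: int = 64
    height_cells: int = 64
    cell_size_m: float = 100.0
    strata: tuple[tuple[str, float], ...] = DEFAULT_STRATA
    class_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(m) for s, m in DEFAULT_CLASS_MIX.items()})
    exclusive_classes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSIVE))
    subareas: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBAREAS))
    patch_scale_cells: float = 3.0
    river_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_cells <= 0 or self.height_cells <= 0:
            raise ValueError("zero-sized raster")
        if self.cell_size_m <= 0 or self.patch_scale_cells <= 0:
            raise ValueError("cell_size_m and patch_scale_cells must be positive")
        if self.river_count < 0:
            raise ValueError("river_count must be >= 0")
        if abs(sum(h for _, h in self.strata) - 1.0) > 1e-9:
            raise ValueError("stratum heights must sum to 1")
        stratum_names = [s for s, _ in self.strata]
        for stratum, mix in self.class_mix.items():
            if stratum not in stratum_names:
                raise ValueError(f"class_mix names unknown stratum {stratum!r}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"class fractions in {stratum!r} must sum to 1")
            for cls, frac in mix.items():
                if cls not in CLASS_CODES:
                    raise ValueError(f"unknown land-cover class {cls!r}")
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"fraction of {cls!r} outside [0,1]")
        for cls, area in self.exclusive_classes.items():
            if area not in self.subareas:
                raise ValueError(f"exclusive class {cls!r} names unknown "
                                 f"sub-area {area!r}")
            host = self.subareas[area][0]
            appears = [s for s, mix in self.class_mix.items() if cls in mix]
            if appears and appears != [host]:
                raise ValueError(
                    f"exclusive class {cls!r} must appear only in the mix of "
                    f"its sub-area's stratum {host!r}, found in {appears}")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(n_rows=self.height_cells, n_cols=self.width_cells,
                            cell_size_m=self.cell_size_m)


@dataclass
class VirtualSpeciesConfig:
    """True occurrence model: logistic in buffer fractional covers."""

    beta0: float = DEFAULT_BETA0
    betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETAS))
    buffer_radius_m: float = 100.0
    n_presence: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.buffer_radius_m <= 0:
            raise ValueError("buffer_radius_m must be positive")
        if self.n_presence < 0:
            raise ValueError("n_presence must be >= 0")


@dataclass
class OccurrenceSet:
    """Labelled occurrence points (presence / pseudo-absence) by sub-area."""

    records: pd.DataFrame  # columns: x, y, study_area, label

    COLUMNS = ("x", "y", "study_area", "label")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=list(self.COLUMNS))
        bad = set(df["label"].unique()) - {PRESENCE, PSEUDO_ABSENCE}
        if bad:
            raise ValueError(f"unknown occurrence labels: {sorted(bad)}")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def counts(self) -> pd.DataFrame:
        return (self.records.groupby(["study_area", "label"]).size()
                .unstack(fill_value=0))

    @staticmethod
    def concat(parts: list["OccurrenceSet"]) -> "OccurrenceSet":
        frames = [p.records for p in parts] or [pd.DataFrame(columns=list(OccurrenceSet.COLUMNS))]
        return OccurrenceSet(pd.concat(frames, ignore_index=True))

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @staticmethod
    def from_csv(path: str | Path) -> "OccurrenceSet":
        return OccurrenceSet(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def stratum_row_bounds(config: LandscapeConfig) -> dict[str, tuple[int, int]]:
    """Half-open row ranges [lo, hi) of each horizontal stratum, north first."""
    bounds, lo = {}, 0
    cum = 0.0
    for i, (name, h) in enumerate(config.strata):
        cum += h
        hi = config.height_cells if i == len(config.strata) - 1 else int(
            round(cum * config.height_cells))
        bounds[name] = (lo, hi)
        lo = hi
    return bounds


def stratum_masks(config: LandscapeConfig) -> dict[str, np.ndarray]:
    shape = (config.height_cells, config.width_cells)
    masks = {}
    for name, (lo, hi) in stratum_row_bounds(config).items():
        m = np.zeros(shape, dtype=bool)
        m[lo:hi, :] = True
        masks[name] = m
    return masks


def subarea_masks(config: LandscapeConfig) -> dict[str, np.ndarray]:
    """Rectangular study sub-area masks (stand-ins for the true polygons)."""
    rows = stratum_row_bounds(config)
    shape = (config.height_cells, config.width_cells)
    masks = {}
    for name, (stratum, lo_f, hi_f) in config.subareas.items():
        r_lo, r_hi = rows[stratum]
        c_lo = int(round(lo_f * config.width_cells))
        c_hi = int(round(hi_f * config.width_cells))
        m = np.zeros(shape, dtype=bool)
        m[r_lo:r_hi, c_lo:c_hi] = True
        masks[name] = m
    return masks


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------

def _smoothed_uniform_field(rng: np.random.Generator, shape: tuple[int, int],
                            sigma: float) -> np.ndarray:
    """Gaussian noise, isotropic smoothing, then global rank -> Uniform(0,1)."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    ranks = rankdata(z.ravel(), method="ordinal").reshape(shape)
    return (ranks - 0.5) / z.size


def generate_landscape(config: LandscapeConfig) -> LandCoverRaster:
    """Generate a categorical land-cover raster per the configured mix.

    Exclusive classes are confined to their sub-area rectangle: outside it the
    per-cell class race simply runs without them. Rivers are carved last as
    1-cell-wide connected north-south water polylines across the central
    stratum (the first river is routed through the plain sub-area so a
    riparian corridor always crosses it).
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.height_cells, config.width_cells)
    grid = np.empty(shape, dtype=np.int64)
    s_masks = stratum_masks(config)
    a_masks = subarea_masks(config)

    for stratum, _ in config.strata:
        mix = config.class_mix.get(stratum)
        if not mix:
            raise ValueError(f"no class mix for stratum {stratum!r}")
        sm = s_masks[stratum]
        classes = [c for c, f in mix.items() if f > 0]
        # score[k] = -log(u)/f_k : Exponential(rate f_k) race, argmin wins.
        score = np.full((len(classes),) + shape, np.inf)
        for k, cls in enumerate(classes):
            u = _smoothed_uniform_field(rng, shape, config.patch_scale_cells)
            s = -np.log(u) / mix[cls]
            if cls in config.exclusive_classes:
                allowed = a_masks[config.exclusive_classes[cls]]
                s = np.where(allowed, s, np.inf)
            score[k] = s
        winner = np.argmin(score, axis=0)
        codes = np.array([CLASS_CODES[c] for c in classes])
        grid[sm] = codes[winner][sm]

    # Rivers: connected 1-cell-wide north-south polylines across the plain.
    plain_rows = None
    for name, (lo, hi) in stratum_row_bounds(config).items():
        if name == "central_plain":
            plain_rows = (lo, hi)
    if plain_rows is not None and config.river_count > 0:
        lo, hi = plain_rows
        water = CLASS_CODES["water"]
        tic = config.subareas.get(TICINO)
        for i in range(config.river_count):
            if i == 0 and tic is not None:
                col = int(round((tic[1] + tic[2]) / 2 * config.width_cells))
            else:
                col = int(rng.integers(0, config.width_cells))
            for row in range(lo, hi):
                grid[row, col] = water
                col = int(np.clip(col + rng.integers(-1, 2), 0,
                                  config.width_cells - 1))

    names = {CLASS_CODES[n]: n for n in CLASS_NAMES}
    return LandCoverRaster(grid=grid, class_names=names, geometry=config.geometry)


# ---------------------------------------------------------------------------
# Occurrence sampling
# ---------------------------------------------------------------------------

def _cell_linear_predictor(landcover: LandCoverRaster,
                           vs: VirtualSpeciesConfig) -> np.ndarray:
    from .covariates import cover_stack  # local import: avoids module cycle

    present = set(landcover.class_names[c] for c in np.unique(landcover.grid))
    unknown = set(vs.betas) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"betas name unknown classes: {sorted(unknown)}")
    classes = [c for c in vs.betas if c in present or vs.betas[c] != 0.0]
    covers = cover_stack(landcover, vs.buffer_radius_m, classes)
    eta = np.full(landcover.grid.shape, float(vs.beta0))
    for k, cls in enumerate(classes):
        eta += vs.betas[cls] * covers[k]
    return eta


def true_suitability(landcover: LandCoverRaster,
                     vs: VirtualSpeciesConfig) -> np.ndarray:
    """The virtual species' true occurrence probability per cell."""
    return expit(_cell_linear_predictor(landcover, vs))


def sample_virtual_occurrences(landcover: LandCoverRaster,
                               vs: VirtualSpeciesConfig,
                               area_mask: np.ndarray,
                               area_name: str = "") -> OccurrenceSet:
    """Draw presence points, without replacement, with probability
    proportional to the true logistic suitability of each masked cell.
    Points are placed at cell centers."""
    area_mask = np.asarray(area_mask, dtype=bool)
    rows, cols = np.nonzero(area_mask)
    if vs.n_presence > rows.size:
        raise ValueError(f"n_presence={vs.n_presence} exceeds the "
                         f"{rows.size} candidate cells in the mask")
    if vs.n_presence == 0:
        return OccurrenceSet(pd.DataFrame(columns=list(OccurrenceSet.COLUMNS)))
    p = expit(_cell_linear_predictor(landcover, vs))[rows, cols]
    rng = np.random.default_rng(vs.seed)
    idx = rng.choice(rows.size, size=vs.n_presence, replace=False, p=p / p.sum())
    geom = landcover.geometry
    xy = [geom.cell_center(int(rows[i]), int(cols[i])) for i in idx]
    df = pd.DataFrame(xy, columns=["x", "y"])
    df["study_area"] = area_name
    df["label"] = PRESENCE
    return OccurrenceSet(df)


def sample_bernoulli_occurrences(landcover: LandCoverRaster,
                                 vs: VirtualSpeciesConfig,
                                 area_mask: np.ndarray, n: int, seed: int,
                                 area_name: str = "") -> OccurrenceSet:
    """Draw n cells uniformly (with replacement) from the mask and label each
    presence with its true logistic probability, else pseudo-absence.

    Unlike the presence-only sampler this yields labelled Bernoulli data under
    which the full coefficient vector (intercept included) of the generating
    logistic model is identified — the design used for parameter-recovery
    checks of the distribution models.
    """
    area_mask = np.asarray(area_mask, dtype=bool)
    rows, cols = np.nonzero(area_mask)
    if rows.size == 0 and n > 0:
        raise ValueError("empty mask")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rows.size, size=n)
    p = expit(_cell_linear_predictor(landcover, vs))[rows[idx], cols[idx]]
    labels = np.where(rng.random(n) < p, PRESENCE, PSEUDO_ABSENCE)
    geom = landcover.geometry
    xy = [geom.cell_center(int(r), int(c)) for r, c in zip(rows[idx], cols[idx])]
    df = pd.DataFrame(xy, columns=["x", "y"])
    df["study_area"] = area_name
    df["label"] = labels
    return OccurrenceSet(df)


def generate_pseudo_absences(area_mask: np.ndarray, n: int, seed: int,
                             geometry: GridGeometry,
                             area_name: str = "") -> OccurrenceSet:
    """Exactly n uniformly random points inside the mask (continuous within
    cells, cells drawn with replacement), labelled pseudo_absence."""
    if n < 0:
        raise ValueError("n must be >= 0")
    area_mask = np.asarray(area_mask, dtype=bool)
    rows, cols = np.nonzero(area_mask)
    if rows.size == 0 and n > 0:
        raise ValueError("empty mask with n > 0")
    if n == 0:
        return OccurrenceSet(pd.DataFrame(columns=list(OccurrenceSet.COLUMNS)))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rows.size, size=n)
    u, v = rng.random(n), rng.random(n)
    cs = geometry.cell_size_m
    x = geometry.x_origin + (cols[idx] + u) * cs
    y = geometry.y_origin - (rows[idx] + v) * cs
    df = pd.DataFrame({"x": x, "y": y})
    df["study_area"] = area_name
    df["label"] = PSEUDO_ABSENCE
    return OccurrenceSet(df)
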