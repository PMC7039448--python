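"""Resistance surfaces, source selection, least-cost paths and kernels.

Suitability h in [0, 1] becomes traversal resistance through a negative
exponential, R(h) = r_max^(1-h): fully suitable cells cost 1, fully
unsuitable cells cost r_max (default 100), and most of the landscape sits
at low resistance — the flexibility that motivates exponential over linear
conversion for a highly mobile species.

The cost substrate is the standard 8-neighbour raster graph: the edge
between adjacent cells i, j costs ``cell_size * (R_i + R_j) / 2``, times
sqrt(2) for diagonal moves; NaN (untraversable) cells carry no edges.
Synoptic connectivity is then measured two ways: factorial least-cost
paths (one path per source pair within the dispersal threshold, summed
into a path-density raster) and cumulative resistant kernels (a Gaussian
kernel of cost distance around each source, truncated at the dispersal
threshold D, with bandwidth sigma = D / 3, summed over sources).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .rasters import (SCALE_0_1, GridGeometry, PathDensityRaster,
                      ResistanceRaster, SuitabilityRaster)

SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class ResistanceParams:
    r_max: float = 100.0
    form: str = "negative-exponential"

    def __post_init__(self) -> None:
        if self.r_max <= 1.0:
            raise ValueError("r_max must exceed 1")
        if self.form != "negative-exponential":
            raise ValueError(f"unknown resistance form {self.form!r}")


@dataclass(frozen=True)
class DispersalScenario:
    """Euclidean dispersal-distance threshold; the study's two scenarios are
    100 km (low dispersal ability) and 850 km (high)."""

    name: str
    threshold_km: float

    def __post_init__(self) -> None:
        if self.threshold_km <= 0:
            raise ValueError("threshold_km must be positive")


LOW_DISPERSAL = DispersalScenario("low", 100.0)
HIGH_DISPERSAL = DispersalScenario("high", 850.0)


def suitability_to_resistance(suit: SuitabilityRaster,
                              params: ResistanceParams = ResistanceParams()
                              ) -> ResistanceRaster:
    """R(h) = r_max^(1-h); strictly decreasing, R(1)=1, R(0)=r_max.
    NaN suitability stays NaN (untraversable)."""
    if suit.scale != SCALE_0_1:
        raise ValueError("resistance conversion expects a 0-1 scaled raster")
    h = suit.grid
    finite = np.isfinite(h)
    if finite.any() and (np.nanmin(h) < -1e-12 or np.nanmax(h) > 1 + 1e-12):
        raise ValueError("suitability outside [0, 1]")
    grid = np.power(params.r_max, 1.0 - np.clip(h, 0.0, 1.0))
    grid[~finite] = np.nan
    return ResistanceRaster(grid=grid, geometry=suit.geometry)


# ---------------------------------------------------------------------------
# Source selection
# ---------------------------------------------------------------------------

@dataclass
class SourceSet:
    """Source locations: centroids of qualifying selection-grid cells."""

    points: pd.DataFrame  # columns: x, y, source_cell_id, stratum

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)

    def to_unicor_xy(self, path) -> None:
        """UNICOR-style XY point file: one 'x y' pair per line."""
        with open(path, "w") as fh:
            fh.write("XCOORD,YCOORD\n")
            for _, r in self.points.iterrows():
                fh.write(f"{r['x']},{r['y']}\n")


def select_sources(suit: SuitabilityRaster, grid_size_m: float = 1000.0,
                   threshold: float = 0.5,
                   strata_masks: dict[str, np.ndarray] | None = None,
                   rarefy_stratum: str | None = None,
                   rarefy_dist_m: float = 5000.0) -> SourceSet:
    """Overlay a selection grid and keep the centroid of every grid cell
    containing at least one pixel with suitability strictly above the
    threshold. Within ``rarefy_stratum`` the qualifying centroids are
    thinned to one per ``rarefy_dist_m`` square block, keeping the centroid
    whose cell has the highest max suitability (ties: lowest row, then
    column) — emulating sporadic occupancy.
    """
    if suit.scale != SCALE_0_1:
        raise ValueError("select_sources expects a 0-1 scaled raster")
    geom = suit.geometry
    k = grid_size_m / geom.cell_size_m
    if k <= 0 or abs(k - round(k)) > 1e-9:
        raise ValueError("grid_size_m must be a positive multiple of the "
                         "raster cell size")
    k = int(round(k))
    nbr = int(np.ceil(geom.n_rows / k))
    nbc = int(np.ceil(geom.n_cols / k))
    recs = []  # (block_row, block_col, x, y, id, stratum, max_suit)
    for bi in range(nbr):
        for bj in range(nbc):
            r0, r1 = bi * k, min((bi + 1) * k, geom.n_rows)
            c0, c1 = bj * k, min((bj + 1) * k, geom.n_cols)
            block = suit.grid[r0:r1, c0:c1]
            if not np.any(block > threshold):
                continue
            # centroid of the (possibly edge-clipped) block extent
            x = geom.x_origin + (c0 + c1) / 2 * geom.cell_size_m
            y = geom.y_origin - (r0 + r1) / 2 * geom.cell_size_m
            stratum = ""
            if strata_masks:
                rc, cc = geom.cell_of(x, y)
                rc = min(rc, geom.n_rows - 1)
                cc = min(cc, geom.n_cols - 1)
                for name, m in strata_masks.items():
                    if m[rc, cc]:
                        stratum = name
                        break
            recs.append((bi, bj, x, y, bi * nbc + bj, stratum,
                         float(np.nanmax(block))))
    if rarefy_stratum is not None:
        keep, best = [], {}
        for rec in recs:
            bi, bj, x, y, _, stratum, mx = rec
            if stratum != rarefy_stratum:
                keep.append(rec)
                continue
            sb = (int((suit.geometry.y_origin - y) // rarefy_dist_m),
                  int((x - suit.geometry.x_origin) // rarefy_dist_m))
            cur = best.get(sb)
            # higher max suitability wins; ties -> lowest row then column
            if cur is None or mx > cur[6] or (
                    mx == cur[6] and (bi, bj) < (cur[0], cur[1])):
                best[sb] = rec
        recs = keep + [best[s] for s in sorted(best)]
        recs.sort(key=lambda r: (r[0], r[1]))
    df = pd.DataFrame([(x, y, sid, stratum)
                       for _, _, x, y, sid, stratum, _ in recs],
                      columns=["x", "y", "source_cell_id", "stratum"])
    return SourceSet(points=df)


# ---------------------------------------------------------------------------
# Cost graph and shortest paths
# ---------------------------------------------------------------------------

@dataclass
class CostGraph:
    """8-neighbour cost graph over a resistance raster. Node ids are linear
    cell indices ``row * n_cols + col``; untraversable cells are isolated."""

    matrix: csr_matrix
    geometry: GridGeometry
    traversable: np.ndarray

    def node_of(self, row: int, col: int) -> int:
        return row * self.geometry.n_cols + col

    def cell_of_node(self, node: int) -> tuple[int, int]:
        return divmod(node, self.geometry.n_cols)

    def node_of_point(self, x: float, y: float) -> int:
        r, c = self.geometry.cell_of(x, y)
        r = int(np.clip(r, 0, self.geometry.n_rows - 1))
        c = int(np.clip(c, 0, self.geometry.n_cols - 1))
        return self.node_of(r, c)


_OFFSETS = ((0, 1, 1.0), (1, 0, 1.0), (1, 1, SQRT2), (1, -1, SQRT2))


def build_cost_graph(res: ResistanceRaster, neighborhood: int = 8) -> CostGraph:
    """Undirected graph: weight(i, j) = cell_size * (R_i + R_j) / 2, with the
    sqrt(2) diagonal factor under the 8-neighbourhood."""
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    R = res.grid
    nr, nc = R.shape
    cs = res.geometry.cell_size_m
    trav = np.isfinite(R)
    if not trav.any():
        raise ValueError("no traversable cells")
    rows_i, cols_j, weights = [], [], []
    offsets = _OFFSETS if neighborhood == 8 else _OFFSETS[:2]
    for dr, dc, mult in offsets:
        r0 = slice(max(0, -dr), nr - max(0, dr))
        r1 = slice(max(0, dr), nr - max(0, -dr))
        c0 = slice(max(0, -dc), nc - max(0, dc))
        c1 = slice(max(0, dc), nc - max(0, -dc))
        ok = trav[r0, c0] & trav[r1, c1]
        w = cs * mult * (R[r0, c0] + R[r1, c1]) / 2.0
        ii = (np.arange(nr)[r0][:, None] * nc + np.arange(nc)[c0][None, :])
        jj = (np.arange(nr)[r1][:, None] * nc + np.arange(nc)[c1][None, :])
        rows_i.append(ii[ok])
        cols_j.append(jj[ok])
        weights.append(w[ok])
    i = np.concatenate(rows_i)
    j = np.concatenate(cols_j)
    w = np.concatenate(weights)
    n = nr * nc
    mat = csr_matrix((np.concatenate([w, w]),
                      (np.concatenate([i, j]), np.concatenate([j, i]))),
                     shape=(n, n))
    return CostGraph(matrix=mat, geometry=res.geometry, traversable=trav)


def cost_distance(graph: CostGraph, source_cell: int) -> np.ndarray:
    """Exact single-source Dijkstra costs from a linear cell index, reshaped
    to the raster grid; unreachable cells are +inf."""
    r, c = graph.cell_of_node(source_cell)
    if not graph.traversable[r, c]:
        raise ValueError("source cell is untraversable")
    d = dijkstra(graph.matrix, directed=False, indices=source_cell)
    return d.reshape(graph.geometry.shape)


def _walk_back(graph: CostGraph, dist_flat: np.ndarray, src: int,
               dst: int) -> list[int]:
    """Reconstruct one minimum-cost path by walking from dst toward src,
    choosing at each step the lowest-linear-index neighbour that lies on an
    optimal path (bit-reproducible tie rule)."""
    mat = graph.matrix
    path = [dst]
    cur = dst
    while cur != src:
        lo, hi = mat.indptr[cur], mat.indptr[cur + 1]
        nbrs = mat.indices[lo:hi]
        wts = mat.data[lo:hi]
        tot = dist_flat[nbrs] + wts
        strict = dist_flat[nbrs] < dist_flat[cur]
        tol = 1e-9 * max(1.0, abs(dist_flat[cur]))
        ok = strict & (tot <= tot[strict].min() + tol) & (
            tot <= dist_flat[cur] + tol)
        cand = nbrs[ok]
        if cand.size == 0:
            raise RuntimeError("path reconstruction failed")
        cur = int(cand.min())
        path.append(cur)
    path.reverse()
    return path


def least_cost_path(graph: CostGraph, src: int, dst: int
                    ) -> tuple[list[int], float]:
    """One minimum-cost path (ordered linear cell indices) and its cost."""
    dist = cost_distance(graph, src).ravel()
    if not np.isfinite(dist[dst]):
        raise ValueError("destination unreachable from source")
    if src == dst:
        return [src], 0.0
    return _walk_back(graph, dist, src, dst), float(dist[dst])


# ---------------------------------------------------------------------------
# Factorial least-cost paths and resistant kernels
# ---------------------------------------------------------------------------

def _source_nodes(graph: CostGraph, sources: SourceSet) -> np.ndarray:
    nodes = [graph.node_of_point(x, y)
             for x, y in zip(sources.points["x"], sources.points["y"])]
    return np.asarray(nodes, dtype=int)


def factorial_lcp(res: ResistanceRaster, sources: SourceSet,
                  scenario: DispersalScenario,
                  distance_filter: str = "euclidean"
                  ) -> tuple[PathDensityRaster, pd.DataFrame]:
    """Accumulate one least-cost path per unordered source pair whose
    separation is within the scenario threshold (Euclidean separation by
    default; ``distance_filter="cost"`` filters on cost distance instead).
    Returns the path-density raster and a report of skipped pairs."""
    if len(sources) == 0:
        raise ValueError("empty SourceSet")
    graph = build_cost_graph(res)
    nodes = _source_nodes(graph, sources)
    pts = sources.points[["x", "y"]].to_numpy(dtype=float)
    ids = sources.points["source_cell_id"].to_numpy()
    density = np.zeros(res.geometry.shape)
    skipped = []
    thr = scenario.threshold_km * 1000.0
    # one Dijkstra per source, reused across all its pairs
    dists = {}
    for a in range(len(nodes)):
        if not graph.traversable[graph.cell_of_node(nodes[a])]:
            continue
        dists[a] = dijkstra(graph.matrix, directed=False,
                            indices=int(nodes[a]))
    flat = density.ravel()
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            eucl = float(np.hypot(*(pts[a] - pts[b])))
            if a not in dists or b not in dists:
                skipped.append((ids[a], ids[b], "untraversable endpoint"))
                continue
            sep = eucl if distance_filter == "euclidean" else \
                float(dists[a][nodes[b]])
            if sep > thr:
                continue
            if not np.isfinite(dists[a][nodes[b]]):
                skipped.append((ids[a], ids[b], "unreachable"))
                continue
            if nodes[a] == nodes[b]:
                flat[nodes[a]] += 1.0
                continue
            path = _walk_back(graph, dists[a], int(nodes[a]), int(nodes[b]))
            flat[path] += 1.0
    report = pd.DataFrame(skipped, columns=["source_a", "source_b", "reason"])
    return (PathDensityRaster(grid=density, geometry=res.geometry,
                              scenario=scenario.name), report)


def resistant_kernel(res: ResistanceRaster, sources: SourceSet,
                     scenario: DispersalScenario,
                     sigma_m: float | None = None) -> PathDensityRaster:
    """Cumulative resistant Gaussian kernel: per source s,
    k_s(c) = exp(-d_cost(s,c)^2 / (2 sigma^2)) where d_cost <= D, else 0,
    summed over sources. D = threshold_km * 1000 (cost distance is in
    distance-equivalent meters: on uniform R = 1 it equals path length);
    sigma defaults to D / 3, so truncation at D removes under 1.2% of the
    kernel mass."""
    if len(sources) == 0:
        raise ValueError("empty SourceSet")
    graph = build_cost_graph(res)
    nodes = _source_nodes(graph, sources)
    D = scenario.threshold_km * 1000.0
    sigma = D / 3.0 if sigma_m is None else sigma_m
    total = np.zeros(res.geometry.shape).ravel()
    for node in nodes:
        if not graph.traversable[graph.cell_of_node(int(node))]:
            continue
        d = dijkstra(graph.matrix, directed=False, indices=int(node),
                     limit=D)
        inside = np.isfinite(d) & (d <= D)
        total[inside] += np.exp(-d[inside] ** 2 / (2.0 * sigma ** 2))
    return PathDensityRaster(grid=total.reshape(res.geometry.shape),
                             geometry=res.geometry, scenario=scenario.name)


def connectivity_extent(density: PathDensityRaster,
                        threshold: float = 0.0) -> float:
    """Percent of non-missing cells with density strictly above threshold."""
    valid = np.isfinite(density.grid)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("all-missing raster")
    return 100.0 * float((density.grid[valid] > threshold).sum()) / n
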