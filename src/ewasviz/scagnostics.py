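"""Graph-theoretic scatterplot diagnostics (scagnostics).

Nine measures in [0, 1] summarise the shape of a 2-D point cloud —
outlying, skewed, clumpy, sparse, striated, convex, skinny, stringy and
monotonic — computed from the Euclidean minimum spanning tree, the convex
hull and the alpha hull of the points after min-max normalisation to the
unit square.  In this package they rank trait-methylation scatters so
that, among hundreds of screened traits, the ones whose strongest scatter
looks structured (monotone, clumped, striated...) can be triaged for
visual inspection.

Geometry conventions, all configurable:

* points are deduplicated, then hex-binned to at most ``max_bins`` bin
  centroids when more than ``max_bins`` points remain;
* outlying points are MST leaves whose incident edges all exceed
  q75 + 1.5 * IQR of MST edge lengths; they are pruned before the shape
  measures are computed;
* the alpha radius is the 90th percentile of MST edge lengths; the alpha
  hull is the union of Delaunay triangles with circumradius <= alpha.

``monotonic`` is the squared Spearman rank correlation of the original
(unbinned) points, with average ranks for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree as _csgraph_mst
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import Polygon
from shapely.ops import unary_union

from ewasviz.io_model import BetaMatrix, EwasResultTable, TraitTable

logger = logging.getLogger("ewasviz")

MEASURE_NAMES = ("outlying", "skewed", "clumpy", "sparse", "striated",
                 "convex", "skinny", "stringy", "monotonic")

#: default cap on binned points; hex binning engages above this count
DEFAULT_MAX_BINS = 250
#: IQR multiplier for the MST outlier cut
OUTLIER_IQR_FACTOR = 1.5
#: percentile of MST edge lengths used as the alpha radius
ALPHA_PERCENTILE = 90.0
#: cosine threshold below which a degree-2 vertex counts as striated
STRIATED_COS = -0.75


@dataclass(frozen=True)
class ScagnosticsProfile:
    """The nine measures for one scatter, each in [0, 1]."""

    outlying: float
    skewed: float
    clumpy: float
    sparse: float
    striated: float
    convex: float
    skinny: float
    stringy: float
    monotonic: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def mst_edges(points: np.ndarray) -> list[tuple[int, int, float]]:
    """Euclidean minimum spanning tree as (i, j, weight) edges.

    Computed over the complete distance graph; with distinct points the
    result is the unique-weight MST used by every measure below.
    """
    n = len(points)
    if n < 2:
        return []
    dist = squareform(pdist(points))
    tree = _csgraph_mst(csr_matrix(dist)).tocoo()
    return [(int(i), int(j), float(w))
            for i, j, w in zip(tree.row, tree.col, tree.data)]


def _normalize_unit_square(x: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Min-max scale both axes to [0, 1]; None when an axis is constant."""
    rx, ry = np.ptp(x), np.ptp(y)
    if rx == 0 or ry == 0:
        return None
    return np.column_stack([(x - x.min()) / rx, (y - y.min()) / ry])


def _hex_bin(points: np.ndarray, max_bins: int,
             rng: np.random.Generator) -> np.ndarray:
    """Reduce a large cloud to at most ``max_bins`` hex-bin centroids.

    A pointy-top hexagonal lattice over the unit square; each non-empty
    bin is replaced by the centroid of its members.  The grid resolution
    is shrunk until the non-empty bin count fits.  Deterministic; the
    generator is accepted for interface stability of seeded binning.
    """
    del rng  # binning is deterministic; no jitter applied
    n_side = int(np.floor(np.sqrt(max_bins)))
    while n_side >= 2:
        w = 1.0 / n_side
        col = np.floor(points[:, 0] / w).astype(int)
        odd = col % 2
        row = np.floor(points[:, 1] / w - 0.5 * odd).astype(int)
        keys = col * 10_000 + row
        uniq = np.unique(keys)
        if len(uniq) <= max_bins:
            centroids = np.array([points[keys == k].mean(axis=0) for k in uniq])
            return centroids
        n_side -= 1
    return points[:max_bins]


def _alpha_hull(points: np.ndarray, tri: Delaunay,
                alpha: float) -> tuple[float, float]:
    """(area, perimeter) of the union of triangles with circumradius <= alpha."""
    keep = []
    for simplex in tri.simplices:
        a, b, c = points[simplex]
        la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c),
                      np.linalg.norm(a - b))
        area2 = abs((b[0] - a[0]) * (c[1] - a[1])
                    - (c[0] - a[0]) * (b[1] - a[1]))
        if area2 <= 0:
            continue
        circumradius = (la * lb * lc) / (2.0 * area2)
        if circumradius <= alpha:
            keep.append(Polygon([a, b, c]))
    if not keep:
        return 0.0, 0.0
    shape = unary_union(keep)
    return float(shape.area), float(shape.length)


def _graph_diameter(n: int, edges: list[tuple[int, int, float]]) -> float:
    """Longest weighted shortest path within the MST."""
    rows = [e[0] for e in edges] + [e[1] for e in edges]
    cols = [e[1] for e in edges] + [e[0] for e in edges]
    data = [e[2] for e in edges] * 2
    graph = csr_matrix((data, (rows, cols)), shape=(n, n))
    dist = shortest_path(graph, method="D", directed=False)
    finite = dist[np.isfinite(dist)]
    return float(finite.max()) if finite.size else 0.0


def _clip01(value: float) -> float:
    return float(min(1.0, max(0.0, value)))


# ---------------------------------------------------------------------------
# the nine measures
# ---------------------------------------------------------------------------

def _measure_outlying(points: np.ndarray,
                      edges: list[tuple[int, int, float]],
                      cut: float) -> tuple[float, np.ndarray]:
    """Outlying measure plus the boolean mask of pruned vertices.

    An outlying vertex is one whose every incident MST edge is longer than
    the cut; the measure is the MST length fraction carried by edges
    incident to such vertices.
    """
    n = len(points)
    incident: list[list[float]] = [[] for _ in range(n)]
    for i, j, w in edges:
        incident[i].append(w)
        incident[j].append(w)
    is_outlier = np.array([bool(ws) and min(ws) > cut for ws in incident])
    total = sum(w for _, _, w in edges)
    if total == 0:
        return 0.0, is_outlier
    outlier_len = sum(w for i, j, w in edges
                      if is_outlier[i] or is_outlier[j])
    return _clip01(outlier_len / total), is_outlier


def _measure_clumpy(n: int, edges: list[tuple[int, int, float]]) -> float:
    """RUNT-based clumpiness.

    For each MST edge j the tree is cut on edges at least as long as j;
    the runt is the smaller of the two components around j's endpoints.
    The edge scores runt_size * (1 - (longest runt edge) / length(j)) —
    large when a sizeable, tight cluster hangs off a long bridge — and
    clumpy is twice the maximum score over edges divided by the vertex
    count (a runt holds at most n/2 vertices, so the result sits in
    [0, 1]).
    """
    if not edges:
        return 0.0
    best = 0.0
    for (a, b, w) in edges:
        if w <= 0:
            continue
        # components under edges strictly shorter than w
        parent = list(range(n))

        def find(u: int) -> int:
            while parent[u] != u:
                parent[u] = parent[parent[u]]
                u = parent[u]
            return u

        shorter = [(i, j, wij) for (i, j, wij) in edges if wij < w]
        for (i, j, _) in shorter:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        side_a, side_b = find(a), find(b)
        if side_a == side_b:
            continue
        roots = np.array([find(v) for v in range(n)])
        size_a = int((roots == side_a).sum())
        size_b = int((roots == side_b).sum())
        runt_root = side_a if size_a <= size_b else side_b
        runt_size = min(size_a, size_b)
        runt_edges = [wij for (i, j, wij) in shorter if find(i) == runt_root]
        inner = max(runt_edges) if runt_edges else 0.0
        best = max(best, runt_size * (1.0 - inner / w))
    return _clip01(2.0 * best / n) if n else 0.0


def _measure_striated(points: np.ndarray,
                      edges: list[tuple[int, int, float]]) -> float:
    """Fraction of vertices that are degree-2 with a near-straight angle."""
    n = len(points)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j, _ in edges:
        neighbors[i].append(j)
        neighbors[j].append(i)
    count = 0
    for v, nbrs in enumerate(neighbors):
        if len(nbrs) != 2:
            continue
        u = points[nbrs[0]] - points[v]
        w = points[nbrs[1]] - points[v]
        nu, nw = np.linalg.norm(u), np.linalg.norm(w)
        if nu == 0 or nw == 0:
            continue
        if float(np.dot(u, w) / (nu * nw)) < STRIATED_COS:
            count += 1
    return _clip01(count / n) if n else 0.0


def compute_scagnostics(x, y, seed: int = 0,
                        max_bins: int = DEFAULT_MAX_BINS,
                        ) -> ScagnosticsProfile | None:
    """Compute the nine scagnostics of a scatter.

    Missing pairs are dropped; coordinates are min-max scaled to the unit
    square, so the measures are invariant to translation and uniform (or
    per-axis) scaling of the input.  Returns None — with a logged reason —
    for fewer than 3 complete points or a zero-variance axis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        logger.warning("scagnostics: only %d complete points (< 3)", len(x))
        return None
    points = _normalize_unit_square(x, y)
    if points is None:
        logger.warning("scagnostics: zero variance on an axis")
        return None

    # monotonic uses the full (unbinned, un-deduplicated) point set
    rho = stats.spearmanr(x, y).statistic
    monotonic = _clip01(float(rho) ** 2) if np.isfinite(rho) else 0.0

    points = np.unique(points, axis=0)
    if len(points) < 3:
        logger.warning("scagnostics: fewer than 3 distinct points")
        return None
    if len(points) > max_bins:
        points = _hex_bin(points, max_bins,
                          np.random.default_rng(seed))

    edges = mst_edges(points)
    lengths = np.array([w for _, _, w in edges])
    q10, q25, q50, q75, q90 = np.percentile(lengths, [10, 25, 50, 75, 90])
    cut = q75 + OUTLIER_IQR_FACTOR * (q75 - q25)

    outlying, outlier_mask = _measure_outlying(points, edges, cut)

    # prune outliers; recompute the tree and its quantiles for shape measures
    if outlier_mask.any() and (~outlier_mask).sum() >= 3:
        points = points[~outlier_mask]
        edges = mst_edges(points)
        lengths = np.array([w for _, _, w in edges])
        q10, q25, q50, q75, q90 = np.percentile(lengths, [10, 25, 50, 75, 90])
    n = len(points)
    total_len = float(lengths.sum())

    sparse = _clip01(q90)
    skewed = _clip01((q90 - q50) / (q90 - q10)) if q90 > q10 else 0.0
    clumpy = _measure_clumpy(n, edges)
    striated = _measure_striated(points, edges)
    stringy = (_clip01(_graph_diameter(n, edges) / total_len)
               if total_len > 0 else 0.0)

    alpha = float(q90)
    try:
        tri = Delaunay(points)
        from scipy.spatial import ConvexHull
        hull_area = float(ConvexHull(points).volume)
        alpha_area, alpha_perim = _alpha_hull(points, tri, alpha)
    except QhullError:
        # collinear cloud: zero-area hull
        hull_area, alpha_area, alpha_perim = 0.0, 0.0, 0.0
    if hull_area > 0 and alpha_area > 0:
        convex = _clip01(alpha_area / hull_area)
        skinny = _clip01(1.0 - np.sqrt(4.0 * np.pi * alpha_area) / alpha_perim)
    else:
        convex, skinny = 0.0, 1.0

    return ScagnosticsProfile(outlying=outlying, skewed=float(skewed),
                              clumpy=clumpy, sparse=float(sparse),
                              striated=striated, convex=convex,
                              skinny=skinny, stringy=stringy,
                              monotonic=monotonic)


def scagnostics_for_trait(trait: str,
                          results: EwasResultTable,
                          betas: BetaMatrix,
                          traits: TraitTable,
                          seed: int = 0) -> ScagnosticsProfile | None:
    """Scagnostics of the trait-vs-methylation scatter at the top probe.

    The screening scatter chosen for triage is the one at the probe with
    the smallest p-value in the trait's (filtered) result table, joined to
    trait values on individual id.  Returns None with a logged reason when
    the top probe is missing from the beta matrix or too few individuals
    carry both values.
    """
    if results.data.empty:
        logger.warning("trait %s: empty result table, no scagnostics", trait)
        return None
    top = results.top_probe()
    if top not in betas.probe_ids:
        logger.warning("trait %s: top probe %s absent from beta matrix",
                       trait, top)
        return None
    meth = betas.probe_vector(top)
    tvals = traits.trait_values(trait)
    joined = meth.to_frame("methylation").join(tvals.to_frame("trait")).dropna()
    return compute_scagnostics(joined["trait"].to_numpy(),
                               joined["methylation"].to_numpy(), seed=seed)
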