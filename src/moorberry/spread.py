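"""Spatial spread analysis of bush centroids and annotated regions.

Four complementary views of how an incursion is spreading:

* :func:`cluster_points` — transitive single-linkage grouping of bush
  centroids at a fixed distance threshold (how many bushes sit in groups of
  three or more, how many are isolated),
* :func:`kernel_density` — a quartic-kernel density raster in points/m²,
* :func:`gi_star` — classic Getis-Ord Gi* hotspot z-scores with binary
  fixed-distance weights (self included), binned at the usual two-sided
  90/95/99% confidence thresholds,
* :func:`h0_persistence` — 0-dimensional persistent homology of the sampled
  annotation regions: grow a disk of common radius around every sample point
  and record the radius at which initially distinct regions first connect.
  Merges between samples of the same region are sampling artifacts and are
  discarded.  The merge radii are exactly the single-linkage merge tree of
  the samples (edges of the Euclidean minimum spanning tree), with an
  inter-region event at radius d/2 when two disks of equal radius touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial import cKDTree

EIGHT_CONN = np.ones((3, 3), dtype=bool)

#: Two-sided z thresholds for the 90 / 95 / 99 % confidence bins.
Z_90, Z_95, Z_99 = 1.645, 1.960, 2.576

FUSED_FRACTIONS = (0.01, 0.10, 0.50, 0.90)


@dataclass
class PointPattern:
    """Bush centroids in metres within a rectangular site frame."""

    points: np.ndarray  # (n, 2) x_m, y_m
    site_id: str = ""
    extent: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ClusterTable:
    """Single-linkage grouping summary at one distance threshold."""

    threshold_m: float
    labels: np.ndarray  # cluster id per point
    sizes: np.ndarray  # size per cluster id

    @property
    def n_points(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def pct_grouped_3plus(self) -> float:
        """Percent of points lying in clusters of size >= 3."""
        if self.n_points == 0:
            return 0.0
        big = self.sizes >= 3
        return 100.0 * self.sizes[big].sum() / self.n_points

    @property
    def n_singletons(self) -> int:
        return int((self.sizes == 1).sum())

    @property
    def largest_cluster_size(self) -> int:
        return int(self.sizes.max()) if self.n_clusters else 0

    def summary(self) -> dict:
        return {
            "threshold_m": self.threshold_m,
            "n_points": self.n_points,
            "n_clusters": self.n_clusters,
            "pct_grouped_3plus": self.pct_grouped_3plus,
            "n_singletons": self.n_singletons,
            "largest_cluster_size": self.largest_cluster_size,
        }


@dataclass
class DensityRaster:
    """Kernel density surface in points per m²."""

    values: np.ndarray  # (rows, cols)
    cell_size_m: float
    extent: tuple[float, float, float, float]


@dataclass
class HotspotFeature:
    x_m: float
    y_m: float
    count: float
    z: float
    bin: str  # none | 90 | 95 | 99 | cold90 | cold95 | cold99


@dataclass
class HotspotMap:
    features: list[HotspotFeature]
    neighborhood_m: float

    def counts_by_bin(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.bin] = out.get(f.bin, 0) + 1
        return out


@dataclass
class RegionSamples:
    """Uniform grid samples of a labeled mask, tagged with region ids."""

    points_px: np.ndarray  # (n, 2) x_px, y_px
    region_ids: np.ndarray  # (n,)
    n_regions: int
    spacing_px: int


@dataclass
class MergeEvent:
    radius: float
    region_a: int
    region_b: int


@dataclass
class PersistenceResult:
    """Inter-region merge events of the growing-disk filtration."""

    sample_spacing_px: int
    region_count: int
    merge_events: list[MergeEvent]
    fused_fraction_radii: dict[float, float] = field(default_factory=dict)
    radius_convention: str = "disk"
    pixel_size_m: Optional[float] = None

    def radii_m(self) -> Optional[dict[float, float]]:
        if self.pixel_size_m is None:
            return None
        return {f: r * self.pixel_size_m for f, r in self.fused_fraction_radii.items()}


# ---------------------------------------------------------------------------
# distance clustering


def cluster_points(pattern: PointPattern, threshold_m: float) -> ClusterTable:
    """Group points by transitive single linkage at a distance threshold.

    Points i and j share a cluster iff a chain of pairwise distances
    <= ``threshold_m`` connects them (the GIS integrate/collect-events
    analogue at the 3 m and 6 m distances used for field grouping).
    """
    if threshold_m <= 0:
        raise ValueError("threshold_m must be positive")
    pts = pattern.points
    n = len(pts)
    if n == 0:
        return ClusterTable(threshold_m, np.empty(0, dtype=int), np.empty(0, dtype=int))
    tree = cKDTree(pts)
    pairs = tree.query_pairs(threshold_m, output_type="ndarray")
    if len(pairs):
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        graph = coo_matrix((n, n))
    _, labels = connected_components(graph, directed=False)
    sizes = np.bincount(labels)
    return ClusterTable(threshold_m, labels, sizes)


# ---------------------------------------------------------------------------
# kernel density


def kernel_density(
    pattern: PointPattern, cell_size_m: float, radius_m: float
) -> DensityRaster:
    """Quartic-kernel density raster (points per m²) over the site extent.

    K(d) = 3 / (pi r²) (1 - d²/r²)² for d < r, 0 otherwise; each point
    contributes unit mass, so the raster integrates to the interior point
    count.
    """
    if not (radius_m > cell_size_m > 0):
        raise ValueError("need radius_m > cell_size_m > 0")
    x0, y0, x1, y1 = pattern.extent
    n_cols = max(1, int(np.ceil((x1 - x0) / cell_size_m)))
    n_rows = max(1, int(np.ceil((y1 - y0) / cell_size_m)))
    values = np.zeros((n_rows, n_cols))
    if len(pattern) == 0:
        return DensityRaster(values, cell_size_m, pattern.extent)
    # cell centers; row 0 at the top (north) edge to match raster convention
    xc = x0 + (np.arange(n_cols) + 0.5) * cell_size_m
    yc = y1 - (np.arange(n_rows) + 0.5) * cell_size_m
    norm = 3.0 / (np.pi * radius_m**2)
    for px, py in pattern.points:
        c0 = max(0, int((px - radius_m - x0) / cell_size_m))
        c1 = min(n_cols, int((px + radius_m - x0) / cell_size_m) + 2)
        r0 = max(0, int((y1 - py - radius_m) / cell_size_m))
        r1 = min(n_rows, int((y1 - py + radius_m) / cell_size_m) + 2)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = xc[c0:c1] - px
        dy = yc[r0:r1] - py
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        u = 1.0 - d2 / radius_m**2
        u[u < 0] = 0.0
        values[r0:r1, c0:c1] += norm * u**2
    return DensityRaster(values, cell_size_m, pattern.extent)


# ---------------------------------------------------------------------------
# Getis-Ord Gi*


def _gi_bin(z: float) -> str:
    if z >= Z_99:
        return "99"
    if z >= Z_95:
        return "95"
    if z >= Z_90:
        return "90"
    if z <= -Z_99:
        return "cold99"
    if z <= -Z_95:
        return "cold95"
    if z <= -Z_90:
        return "cold90"
    return "none"


def gi_star(
    features: Sequence[tuple[float, float, float]], neighborhood_m: float
) -> HotspotMap:
    """Classic Getis-Ord Gi* with binary fixed-distance weights, self included.

    For feature i with neighbors N(i) = {j : d_ij <= neighborhood_m} (i in
    N(i)):

        Gi* = (sum_{j in N(i)} x_j - Xbar |N(i)|)
              / (S sqrt((n |N(i)| - |N(i)|²) / (n - 1)))

    with Xbar the global mean and S the global (population) sd of the counts.
    Degenerate denominators (zero count variance, or a neighborhood covering
    all features) yield z = 0 and bin "none".
    """
    feats = list(features)
    n = len(feats)
    if n < 2:
        raise ValueError("gi_star needs at least 2 features")
    xy = np.array([(f[0], f[1]) for f in feats])
    x = np.array([f[2] for f in feats], dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    tree = cKDTree(xy)
    neighbors = tree.query_ball_point(xy, neighborhood_m)
    out = []
    for i, nb in enumerate(neighbors):
        wi = float(len(nb))  # binary weights; self is always in nb
        num = x[nb].sum() - xbar * wi
        den = s * np.sqrt(max(n * wi - wi**2, 0.0) / (n - 1))
        z = float(num / den) if den > 0 else 0.0
        out.append(HotspotFeature(xy[i, 0], xy[i, 1], x[i], z, _gi_bin(z)))
    return HotspotMap(out, neighborhood_m)


# ---------------------------------------------------------------------------
# region sampling and 0-D persistence


def sample_regions(mask: np.ndarray, spacing_px: int) -> RegionSamples:
    """Uniform grid samples of a binary mask, labeled by connected component.

    Grid points at rows/cols 0, spacing, 2*spacing, ... restricted to mask
    pixels.  Every component contributes at least one sample: components the
    grid misses fall back to their pixel nearest the component centroid.
    """
    if spacing_px < 1:
        raise ValueError("spacing_px must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    labels, n_regions = ndimage.label(mask, structure=EIGHT_CONN)
    if n_regions == 0:
        return RegionSamples(np.empty((0, 2)), np.empty(0, dtype=int), 0, spacing_px)
    rows = np.arange(0, mask.shape[0], spacing_px)
    cols = np.arange(0, mask.shape[1], spacing_px)
    sub = labels[np.ix_(rows, cols)]
    rr, cc = np.nonzero(sub)
    pts = np.column_stack([cols[cc], rows[rr]]).astype(float)  # x, y
    ids = sub[rr, cc]
    missing = set(range(1, n_regions + 1)) - set(np.unique(ids).tolist())
    if missing:
        extra_pts, extra_ids = [], []
        centroids = ndimage.center_of_mass(mask, labels, sorted(missing))
        for rid, (cy, cx) in zip(sorted(missing), centroids):
            ys, xs = np.nonzero(labels == rid)
            k = np.argmin((xs - cx) ** 2 + (ys - cy) ** 2)
            extra_pts.append((float(xs[k]), float(ys[k])))
            extra_ids.append(rid)
        pts = np.vstack([pts, np.array(extra_pts)]) if len(pts) else np.array(extra_pts)
        ids = np.concatenate([ids, np.array(extra_ids)])
    return RegionSamples(pts, ids.astype(int), int(n_regions), spacing_px)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def h0_persistence(
    samples: RegionSamples,
    radius_convention: Literal["disk", "distance"] = "disk",
    pixel_size_m: Optional[float] = None,
    fractions: Sequence[float] = FUSED_FRACTIONS,
) -> PersistenceResult:
    """0-D persistence of the sampled regions under a growing-disk filtration.

    Disks of common radius grow at uniform speed around every sample point;
    when the disks of two samples belonging to *different* region-components
    touch, one region is absorbed by the other (an inter-region merge event).
    Merges between samples of one region are discarded as sampling artifacts.
    Under the "disk" convention the event radius is d/2 (two disks of equal
    radius touch); "distance" reports the pairwise distance d instead.

    The merge structure is computed along the Euclidean minimum spanning tree
    of the samples, which carries exactly the single-linkage merge radii.

    ``fused_fraction_radii[f]`` is the smallest event radius at which at
    least a fraction ``f`` of the R-1 possible inter-region merges happened.
    """
    ids = np.unique(samples.region_ids)
    r_count = len(ids)
    if r_count < 2:
        return PersistenceResult(
            samples.spacing_px, r_count, [], {}, radius_convention, pixel_size_m
        )
    pts = samples.points_px
    n = len(pts)
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    mst = minimum_spanning_tree(dist).tocoo()
    order = np.argsort(mst.data, kind="stable")
    uf_samples = _UnionFind(n)
    region_index = {rid: k for k, rid in enumerate(ids)}
    uf_regions = _UnionFind(r_count)
    sample_region = np.array([region_index[r] for r in samples.region_ids])
    events: list[MergeEvent] = []
    factor = 0.5 if radius_convention == "disk" else 1.0
    for k in order:
        i, j, d = int(mst.row[k]), int(mst.col[k]), float(mst.data[k])
        uf_samples.union(i, j)
        ra = uf_regions.find(int(sample_region[i]))
        rb = uf_regions.find(int(sample_region[j]))
        if ra != rb:
            events.append(MergeEvent(d * factor, int(ids[ra]), int(ids[rb])))
            uf_regions.union(ra, rb)
    fused: dict[float, float] = {}
    total = r_count - 1
    for f in fractions:
        k = max(1, int(np.ceil(f * total)))
        if k <= len(events):
            fused[f] = events[k - 1].radius
    return PersistenceResult(
        samples.spacing_px, r_count, events, fused, radius_convention, pixel_size_m
    )
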