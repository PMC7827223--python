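"""Clustering, kernel density, Gi* and 0-D persistence against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moorberry.spread import (
    PointPattern,
    cluster_points,
    gi_star,
    h0_persistence,
    kernel_density,
    sample_regions,
)


def _pattern(pts, extent=(0, 0, 50, 50)):
    return PointPattern(np.asarray(pts, float), "t", extent)


# ---------------------------------------------------------------------------
# cluster_points


def test_pair_within_threshold_forms_one_cluster():
    t = cluster_points(_pattern([(0, 0), (0, 2.5)]), 3.0)
    assert t.n_clusters == 1
    assert t.largest_cluster_size == 2


def test_chained_cluster_is_transitive():
    t = cluster_points(_pattern([(0, 0), (0, 2.5), (0, 5.0)]), 3.0)
    assert t.n_clusters == 1
    assert t.pct_grouped_3plus == 100.0


def test_all_far_apart_are_singletons():
    t = cluster_points(_pattern([(0, 0), (10, 0), (0, 10)]), 3.0)
    assert t.n_singletons == 3
    assert t.pct_grouped_3plus == 0.0


def _union_find_clusters(pts, threshold):
    """Oracle: union-find over the full pairwise distance matrix."""
    n = len(pts)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(pts[i] - pts[j])) <= threshold:
                parent[find(j)] = find(i)
    roots = [find(i) for i in range(n)]
    return sorted(np.bincount(np.unique(roots, return_inverse=True)[1]))


def test_cluster_sizes_match_union_find_oracle(rng):
    for _ in range(20):
        pts = rng.uniform(0, 30, (rng.integers(2, 60), 2))
        t = cluster_points(_pattern(pts, (0, 0, 30, 30)), 3.0)
        assert sorted(t.sizes.tolist()) == _union_find_clusters(pts, 3.0)
        assert t.sizes.sum() == len(pts)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    coords=st.lists(
        st.tuples(
            st.floats(0, 30, allow_nan=False), st.floats(0, 30, allow_nan=False)
        ),
        min_size=1,
        max_size=40,
    ),
    threshold=st.floats(0.5, 10, allow_nan=False),
)
def test_cluster_table_bookkeeping_invariants(coords, threshold):
    """Sizes partition the points; singleton and 3+ counts are consistent."""
    t = cluster_points(_pattern(coords, (0, 0, 30, 30)), threshold)
    assert t.sizes.sum() == len(coords)
    assert t.n_singletons <= t.n_clusters
    grouped = t.sizes[t.sizes >= 3].sum()
    assert t.pct_grouped_3plus == pytest.approx(100 * grouped / len(coords))


# ---------------------------------------------------------------------------
# kernel_density


def test_density_zero_far_from_points():
    d = kernel_density(_pattern([(25, 25)]), 1.0, 3.0)
    # corner cell center is > 3 m from the single point
    assert d.values[0, 0] == 0.0


def test_density_maximum_at_the_point():
    d = kernel_density(_pattern([(25.5, 25.5)]), 1.0, 5.0)
    r, c = np.unravel_index(np.argmax(d.values), d.values.shape)
    # point sits in cell (row 24, col 25) with y measured from the north edge
    assert (r, c) == (24, 25)


def test_density_integrates_to_point_count(rng):
    pts = rng.uniform(15, 35, (12, 2))  # interior points, kernel fully inside
    d = kernel_density(_pattern(pts), 0.5, 4.0)
    mass = d.values.sum() * 0.5**2
    assert mass == pytest.approx(12, rel=0.01)


def test_empty_pattern_gives_zero_raster():
    d = kernel_density(_pattern(np.empty((0, 2))), 1.0, 3.0)
    assert d.values.sum() == 0.0


# ---------------------------------------------------------------------------
# gi_star


def test_equal_counts_give_zero_z():
    feats = [(0, 0, 3.0), (5, 0, 3.0), (0, 5, 3.0)]
    hm = gi_star(feats, 4.0)
    assert all(f.z == 0.0 for f in hm.features)
    assert all(f.bin == "none" for f in hm.features)


def test_single_large_count_is_the_hottest():
    # separated features (neighborhood = self) so neighborhood sizes are
    # comparable and the count-holder must carry the maximum positive z
    pts = [(10.0 * i, 0.0) for i in range(15)]
    counts = np.zeros(15)
    counts[7] = 50
    hm = gi_star([(x, y, c) for (x, y), c in zip(pts, counts)], 5.0)
    zs = [f.z for f in hm.features]
    assert np.argmax(zs) == 7
    assert zs[7] > 0


def _gi_star_formula(xy, x, radius):
    """Oracle: direct evaluation of the Gi* formula, one feature at a time."""
    n = len(x)
    xbar = x.mean()
    s = np.sqrt((x**2).sum() / n - xbar**2)
    zs = []
    for i in range(n):
        w = np.array(
            [1.0 if np.hypot(*(xy[i] - xy[j])) <= radius else 0.0 for j in range(n)]
        )
        sw = w.sum()
        num = (w * x).sum() - xbar * sw
        den = s * np.sqrt((n * (w**2).sum() - sw**2) / (n - 1))
        zs.append(num / den if den > 0 else 0.0)
    return np.array(zs)


def test_z_scores_match_formula_oracle(rng):
    for _ in range(10):
        xy = rng.uniform(0, 30, (10, 2))
        counts = rng.poisson(4, 10).astype(float)
        if counts.std() == 0:
            counts[0] += 1
        hm = gi_star([(x, y, c) for (x, y), c in zip(xy, counts)], 10.0)
        expected = _gi_star_formula(xy, counts, 10.0)
        assert np.allclose([f.z for f in hm.features], expected, atol=1e-12)


def test_z_sums_to_zero_for_constant_neighbor_counts(rng):
    # on a ring every feature has the same number of neighbors, so the
    # numerators telescope and the common denominator cancels
    n = 12
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    xy = 10 * np.column_stack([np.cos(ang), np.sin(ang)])
    counts = rng.poisson(5, n).astype(float)
    radius = np.hypot(*(xy[0] - xy[1])) + 1e-9  # exactly 2 neighbors + self
    hm = gi_star([(x, y, c) for (x, y), c in zip(xy, counts)], radius)
    assert abs(sum(f.z for f in hm.features)) < 1e-9 * n


def test_zero_variance_counts_give_all_none_bins():
    feats = [(0, 0, 2.0), (1, 0, 2.0), (2, 0, 2.0)]
    hm = gi_star(feats, 1.5)
    assert {f.bin for f in hm.features} == {"none"}


# ---------------------------------------------------------------------------
# sample_regions


def test_single_pixel_component_always_sampled():
    mask = np.zeros((20, 20), bool)
    mask[13, 17] = True
    s = sample_regions(mask, 6)
    assert len(s.points_px) == 1
    assert tuple(s.points_px[0]) == (17.0, 13.0)


def test_full_frame_sample_count():
    mask = np.ones((30, 40), bool)
    s = sample_regions(mask, 7)
    assert len(s.points_px) == int(np.ceil(30 / 7)) * int(np.ceil(40 / 7))


def test_region_ids_match_flood_fill(rng):
    from scipy import ndimage

    mask = rng.random((50, 50)) > 0.85
    mask = ndimage.binary_dilation(mask, np.ones((3, 3), bool))
    s = sample_regions(mask, 4)
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), bool))
    for (x, y), rid in zip(s.points_px, s.region_ids):
        assert labels[int(y), int(x)] == rid


# ---------------------------------------------------------------------------
# h0_persistence


def _samples(points, ids, spacing=1):
    from moorberry.spread import RegionSamples

    return RegionSamples(
        np.asarray(points, float), np.asarray(ids, int), len(set(ids)), spacing
    )


def test_two_point_regions_merge_at_half_distance():
    res = h0_persistence(_samples([(0, 0), (10, 0)], [1, 2]))
    assert len(res.merge_events) == 1
    assert res.merge_events[0].radius == pytest.approx(5.0)
    assert set(res.fused_fraction_radii.values()) == {5.0}


def test_three_regions_on_a_line():
    res = h0_persistence(_samples([(0, 0), (10, 0), (30, 0)], [1, 2, 3]))
    radii = [e.radius for e in res.merge_events]
    assert radii == pytest.approx([5.0, 10.0])
    assert res.fused_fraction_radii[0.5] == pytest.approx(5.0)
    assert res.fused_fraction_radii[0.9] == pytest.approx(10.0)


def test_distance_convention_doubles_radii():
    res = h0_persistence(
        _samples([(0, 0), (10, 0)], [1, 2]), radius_convention="distance"
    )
    assert res.merge_events[0].radius == pytest.approx(10.0)


def test_intra_region_merges_are_discarded():
    # two samples of region 1 bracketing region 2: only 1 inter-region event
    res = h0_persistence(_samples([(0, 0), (3, 0), (6, 0)], [1, 2, 1]))
    assert res.region_count == 2
    assert len(res.merge_events) == 1
    assert res.merge_events[0].radius == pytest.approx(1.5)


def _brute_force_single_linkage(points, ids):
    """Oracle: union-find over all pairs sorted by distance ascending."""
    n = len(points)
    pairs = sorted(
        ((np.hypot(*(points[i] - points[j])), i, j) for i in range(n) for j in range(i + 1, n))
    )
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    rparent = {r: r for r in set(ids)}

    def rfind(a):
        while rparent[a] != a:
            rparent[a] = rparent[rparent[a]]
            a = rparent[a]
        return a

    events = []
    for d, i, j in pairs:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        parent[rj] = ri
        ra, rb = rfind(ids[i]), rfind(ids[j])
        if ra != rb:
            events.append(d / 2)
            rparent[rb] = ra
    return events


def test_merge_radii_match_brute_force_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(5, 60))
        pts = rng.uniform(0, 100, (n, 2))
        ids = rng.integers(1, max(2, n // 3), n)
        if len(set(ids.tolist())) < 2:
            ids[0] = ids.max() + 1
        res = h0_persistence(_samples(pts, ids))
        expected = _brute_force_single_linkage(pts, ids.tolist())
        assert [e.radius for e in res.merge_events] == pytest.approx(expected)
        assert len(res.merge_events) == res.region_count - 1


def test_densifying_regions_never_increases_merge_radii(rng):
    # two square regions; add more samples inside each and compare radii
    coarse_pts, coarse_ids = [], []
    fine_pts, fine_ids = [], []
    for rid, (ox, oy) in ((1, (0, 0)), (2, (20, 0))):
        for x in range(0, 6, 5):
            for y in range(0, 6, 5):
                coarse_pts.append((ox + x, oy + y))
                coarse_ids.append(rid)
        for x in range(0, 6, 1):
            for y in range(0, 6, 1):
                fine_pts.append((ox + x, oy + y))
                fine_ids.append(rid)
    r_coarse = h0_persistence(_samples(coarse_pts, coarse_ids))
    r_fine = h0_persistence(_samples(fine_pts, fine_ids))
    assert r_fine.merge_events[0].radius <= r_coarse.merge_events[0].radius


def test_merge_radii_match_scipy_single_linkage(rng):
    # with every sample its own region, the inter-region merge radii are the
    # single-linkage dendrogram heights halved; scipy's implementation is an
    # independent code path from the package's MST + union-find
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist

    pts = rng.uniform(0, 100, (50, 2))
    res = h0_persistence(_samples(pts, np.arange(1, 51)))
    heights = linkage(pdist(pts), method="single")[:, 2]
    assert sorted(e.radius for e in res.merge_events) == pytest.approx(
        sorted(heights / 2)
    )


def test_single_region_has_no_events():
    res = h0_persistence(_samples([(0, 0), (5, 5)], [1, 1]))
    assert res.merge_events == []
    assert res.fused_fraction_radii == {}


def test_fused_fraction_radii_monotone(rng):
    pts = rng.uniform(0, 50, (40, 2))
    ids = np.arange(1, 41)
    res = h0_persistence(_samples(pts, ids))
    radii = [res.fused_fraction_radii[f] for f in (0.01, 0.10, 0.50, 0.90)]
    assert radii == sorted(radii)


def test_cluster_and_persistence_connectivity_agree(rng):
    # clusters at threshold t == region-components at merge radius t/2 when
    # every centroid is its own region
    pts = rng.uniform(0, 40, (30, 2))
    t = 4.0
    table = cluster_points(_pattern(pts, (0, 0, 40, 40)), t)
    res = h0_persistence(_samples(pts, np.arange(1, 31)))
    merges_within = sum(1 for e in res.merge_events if e.radius <= t / 2)
    assert 30 - merges_within == table.n_clusters
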