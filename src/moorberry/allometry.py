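"""Per-bush and per-class statistics from annotation masks and the DEM.

Bushes are the 8-connected components of the blueberry mask (hand-drawn
annotation strokes that touch diagonally belong to one bush).  Heights are
DEM statistics over the component pixels minus the elevation of the ground
point nearest to the component centroid; ground points are annotated close
to bushes, so no ground-surface interpolation is performed by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .scene import CLASSES, LIVING_CLASSES, GroundPoint

EIGHT_CONN = np.ones((3, 3), dtype=bool)


class MaskError(ValueError):
    """Raised for non-binary or mutually overlapping masks."""


@dataclass
class BushRecord:
    """One connected component of the blueberry mask."""

    component_id: int
    pixel_count: int
    area_m2: float
    centroid_xy: tuple[float, float]  # (x_px, y_px)
    max_height_m: Optional[float] = None
    median_height_m: Optional[float] = None
    height_clamped: bool = False  # negative raw height clamped to 0


@dataclass
class InventorySummary:
    """Site-level inventory in the shape of a survey summary table row."""

    site_area_ha: float
    bush_count: int
    bushes_per_ha: Optional[float]
    total_bush_area_m2: float
    mean_area_per_bush_m2: Optional[float]
    class_area_fractions: Optional[dict[str, float]] = None
    blueberry_share_of_living_pct: Optional[float] = None


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, as used for report presentation."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _check_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise MaskError(f"mask is not binary; values found: {vals[:10]}")
    return arr.astype(bool)


def label_bushes(mask: np.ndarray, pixel_size_m: float = 1.0) -> list[BushRecord]:
    """One record per 8-connected component of a binary mask."""
    mask = _check_binary(mask)
    labels, n = ndimage.label(mask, structure=EIGHT_CONN)
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]
    centroids = ndimage.center_of_mass(mask, labels, np.arange(1, n + 1))
    records = []
    for i in range(n):
        cy, cx = centroids[i]
        records.append(
            BushRecord(
                component_id=i + 1,
                pixel_count=int(counts[i]),
                area_m2=float(counts[i]) * pixel_size_m**2,
                centroid_xy=(float(cx), float(cy)),
            )
        )
    return records


def compute_class_areas(
    masks: dict[str, np.ndarray], pixel_size_m: float
) -> pd.DataFrame:
    """Pixel counts, areas and area shares per annotation class.

    Returns a frame indexed by class with columns ``pixels``, ``area_m2``,
    ``pct_site`` (share of all pixels) and ``pct_living`` (share within the
    living vegetation: blueberry + tree + yellow bush; NaN otherwise).
    """
    first = next(iter(masks.values()))
    overlap = np.zeros(first.shape, dtype=np.int16)
    binarized = {}
    for name, m in masks.items():
        b = _check_binary(m)
        overlap += b
        binarized[name] = b
    n_over = int((overlap > 1).sum())
    if n_over:
        raise MaskError(f"masks overlap on {n_over} pixels")
    total_px = first.size
    living_px = sum(int(binarized[c].sum()) for c in LIVING_CLASSES if c in binarized)
    rows = []
    for name in CLASSES:
        if name not in binarized:
            continue
        px = int(binarized[name].sum())
        rows.append(
            {
                "class": name,
                "pixels": px,
                "area_m2": px * pixel_size_m**2,
                "pct_site": 100.0 * px / total_px,
                "pct_living": (
                    100.0 * px / living_px
                    if name in LIVING_CLASSES and living_px
                    else math.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def compute_bush_heights(
    dem: np.ndarray,
    records: Sequence[BushRecord],
    ground_points: Sequence[GroundPoint],
    statistic: Literal["max", "median"] = "max",
    mask: Optional[np.ndarray] = None,
    max_ground_dist_px: Optional[float] = None,
) -> list[BushRecord]:
    """DEM-based bush heights relative to the nearest annotated ground point.

    height = statistic(DEM over component pixels) - elevation of the ground
    point nearest to the component centroid.  Negative results are clamped to
    0 m and flagged (hassocks inflate apparent ground elevation).  If no
    ground point lies within ``max_ground_dist_px`` of a centroid the height
    stays undefined (None) for that bush.  Records are updated in place and
    returned.

    ``mask`` must be the same binary raster the records were labeled from;
    it is re-labeled to recover each component's pixel set.
    """
    if not ground_points:
        raise ValueError("at least one ground point is required")
    if mask is None:
        raise ValueError("mask is required to recover component pixels")
    mask = _check_binary(mask)
    labels, n = ndimage.label(mask, structure=EIGHT_CONN)
    if n != len(records):
        raise ValueError(
            f"mask has {n} components but {len(records)} records were given"
        )
    gxy = np.array([(g.x_px, g.y_px) for g in ground_points])
    gel = np.array([g.elevation_m for g in ground_points])
    stat = np.max if statistic == "max" else np.median
    for rec in records:
        comp = labels == rec.component_id
        cx, cy = rec.centroid_xy
        d = np.hypot(gxy[:, 0] - cx, gxy[:, 1] - cy)
        k = int(np.argmin(d))
        if max_ground_dist_px is not None and d[k] > max_ground_dist_px:
            height = None
        else:
            raw = float(stat(dem[comp]) - gel[k])
            height = max(raw, 0.0)
            if statistic == "max":
                rec.height_clamped = raw < 0
        if statistic == "max":
            rec.max_height_m = height
        else:
            rec.median_height_m = height
    return list(records)


def summarize_inventory(
    records_or_total: Sequence[BushRecord] | float,
    site_area_ha: float,
    bush_count: Optional[int] = None,
    class_area_fractions: Optional[dict[str, float]] = None,
    blueberry_share_of_living_pct: Optional[float] = None,
) -> InventorySummary:
    """Site inventory summary (count, density, mean area per bush).

    Accepts either a list of :class:`BushRecord` or a pre-computed total
    blueberry area in m² together with an explicit ``bush_count`` (as when
    reproducing a printed survey table from its own inputs).  With zero
    bushes the ratio fields are undefined (None), not 0.
    """
    if isinstance(records_or_total, (int, float)):
        if bush_count is None:
            raise ValueError("bush_count is required with a pre-computed area")
        total_area = float(records_or_total)
        count = int(bush_count)
    else:
        records = list(records_or_total)
        total_area = sum(r.area_m2 for r in records)
        count = len(records)
    return InventorySummary(
        site_area_ha=site_area_ha,
        bush_count=count,
        bushes_per_ha=count / site_area_ha if site_area_ha > 0 else None,
        total_bush_area_m2=total_area,
        mean_area_per_bush_m2=total_area / count if count else None,
        class_area_fractions=class_area_fractions,
        blueberry_share_of_living_pct=blueberry_share_of_living_pct,
    )


def bin_distribution(
    values: Iterable[Optional[float]], bin_edges: Sequence[float]
) -> pd.DataFrame:
    """Histogram with left-closed right-open bins plus an overflow bin.

    The survey convention for bush heights: 0.5 m classes from 0 m up to
    < 3.5 m plus a "more than 3.5 m" bin.  ``None``/NaN values (bushes
    without a defined height) are excluded; counts sum to the number of
    defined values.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or not (np.diff(edges) > 0).all():
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    vals = np.array(
        [v for v in values if v is not None and not math.isnan(v)], dtype=float
    )
    counts = []
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        counts.append(int(((vals >= lo) & (vals < hi)).sum()))
        labels.append(f"[{lo:g}, {hi:g})")
    counts.append(int((vals >= edges[-1]).sum()))
    labels.append(f">= {edges[-1]:g}")
    under = int((vals < edges[0]).sum())
    if under:
        raise ValueError(f"{under} values fall below the first bin edge")
    return pd.DataFrame({"bin": labels, "count": counts})
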