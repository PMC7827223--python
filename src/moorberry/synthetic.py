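"""Seeded generator of synthetic wetland scenes with full ground truth.

The generator emulates the statistical structure of an invasive-blueberry
incursion imaged by UAV at 5-7 cm/pixel: soil dominating the area (with a
configurable fraction of reddish-tinted soil acting as hard negatives for the
classifier), blueberry bushes covering roughly 1-1.5% of the site with canopy
radii of 20-100 px, clustered bush point patterns (Neyman-Scott style), a DEM
that is smooth ground plus hassock noise plus one canopy bump per bush, and
ground elevation points annotated close to bushes.

Everything is drawn from a single seeded :class:`numpy.random.Generator`;
identical config + seed yields a bit-identical scene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .scene import (
    CLASSES,
    GroundPoint,
    OrthomosaicScene,
    PlantedBush,
    SceneTruth,
)
from .spread import PointPattern

EIGHT_CONN = np.ones((3, 3), dtype=bool)


class ConfigError(ValueError):
    """Raised for an unsatisfiable scene configuration."""


class PlacementError(RuntimeError):
    """Raised when the frame is too small to place the requested bushes."""


@dataclass
class ClusterProcess:
    """Neyman-Scott-style clustering of bush centroids.

    ``parent_count`` cluster centres are placed uniformly; offspring are
    scattered around them with isotropic Gaussian spread ``cluster_sigma_m``.
    A ``background_fraction`` of the points is instead uniform over the frame,
    mimicking isolated bushes far from any spreading centre.
    """

    parent_count: int = 5
    offspring_per_parent: int = 8
    cluster_sigma_m: float = 6.0
    background_fraction: float = 0.2


@dataclass
class HeightModel:
    """Bush height distribution and ground micro-relief.

    Bush heights are mostly shallow (mode ``short_mode_m``) with a thin tail
    of tall individuals up to ``tall_tail_max_m``.  ``hassock_noise_sd_m`` is
    the standard deviation of the zero-mean grass-tussock noise added to the
    ground surface; it is the dominant error source of DEM-based heights.
    """

    short_mode_m: float = 0.3
    tall_tail_max_m: float = 3.0
    tall_fraction: float = 0.12
    hassock_noise_sd_m: float = 0.1


DEFAULT_FRACTIONS = {
    "blueberry": 0.012,
    "tree": 0.05,
    "yellow_bush": 0.03,
    "water": 0.03,
    "dead_tree": 0.01,
}

DEFAULT_PALETTE = {
    "soil": (150, 124, 96),
    "blueberry": (158, 32, 72),
    "tree": (34, 85, 45),
    "yellow_bush": (205, 180, 60),
    "water": (40, 60, 110),
    "dead_tree": (105, 105, 100),
}

#: Reddish tint applied to confounder soil pixels (still labeled soil).
CONFOUNDER_COLOR = (176, 102, 86)


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    ``class_fractions`` are target area fractions for the non-soil classes;
    the remainder of the frame is soil.  ``bush_count`` may be ``None``, in
    which case the generator derives the number of bushes from the blueberry
    area-fraction target and the radius range; an explicit count wins over
    the fraction target.
    """

    width_px: int = 600
    height_px: int = 600
    pixel_size_m: float = 0.05
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    bush_radius_range_px: tuple[float, float] = (20.0, 100.0)
    bush_count: Optional[int] = None
    cluster_process: ClusterProcess = field(default_factory=ClusterProcess)
    height_model: HeightModel = field(default_factory=HeightModel)
    confounder_fraction: float = 0.05
    palette: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    seed: int = 0
    site_id: str = "S1"

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigError("frame dimensions must be positive")
        if self.pixel_size_m <= 0:
            raise ConfigError("pixel_size_m must be positive")
        total = sum(self.class_fractions.values())
        if total > 1.0 + 1e-9:
            raise ConfigError(
                f"class fractions sum to {total:.3f} > 1; remainder must be soil"
            )
        for name in self.class_fractions:
            if name not in CLASSES or name == "soil":
                raise ConfigError(f"unknown class fraction {name!r}")
        rmin, rmax = self.bush_radius_range_px
        half = min(self.width_px, self.height_px) / 2
        if not (1 <= rmin <= rmax <= half):
            raise ConfigError(
                f"bush radius range {self.bush_radius_range_px} must lie in "
                f"[1, {half}]"
            )

    def with_seed(self, seed: int, site_id: Optional[str] = None) -> "SceneConfig":
        """A copy with a different seed (and optionally site id)."""
        return replace(
            self, seed=seed, site_id=site_id if site_id is not None else self.site_id
        )


def study_corpus(seed: int, n_scenes: int = 3, width_px: int = 1600) -> list[SceneConfig]:
    """Scene configs for a scaled-down multi-site study corpus.

    Each scene stands in for one fully annotated survey site: 1600 px square
    at 5 cm/px (80 x 80 m, 0.64 ha) with canopy radii 16-48 px, scaled down
    from the multi-hectare originals so that a full leave-one-mosaic-out run
    stays desk-sized while every mosaic still yields a few hundred patches
    and a few dozen blueberry-positive ones.
    """
    return [
        SceneConfig(
            width_px=width_px,
            height_px=width_px,
            bush_radius_range_px=(16, 48),
            seed=seed * 100 + i,
            site_id=f"S{i + 1}",
        )
        for i in range(n_scenes)
    ]


def survey_pattern_config(seed: int, bush_count: int = 500) -> SceneConfig:
    """Config for a survey-scale centroid pattern (no raster rendering).

    A 400 x 400 m frame (8000 px at 5 cm/px) holding ``bush_count`` bush
    centroids — about 31 bushes/ha, the density of the surveyed sites — so
    the distance-clustering and hotspot statistics operate on a pattern of
    realistic size.  The cluster process (60 spreading centres, 4 m
    offspring spread, 30% background) produces the survey-like picture of
    roughly a quarter of bushes in groups of three or more at 3 m, rising
    steeply at 6 m.
    """
    cfg = SceneConfig(
        width_px=8000,
        height_px=8000,
        bush_count=bush_count,
        bush_radius_range_px=(16, 48),
        seed=seed * 100 + 50,
        site_id="survey_pattern",
    )
    cfg.cluster_process = ClusterProcess(
        parent_count=60,
        offspring_per_parent=10,
        cluster_sigma_m=4.0,
        background_fraction=0.3,
    )
    return cfg


def _estimated_bush_count(cfg: SceneConfig) -> int:
    rmin, rmax = cfg.bush_radius_range_px
    mean_area = math.pi * (rmin**2 + rmin * rmax + rmax**2) / 3  # E[pi r^2], uniform r
    target_px = cfg.class_fractions.get("blueberry", 0.0) * cfg.width_px * cfg.height_px
    if target_px <= 0:
        return 0
    return max(1, round(target_px / mean_area))


def generate_point_pattern(
    cfg: SceneConfig, n_points: Optional[int] = None
) -> PointPattern:
    """Clustered bush centroids (metres) inside the scene frame.

    A Neyman-Scott-style pattern: uniformly placed parents with Gaussian
    offspring, plus a ``background_fraction`` of uniform points.  ``n_points``
    overrides ``cfg.bush_count`` (which itself defaults to a count derived
    from the blueberry area-fraction target).
    """
    cfg.validate()
    n = n_points if n_points is not None else cfg.bush_count
    if n is None:
        n = _estimated_bush_count(cfg)
    if n < 0:
        raise ConfigError("bush_count must be >= 0")
    w_m = cfg.width_px * cfg.pixel_size_m
    h_m = cfg.height_px * cfg.pixel_size_m
    extent = (0.0, 0.0, w_m, h_m)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    if n == 0:
        return PointPattern(np.empty((0, 2)), cfg.site_id, extent)

    cp = cfg.cluster_process
    rmin = cfg.bush_radius_range_px[0] * cfg.pixel_size_m
    margin = rmin * 1.4  # room for the blob boundary noise
    if 2 * margin >= w_m or 2 * margin >= h_m:
        raise PlacementError(
            f"frame {w_m:.1f} x {h_m:.1f} m too small for bushes of radius "
            f">= {rmin:.1f} m"
        )
    n_bg = int(round(n * cp.background_fraction))
    n_cl = n - n_bg
    pts = []
    if n_cl > 0:
        n_parents = max(1, min(cp.parent_count, n_cl))
        parents = np.column_stack(
            [
                rng.uniform(margin, w_m - margin, n_parents),
                rng.uniform(margin, h_m - margin, n_parents),
            ]
        )
        assignment = rng.integers(0, n_parents, n_cl)
        offsets = rng.normal(0.0, cp.cluster_sigma_m, (n_cl, 2))
        pts.append(parents[assignment] + offsets)
    if n_bg > 0:
        pts.append(
            np.column_stack(
                [
                    rng.uniform(margin, w_m - margin, n_bg),
                    rng.uniform(margin, h_m - margin, n_bg),
                ]
            )
        )
    points = np.vstack(pts)
    points[:, 0] = np.clip(points[:, 0], margin, w_m - margin)
    points[:, 1] = np.clip(points[:, 1], margin, h_m - margin)
    return PointPattern(points, cfg.site_id, extent)


def _blob_mask(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    radius: float,
    rng: np.random.Generator,
    roughness: float = 0.12,
) -> np.ndarray:
    """Irregular blob: a disk whose boundary radius varies with angle.

    The boundary is ``r(theta) = radius * (1 + roughness * s(theta))`` with
    ``s`` a zero-mean band-limited Fourier series, so component areas are
    close to, but deliberately not exactly, ``pi r^2``.
    """
    h, w = shape
    n_harm = 4
    amp = rng.normal(0.0, 1.0, n_harm) / np.sqrt(n_harm)
    phase = rng.uniform(0, 2 * np.pi, n_harm)
    rmax = radius * (1 + roughness * 2.5)
    r0 = max(0, int(np.floor(cy - rmax)))
    r1 = min(h, int(np.ceil(cy + rmax)) + 1)
    c0 = max(0, int(np.floor(cx - rmax)))
    c1 = min(w, int(np.ceil(cx + rmax)) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx - cx
    dy = yy - cy
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    s = np.zeros_like(theta)
    for k in range(n_harm):
        s += amp[k] * np.cos((k + 2) * theta + phase[k])
    boundary = radius * (1 + roughness * s)
    sub = dist <= boundary
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = sub
    return out


def _sample_height(hm: HeightModel, rng: np.random.Generator) -> float:
    """Mostly-shallow height with a thin tall tail (metres)."""
    if rng.random() < hm.tall_fraction:
        return float(rng.uniform(0.6, hm.tall_tail_max_m))
    h = rng.gamma(2.0, hm.short_mode_m / 2.0) + 0.03
    return float(min(h, 0.6))


def _canopy_profile(dist: np.ndarray, radius: float) -> np.ndarray:
    """Relative canopy height: plateau core, cosine falloff at the rim."""
    core = 0.6 * radius
    prof = np.ones_like(dist)
    rim = dist > core
    t = np.clip((dist[rim] - core) / max(radius - core, 1e-9), 0, 1)
    prof[rim] = 0.3 + 0.7 * 0.5 * (1 + np.cos(np.pi * t))
    return prof


def _smooth_field(
    shape: tuple[int, int], rng: np.random.Generator, coarse: int = 9
) -> np.ndarray:
    """Smooth zero-mean field with unit sd, from upsampled coarse noise."""
    h, w = shape
    grid = rng.normal(0.0, 1.0, (coarse, coarse))
    field = ndimage.zoom(grid, (h / coarse, w / coarse), order=3, mode="nearest")
    field = field[:h, :w]
    if field.shape != (h, w):  # zoom can undershoot by a row/col
        field = np.pad(field, ((0, h - field.shape[0]), (0, w - field.shape[1])), mode="edge")
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def _paint_class_blobs(
    free: np.ndarray,
    target_px: int,
    blob_radius: tuple[float, float],
    rng: np.random.Generator,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Accumulate irregular blobs on free pixels until ``target_px`` reached.

    The last blob is trimmed (farthest pixels first) so the painted pixel
    count matches the target exactly whenever enough free space exists.
    """
    h, w = free.shape
    mask = np.zeros((h, w), dtype=bool)
    count = 0
    for _ in range(max_iter):
        if count >= target_px:
            break
        r = rng.uniform(*blob_radius)
        cx = rng.uniform(r, w - r)
        cy = rng.uniform(r, h - r)
        blob = _blob_mask((h, w), cx, cy, r, rng) & free & ~mask
        n_new = int(blob.sum())
        if n_new == 0:
            continue
        if count + n_new > target_px:
            ys, xs = np.nonzero(blob)
            d = np.hypot(xs - cx, ys - cy)
            keep = np.argsort(d)[: target_px - count]
            blob = np.zeros_like(blob)
            blob[ys[keep], xs[keep]] = True
            n_new = target_px - count
        mask |= blob
        count += n_new
    return mask


def generate_scene(cfg: SceneConfig) -> OrthomosaicScene:
    """Render a full synthetic scene with exact ground-truth bookkeeping.

    Rendering order: soil background with reddish confounder patches, then
    water / tree / yellow-bush / dead-tree blobs painted onto still-free soil
    until each class hits its target pixel count, then blueberry bushes at
    clustered centroids (radii drawn from the configured range; when
    ``bush_count`` is None, radii are rescaled within the range so the
    realized blueberry fraction lands on target).  The DEM is smooth ground
    + hassock noise, with each bush's canopy bump replacing the ground noise
    under its pixels.  Ground points are sampled just outside each bush.
    """
    cfg.validate()
    h, w = cfg.height_px, cfg.width_px
    n_px = h * w
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))

    # --- blueberry centroids and radii -----------------------------------
    rmin, rmax = cfg.bush_radius_range_px
    bb_target = cfg.class_fractions.get("blueberry", 0.0) * n_px
    if cfg.bush_count is not None:
        n_bush = cfg.bush_count
    else:
        n_bush = _estimated_bush_count(cfg)
    pattern = generate_point_pattern(cfg, n_points=n_bush)
    radii = rng.uniform(rmin, rmax, n_bush)
    if cfg.bush_count is None and n_bush > 0 and bb_target > 0:
        # rescale within the legal range so sum(pi r^2) ~= target pixels
        scale = math.sqrt(bb_target / (np.pi * (radii**2).sum()))
        radii = np.clip(radii * scale, rmin * 1.02, rmax * 0.98)

    # --- masks ------------------------------------------------------------
    masks = {name: np.zeros((h, w), dtype=bool) for name in CLASSES}
    bb_mask = masks["blueberry"]
    planted: list[PlantedBush] = []
    for i in range(n_bush):
        r = float(radii[i])
        cx = pattern.points[i, 0] / cfg.pixel_size_m
        cy = h - 1 - pattern.points[i, 1] / cfg.pixel_size_m
        pad = r * 1.35
        cx = float(np.clip(cx, pad, w - 1 - pad)) if w - 1 > 2 * pad else (w - 1) / 2
        cy = float(np.clip(cy, pad, h - 1 - pad)) if h - 1 > 2 * pad else (h - 1) / 2
        blob = _blob_mask((h, w), cx, cy, r, rng)
        if not blob.any():
            raise PlacementError(
                f"bush {i} of radius {r:.1f}px cannot be placed in a "
                f"{w}x{h} frame"
            )
        bb_mask |= blob
        height = _sample_height(cfg.height_model, rng)
        planted.append(PlantedBush((cx, cy), r, height))

    free = ~bb_mask
    blob_r_cap = max(8.0, math.sqrt(0.002 * n_px / math.pi))
    for name in ("water", "tree", "yellow_bush", "dead_tree"):
        frac = cfg.class_fractions.get(name, 0.0)
        if frac <= 0:
            continue
        target = int(round(frac * n_px))
        m = _paint_class_blobs(free, target, (6.0, blob_r_cap), rng)
        masks[name] = m
        free &= ~m
    masks["soil"] = free.copy()

    # --- RGB ---------------------------------------------------------------
    rgb = np.empty((h, w, 3), dtype=np.float64)
    rgb[:] = cfg.palette["soil"]
    # reddish soil confounders: smooth-field threshold -> contiguous patches
    if cfg.confounder_fraction > 0:
        fieldv = _smooth_field((h, w), rng, coarse=max(6, min(h, w) // 60))
        thr = np.quantile(fieldv, 1 - cfg.confounder_fraction)
        conf = (fieldv > thr) & free
        rgb[conf] = CONFOUNDER_COLOR
    for name in CLASSES:
        if name == "soil":
            continue
        rgb[masks[name]] = cfg.palette[name]
    rgb += rng.normal(0.0, 6.0, (h, w, 3))
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    # --- DEM ----------------------------------------------------------------
    hm = cfg.height_model
    ground = 0.15 * _smooth_field((h, w), rng, coarse=7)
    hassock = rng.normal(0.0, hm.hassock_noise_sd_m, (h, w))
    dem = ground + hassock
    bump = np.zeros((h, w), dtype=np.float64)
    for bush in planted:
        cx, cy = bush.centroid_xy
        r_eff = bush.base_radius_px * 1.35
        r0 = max(0, int(cy - r_eff))
        r1 = min(h, int(cy + r_eff) + 1)
        c0 = max(0, int(cx - r_eff))
        c1 = min(w, int(cx + r_eff) + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dist = np.hypot(xx - cx, yy - cy)
        prof = bush.true_height_m * _canopy_profile(dist, bush.base_radius_px)
        np.maximum(bump[r0:r1, c0:c1], prof, out=bump[r0:r1, c0:c1])
    canopy = bb_mask
    dem[canopy] = ground[canopy] + bump[canopy] + rng.normal(
        0.0, 0.02, int(canopy.sum())
    )

    # --- ground points near bushes -----------------------------------------
    ground_points: list[GroundPoint] = []
    for bush in planted:
        cx, cy = bush.centroid_xy
        for _ in range(12):
            ang = rng.uniform(0, 2 * np.pi)
            d = bush.base_radius_px * 1.35 + rng.uniform(2, 8)
            gx = int(round(cx + d * math.cos(ang)))
            gy = int(round(cy + d * math.sin(ang)))
            if 0 <= gx < w and 0 <= gy < h and not bb_mask[gy, gx]:
                ground_points.append(GroundPoint(gx, gy, float(dem[gy, gx])))
                break

    n_comp = int(ndimage.label(bb_mask, structure=EIGHT_CONN)[1])
    truth = SceneTruth(
        planted=planted,
        merged_component_count=n_comp,
        class_pixel_counts={c: int(masks[c].sum()) for c in CLASSES},
        realized_fractions={c: float(masks[c].sum()) / n_px for c in CLASSES},
    )
    scene = OrthomosaicScene(
        rgb=rgb,
        dem=dem,
        masks=masks,
        ground_points=ground_points,
        pixel_size_m=cfg.pixel_size_m,
        site_id=cfg.site_id,
        truth=truth,
    )
    scene.validate()
    return scene
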