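"""Core scene container shared by every stage of the pipeline.

Coordinate convention (used everywhere in the package): rasters are row-major
with the origin at the top-left pixel, 0-based indices, half-open tile
intervals.  Metric coordinates are ``x = col * pixel_size_m`` (east) and
``y = (height_px - 1 - row) * pixel_size_m`` (north).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The six annotation classes of a fully labeled wetland orthomosaic.
CLASSES = ("blueberry", "tree", "yellow_bush", "soil", "water", "dead_tree")

#: Classes counted as living vegetation when reporting vegetation shares.
LIVING_CLASSES = ("blueberry", "tree", "yellow_bush")


class SceneValidationError(ValueError):
    """Raised when scene rasters are inconsistent (shape, overlap, dtype)."""


@dataclass
class GroundPoint:
    """A hand-annotated ground elevation sample near a bush."""

    x_px: float
    y_px: float
    elevation_m: float


@dataclass
class PlantedBush:
    """Generator bookkeeping for one planted bush (ground truth)."""

    centroid_xy: tuple[float, float]  # (x_px, y_px)
    base_radius_px: float
    true_height_m: float


@dataclass
class SceneTruth:
    """Exact ground truth recorded while a synthetic scene is rendered.

    ``merged_component_count`` is the number of connected components of the
    final blueberry mask: bushes planted so close that their canopies touch
    are annotated (and therefore counted) as one bush, exactly as happens
    with hand-drawn mask annotations.
    """

    planted: list[PlantedBush] = field(default_factory=list)
    merged_component_count: int = 0
    class_pixel_counts: dict[str, int] = field(default_factory=dict)
    realized_fractions: dict[str, float] = field(default_factory=dict)


@dataclass
class OrthomosaicScene:
    """A co-registered orthomosaic: RGB, DEM, per-class masks and points.

    The DEM is in metres above the site datum (0 = smooth ground level).
    ``dem`` may be ``None`` for sites where only the RGB mosaic was
    annotated; height operations are then unavailable.
    """

    rgb: np.ndarray  # H x W x 3 uint8
    dem: Optional[np.ndarray]  # H x W float, metres
    masks: dict[str, np.ndarray]  # class -> H x W bool
    ground_points: list[GroundPoint]
    pixel_size_m: float
    site_id: str
    truth: Optional[SceneTruth] = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    @property
    def site_area_ha(self) -> float:
        h, w = self.shape
        return h * w * self.pixel_size_m**2 / 10_000.0

    def validate(self) -> None:
        """Check the scene invariants; raise :class:`SceneValidationError`."""
        h, w = self.shape
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise SceneValidationError("rgb must be H x W x 3")
        if self.dem is not None and self.dem.shape != (h, w):
            raise SceneValidationError(
                f"DEM shape {self.dem.shape} != RGB shape {(h, w)}"
            )
        overlap = np.zeros((h, w), dtype=np.int16)
        for name, mask in self.masks.items():
            if mask.shape != (h, w):
                raise SceneValidationError(
                    f"mask {name!r} shape {mask.shape} != RGB shape {(h, w)}"
                )
            if mask.dtype != bool:
                raise SceneValidationError(f"mask {name!r} must be boolean")
            overlap += mask
        n_over = int((overlap > 1).sum())
        if n_over:
            raise SceneValidationError(
                f"class masks overlap on {n_over} pixels; masks must be "
                "mutually exclusive on annotated pixels"
            )
        if self.pixel_size_m <= 0:
            raise SceneValidationError("pixel_size_m must be positive")
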