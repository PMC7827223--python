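"""Tiling of orthomosaics into multi-label patches, augmentation, balancing.

The orthomosaic is divided into non-overlapping axis-parallel patches of side
100 px (chosen so a patch is on the order of one bush: canopy radii span
20-100 px); trailing strips that do not fill a patch are dropped.  A patch
carries the *set* of classes annotated inside it (multi-label: a patch with
soil, a bush edge and some water carries all three labels) and the fraction
of its pixels annotated blueberry, which the classifier regresses alongside
the presence labels.

Six geometry-preserving augmentations generate synthetic blueberry patches:
up/down flip, left/right flip, small central rotation, Gaussian blur, linear
contrast change and localized elastic deformation.  All leave the label set
unchanged and are deterministic per seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .scene import OrthomosaicScene

TRANSFORMS = (
    "flip_ud",
    "flip_lr",
    "rotate",
    "blur",
    "contrast",
    "elastic",
)

DEFAULT_SIDE_PX = 100
REFINED_SIDE_PX = 25


@dataclass
class Patch:
    """One tile of an orthomosaic with its multi-label annotation."""

    site_id: str
    origin: tuple[int, int]  # (row, col) of the top-left pixel
    side_px: int
    image: np.ndarray  # side x side x 3 uint8
    labels: frozenset[str]
    blueberry_pixel_fraction: float

    @property
    def has_blueberry(self) -> bool:
        return self.blueberry_pixel_fraction > 0


def tile_orthomosaic(
    scene: OrthomosaicScene, side_px: int = DEFAULT_SIDE_PX
) -> list[Patch]:
    """Non-overlapping grid tiles with label sets and blueberry fractions."""
    h, w = scene.shape
    if h < side_px or w < side_px:
        raise ValueError(
            f"scene {w}x{h} is smaller than one {side_px}px tile"
        )
    patches = []
    for r0 in range(0, h - side_px + 1, side_px):
        for c0 in range(0, w - side_px + 1, side_px):
            sl = (slice(r0, r0 + side_px), slice(c0, c0 + side_px))
            labels = frozenset(
                name for name, m in scene.masks.items() if m[sl].any()
            )
            bb = scene.masks["blueberry"][sl].sum() if "blueberry" in scene.masks else 0
            patches.append(
                Patch(
                    site_id=scene.site_id,
                    origin=(r0, c0),
                    side_px=side_px,
                    image=scene.rgb[sl],
                    labels=labels,
                    blueberry_pixel_fraction=float(bb) / side_px**2,
                )
            )
    return patches


def augment_patch(patch: Patch, transform_id: str, seed: int = 0) -> Patch:
    """Apply one of the six augmentations; labels are preserved.

    Randomized magnitudes (rotation angle, blur sigma, contrast gain/bias,
    elastic field) are drawn from a generator seeded with ``seed`` so that
    augmentation is reproducible.
    """
    if transform_id not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform_id!r}; one of {TRANSFORMS}")
    rng = np.random.default_rng(seed)
    img = patch.image.astype(np.float64)
    if transform_id == "flip_ud":
        out = img[::-1]
    elif transform_id == "flip_lr":
        out = img[:, ::-1]
    elif transform_id == "rotate":
        angle = float(rng.uniform(-15.0, 15.0))
        out = sktransform.rotate(
            img, angle, mode="reflect", preserve_range=True, order=1
        )
    elif transform_id == "blur":
        sigma = float(rng.uniform(0.5, 1.5))
        out = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
    elif transform_id == "contrast":
        gain = float(rng.uniform(0.9, 1.1))
        bias = float(rng.uniform(-10.0, 10.0))
        out = img * gain + bias
    else:  # elastic
        alpha, sigma = 8.0, 6.0
        dx = ndimage.gaussian_filter(rng.normal(size=img.shape[:2]), sigma) * alpha
        dy = ndimage.gaussian_filter(rng.normal(size=img.shape[:2]), sigma) * alpha
        rr, cc = np.meshgrid(
            np.arange(img.shape[0]), np.arange(img.shape[1]), indexing="ij"
        )
        coords = np.array([rr + dy, cc + dx])
        out = np.stack(
            [
                ndimage.map_coordinates(img[..., k], coords, order=1, mode="reflect")
                for k in range(3)
            ],
            axis=-1,
        )
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return replace(patch, image=out)


def balance_dataset(
    patches: Sequence[Patch],
    blueberry_upsample_factor: int = 12,
    soil_downsample_fraction: float = 0.5,
    transforms: Sequence[str] = TRANSFORMS,
    seed: int = 0,
    split: str = "train",
) -> list[Patch]:
    """Counter the extreme class imbalance of the training split.

    Each blueberry-containing patch contributes the original plus
    ``blueberry_upsample_factor`` augmented copies (transforms cycled, with
    seeded random magnitudes); soil-only patches are subsampled to
    ``soil_downsample_fraction`` of their number.  Balancing a validation or
    test split would bias the evaluation and is refused.
    """
    if split != "train":
        raise ValueError(f"balancing is only allowed on the train split, not {split!r}")
    if not 0 < soil_downsample_fraction <= 1:
        raise ValueError("soil_downsample_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out: list[Patch] = []
    soil_only = [p for p in patches if p.labels == frozenset({"soil"})]
    n_keep = int(round(len(soil_only) * soil_downsample_fraction))
    kept_soil = set(
        rng.choice(len(soil_only), size=n_keep, replace=False).tolist()
    ) if soil_only else set()
    n_blueberry = 0
    soil_idx = 0
    for p in patches:
        if p.labels == frozenset({"soil"}):
            if soil_idx in kept_soil:
                out.append(p)
            soil_idx += 1
            continue
        out.append(p)
        if p.has_blueberry:
            n_blueberry += 1
            for k in range(blueberry_upsample_factor):
                tid = transforms[k % len(transforms)]
                out.append(augment_patch(p, tid, seed=int(rng.integers(2**31))))
    if n_blueberry == 0:
        warnings.warn("no blueberry patches to upsample", stacklevel=2)
    return out
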