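"""Classifier training, leave-one-mosaic-out evaluation and refinement.

Cross-validation rotates whole orthomosaics through the train / validation /
test roles (leave-one-mosaic-out) so that no patches of the test mosaic leak
into training.  Prediction paints the full footprint of every positive
100x100 patch into a coarse binary mask; refinement splits each positive
patch into a 4x4 grid of 25x25 sub-patches, upsamples each to the network
input size and re-classifies it, producing a refined mask that is by
construction a subset of the coarse mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evaluation import ConfusionCounts, confusion_counts, gt_cover, metrics
from .network import BACKBONES, N_CLASSES, PatchNet
from .patches import TRANSFORMS, Patch, balance_dataset, tile_orthomosaic
from .scene import CLASSES, OrthomosaicScene


def default_class_weights() -> dict[str, float]:
    """Blueberry weighted 8x the soil class and 4x every other class."""
    w = {c: 2.0 for c in CLASSES}
    w["soil"] = 1.0
    w["blueberry"] = 8.0
    return w


@dataclass
class TrainConfig:
    """Training settings for the imbalance-aware multi-label classifier."""

    backbone: str = "tiny_mlp"
    weights_mode: str = "unfrozen"  # frozen: only the head trains
    class_loss_weights: dict[str, float] = field(default_factory=default_class_weights)
    blueberry_upsample_factor: int = 12
    soil_downsample_fraction: float = 0.5
    augmentations: tuple[str, ...] = TRANSFORMS
    epochs: int = 40
    learning_rate: float = 0.01
    batch_size: int = 32
    seed: int = 0
    threshold: float = 0.5
    input_size: int = 16
    fraction_loss_weight: float = 1.0
    patch_side_px: int = 100

    def validate(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.weights_mode not in ("frozen", "unfrozen"):
            raise ValueError("weights_mode must be 'frozen' or 'unfrozen'")
        if any(w <= 0 for w in self.class_loss_weights.values()):
            raise ValueError("class loss weights must be positive")
        if not 0 < self.soil_downsample_fraction <= 1:
            raise ValueError("soil_downsample_fraction must be in (0, 1]")


class DataLeakageError(ValueError):
    """Raised when the same site appears in two cross-validation roles."""


@dataclass
class TrainedModel:
    net: PatchNet
    cfg: TrainConfig
    classes: tuple[str, ...]
    patch_side_px: int
    log: list[dict] = field(default_factory=list)

    def predict_sets(self, images: np.ndarray) -> list[set[str]]:
        probs = self.net.predict_proba(images)
        return [
            {self.classes[c] for c in range(N_CLASSES) if probs[i, c] >= self.cfg.threshold}
            for i in range(len(images))
        ]


@dataclass
class PredictionMask:
    """Binary raster of predicted-blueberry patch footprints."""

    site_id: str
    granularity: str  # coarse_100 | refined_25
    mask: np.ndarray  # H x W bool


def _encode(patches: Sequence[Patch]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    images = np.stack([p.image for p in patches])
    y = np.zeros((len(patches), N_CLASSES))
    for i, p in enumerate(patches):
        for c, name in enumerate(CLASSES):
            if name in p.labels:
                y[i, c] = 1.0
    frac = np.array([p.blueberry_pixel_fraction for p in patches])
    return images, y, frac


def train_classifier(
    train_patches: Sequence[Patch],
    val_patches: Sequence[Patch],
    cfg: TrainConfig,
) -> TrainedModel:
    """Train the dual-loss multi-label classifier on pre-balanced patches.

    Raises :class:`DataLeakageError` if a site id occurs in both splits.
    The returned model carries a per-epoch log (training loss, validation
    blueberry TPR and accuracy) and is fully reproducible from cfg + seed.
    """
    cfg.validate()
    train_sites = {p.site_id for p in train_patches}
    val_sites = {p.site_id for p in val_patches}
    if train_sites & val_sites:
        raise DataLeakageError(
            f"sites {sorted(train_sites & val_sites)} appear in train and validation"
        )
    rng = np.random.default_rng(cfg.seed)
    net = PatchNet.initialize(cfg.backbone, cfg.input_size, rng)
    images, y, frac = _encode(train_patches)
    feats = net.featurize(images)
    weights = np.array([cfg.class_loss_weights[c] for c in CLASSES])
    frozen = cfg.weights_mode == "frozen"
    val_feats = val_y = None
    if len(val_patches):
        val_images, val_y, _ = _encode(val_patches)
        val_feats = net.featurize(val_images)
    log: list[dict] = []
    n = len(feats)
    bb_idx = CLASSES.index("blueberry")
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = net.loss_and_grads(
                feats[idx], y[idx], frac[idx], weights, cfg.fraction_loss_weight
            )
            net.adam_step(grads, cfg.learning_rate, frozen)
            epoch_loss += loss * len(idx)
        entry = {"epoch": epoch, "train_loss": epoch_loss / n}
        if val_feats is not None:
            _, vp = net.forward(val_feats)
            pred = vp[:, bb_idx] >= cfg.threshold
            truth = val_y[:, bb_idx] > 0
            counts = confusion_counts(pred, truth, "patch")
            m = metrics(counts)
            entry["val_blueberry_tpr"] = m["tpr"]
            entry["val_acc"] = m["acc"]
        log.append(entry)
    return TrainedModel(net, cfg, CLASSES, cfg.patch_side_px, log)


def predict_patches(
    model: TrainedModel,
    patches: Sequence[Patch],
    scene_shape: tuple[int, int],
) -> tuple[list[set[str]], PredictionMask]:
    """Per-patch class sets and the coarse blueberry footprint mask."""
    if patches and patches[0].side_px != model.patch_side_px:
        raise ValueError(
            f"patch side {patches[0].side_px} != model patch side "
            f"{model.patch_side_px}"
        )
    mask = np.zeros(scene_shape, dtype=bool)
    if not patches:
        return [], PredictionMask("", "coarse_100", mask)
    images = np.stack([p.image for p in patches])
    label_sets = model.predict_sets(images)
    for p, labels in zip(patches, label_sets):
        if "blueberry" in labels:
            r0, c0 = p.origin
            mask[r0 : r0 + p.side_px, c0 : c0 + p.side_px] = True
    return label_sets, PredictionMask(patches[0].site_id, "coarse_100", mask)


def refine_predictions(
    model: TrainedModel,
    positive_patches: Sequence[Patch],
    scene_shape: tuple[int, int],
) -> PredictionMask:
    """Re-classify the 4x4 sub-patches of each positive coarse patch.

    Each positive 100x100 patch is divided into 16 sub-patches of side 25,
    each upsampled (bilinearly, inside the network's featurizer) to the
    network input size and re-classified; the refined mask is the union of
    positive sub-patch footprints and is always a subset of the coarse mask.
    """
    mask = np.zeros(scene_shape, dtype=bool)
    site = positive_patches[0].site_id if positive_patches else ""
    for p in positive_patches:
        sub = p.side_px // 4
        tiles = []
        origins = []
        for i in range(4):
            for j in range(4):
                tiles.append(p.image[i * sub : (i + 1) * sub, j * sub : (j + 1) * sub])
                origins.append((p.origin[0] + i * sub, p.origin[1] + j * sub))
        label_sets = model.predict_sets(np.stack(tiles))
        for (r0, c0), labels in zip(origins, label_sets):
            if "blueberry" in labels:
                mask[r0 : r0 + sub, c0 : c0 + sub] = True
    return PredictionMask(site, "refined_25", mask)


# ---------------------------------------------------------------------------
# leave-one-mosaic-out


@dataclass
class FoldResult:
    test_site: str
    val_site: str
    train_sites: tuple[str, ...]
    patch_counts: ConfusionCounts
    blueberry_tpr: Optional[float]
    acc: Optional[float]
    dice_coarse: Optional[float]
    dice_refined: Optional[float]
    gt_cover_coarse: Optional[float]
    gt_cover_refined: Optional[float]


@dataclass
class LomoResult:
    folds: list[FoldResult]

    def pooled(self) -> dict[str, Optional[float]]:
        """Mean of per-fold metrics (macro) plus count-pooled patch metrics."""
        def mean_of(name: str) -> Optional[float]:
            vals = [getattr(f, name) for f in self.folds if getattr(f, name) is not None]
            return float(np.mean(vals)) if vals else None

        out = {
            name: mean_of(name)
            for name in (
                "blueberry_tpr",
                "acc",
                "dice_coarse",
                "dice_refined",
                "gt_cover_coarse",
                "gt_cover_refined",
            )
        }
        total = self.folds[0].patch_counts
        for f in self.folds[1:]:
            total = total + f.patch_counts
        micro = metrics(total)
        out["micro_blueberry_tpr"] = micro["tpr"]
        out["micro_acc"] = micro["acc"]
        return out


def _tiled_extent(shape: tuple[int, int], side: int) -> tuple[slice, slice]:
    return slice(0, shape[0] // side * side), slice(0, shape[1] // side * side)


def evaluate_masks(
    scene: OrthomosaicScene,
    coarse: PredictionMask,
    refined: Optional[PredictionMask],
    side_px: int,
) -> dict[str, Optional[float]]:
    """Pixel-level Dice and GT-cover of coarse (and refined) masks.

    Metrics are computed over the tiled extent of the scene (trailing strips
    that never entered a patch are excluded from both masks and truth).
    """
    rs, cs = _tiled_extent(scene.shape, side_px)
    truth = scene.masks["blueberry"][rs, cs]
    out: dict[str, Optional[float]] = {}
    m = metrics(confusion_counts(coarse.mask[rs, cs], truth, "pixel"))
    out["dice_coarse"] = m["dice"]
    out["gt_cover_coarse"] = gt_cover(coarse.mask[rs, cs], truth)
    if refined is not None:
        m = metrics(confusion_counts(refined.mask[rs, cs], truth, "pixel"))
        out["dice_refined"] = m["dice"]
        out["gt_cover_refined"] = gt_cover(refined.mask[rs, cs], truth)
    return out


def leave_one_mosaic_out(
    scenes: Sequence[OrthomosaicScene],
    cfg: TrainConfig,
) -> LomoResult:
    """Rotate whole mosaics through train / validation / test roles.

    With n scenes there are n folds; in fold k scene k is the test mosaic,
    scene (k+1) mod n the validation mosaic and the rest train.  Training
    patches are balanced (upsampling + soil downsampling); validation and
    test patches never are.  Reported pooled metrics are fold averages.
    """
    if len(scenes) < 3:
        raise ValueError("leave-one-mosaic-out needs at least 3 scenes")
    sites = [s.site_id for s in scenes]
    if len(set(sites)) != len(sites):
        raise DataLeakageError("scene site ids must be unique")
    tiles = {s.site_id: tile_orthomosaic(s, cfg.patch_side_px) for s in scenes}
    folds = []
    n = len(scenes)
    for k in range(n):
        test_scene = scenes[k]
        val_scene = scenes[(k + 1) % n]
        train_scenes = [scenes[i] for i in range(n) if i not in (k, (k + 1) % n)]
        train_patches: list[Patch] = []
        for s in train_scenes:
            train_patches.extend(tiles[s.site_id])
        train_patches = balance_dataset(
            train_patches,
            cfg.blueberry_upsample_factor,
            cfg.soil_downsample_fraction,
            cfg.augmentations,
            seed=cfg.seed + k,
        )
        model = train_classifier(train_patches, tiles[val_scene.site_id], cfg)
        test_patches = tiles[test_scene.site_id]
        label_sets, coarse = predict_patches(model, test_patches, test_scene.shape)
        positive = [
            p for p, labels in zip(test_patches, label_sets) if "blueberry" in labels
        ]
        refined = refine_predictions(model, positive, test_scene.shape)
        pred = np.array(["blueberry" in ls for ls in label_sets])
        truth = np.array([p.has_blueberry for p in test_patches])
        counts = confusion_counts(pred, truth, "patch")
        patch_m = metrics(counts)
        pix = evaluate_masks(test_scene, coarse, refined, cfg.patch_side_px)
        folds.append(
            FoldResult(
                test_site=test_scene.site_id,
                val_site=val_scene.site_id,
                train_sites=tuple(s.site_id for s in train_scenes),
                patch_counts=counts,
                blueberry_tpr=patch_m["tpr"],
                acc=patch_m["acc"],
                dice_coarse=pix["dice_coarse"],
                dice_refined=pix["dice_refined"],
                gt_cover_coarse=pix["gt_cover_coarse"],
                gt_cover_refined=pix["gt_cover_refined"],
            )
        )
    return LomoResult(folds)
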