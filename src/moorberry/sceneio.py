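"""Reading and writing scenes as plain rasters with a JSON manifest.

A scene on disk is: an RGB PNG, a float32 TIFF DEM, one 1-bit PNG per class
named ``<site>_<class>.png``, ground points and bush centroids as CSV
(columns x_px, y_px, value) and GeoJSON, plus a ``manifest.json`` linking the
files with the pixel size, per-file SHA-256 checksums and, for synthetic
scenes, the generator's ground-truth record.  The geospatial stack is not
required: pixel size travels in the manifest instead of GeoTIFF tags.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .scene import (
    CLASSES,
    GroundPoint,
    OrthomosaicScene,
    PlantedBush,
    SceneTruth,
    SceneValidationError,
)

MASK_THRESHOLD = 128  # grayscale masks binarize at 0/255 threshold 128


class ManifestError(ValueError):
    """Raised for missing files or inconsistent raster dimensions."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _points_geojson(points: list[tuple[float, float, float]]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"value": v},
            }
            for x, y, v in points
        ],
    }


def write_scene(scene: OrthomosaicScene, out_dir: str | Path) -> Path:
    """Write all scene artifacts; returns the manifest path."""
    scene.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    site = scene.site_id
    files: dict[str, str] = {}

    rgb_name = f"{site}_rgb.png"
    Image.fromarray(scene.rgb).save(out / rgb_name)
    files["rgb"] = rgb_name

    if scene.dem is not None:
        dem_name = f"{site}_dem.tif"
        tifffile.imwrite(out / dem_name, scene.dem.astype(np.float32))
        files["dem"] = dem_name

    for name in CLASSES:
        if name not in scene.masks:
            continue
        mask_name = f"{site}_{name}.png"
        Image.fromarray(scene.masks[name]).convert("1").save(out / mask_name)
        files[f"mask_{name}"] = mask_name

    gp_name = f"{site}_ground_points.csv"
    pd.DataFrame(
        [(g.x_px, g.y_px, g.elevation_m) for g in scene.ground_points],
        columns=["x_px", "y_px", "value"],
    ).to_csv(out / gp_name, index=False)
    files["ground_points"] = gp_name
    gp_geo = f"{site}_ground_points.geojson"
    (out / gp_geo).write_text(
        json.dumps(
            _points_geojson(
                [(g.x_px, g.y_px, g.elevation_m) for g in scene.ground_points]
            )
        )
    )
    files["ground_points_geojson"] = gp_geo

    manifest = {
        "site_id": site,
        "pixel_size_m": scene.pixel_size_m,
        "files": files,
        "checksums": {k: _sha256(out / v) for k, v in files.items()},
    }
    if scene.truth is not None:
        manifest["truth"] = {
            "planted": [dataclasses.asdict(b) for b in scene.truth.planted],
            "merged_component_count": scene.truth.merged_component_count,
            "class_pixel_counts": scene.truth.class_pixel_counts,
            "realized_fractions": scene.truth.realized_fractions,
        }
    path = out / f"{site}_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def binarize_mask(arr: np.ndarray) -> np.ndarray:
    """Grayscale 0/255 annotation layer -> boolean mask (threshold 128)."""
    if arr.dtype == bool:
        return arr
    return np.asarray(arr) >= MASK_THRESHOLD


def read_scene(manifest_path: str | Path) -> OrthomosaicScene:
    """Load a scene from its manifest; raster dimensions are cross-checked.

    A missing DEM entry is allowed (height operations are then unavailable);
    a missing class-mask file is an error naming the file.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    files = manifest["files"]

    rgb_path = base / files["rgb"]
    if not rgb_path.exists():
        raise ManifestError(f"missing RGB raster: {rgb_path}")
    rgb = np.asarray(Image.open(rgb_path).convert("RGB"))
    shape = rgb.shape[:2]

    dem = None
    if "dem" in files:
        dem_path = base / files["dem"]
        if not dem_path.exists():
            raise ManifestError(f"missing DEM raster: {dem_path}")
        dem = tifffile.imread(dem_path).astype(np.float64)
        if dem.shape != shape:
            raise ManifestError(
                f"DEM {dem_path.name} has shape {dem.shape}, RGB has {shape}"
            )

    masks: dict[str, np.ndarray] = {}
    for name in CLASSES:
        key = f"mask_{name}"
        if key not in files:
            continue
        mpath = base / files[key]
        if not mpath.exists():
            raise ManifestError(f"missing class mask file: {mpath}")
        arr = np.asarray(Image.open(mpath).convert("L"))
        if arr.shape != shape:
            raise ManifestError(
                f"mask {mpath.name} has shape {arr.shape}, RGB has {shape}"
            )
        masks[name] = binarize_mask(arr)

    ground_points: list[GroundPoint] = []
    if "ground_points" in files:
        gp_path = base / files["ground_points"]
        if gp_path.exists():
            df = pd.read_csv(gp_path)
            ground_points = [
                GroundPoint(r.x_px, r.y_px, r.value) for r in df.itertuples()
            ]

    truth: Optional[SceneTruth] = None
    if "truth" in manifest:
        t = manifest["truth"]
        truth = SceneTruth(
            planted=[
                PlantedBush(tuple(b["centroid_xy"]), b["base_radius_px"], b["true_height_m"])
                for b in t["planted"]
            ],
            merged_component_count=t["merged_component_count"],
            class_pixel_counts={k: int(v) for k, v in t["class_pixel_counts"].items()},
            realized_fractions=t["realized_fractions"],
        )

    scene = OrthomosaicScene(
        rgb=rgb,
        dem=dem,
        masks=masks,
        ground_points=ground_points,
        pixel_size_m=float(manifest["pixel_size_m"]),
        site_id=manifest["site_id"],
        truth=truth,
    )
    try:
        scene.validate()
    except SceneValidationError as exc:
        raise ManifestError(str(exc)) from exc
    return scene
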