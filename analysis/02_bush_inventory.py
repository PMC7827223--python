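"""Per-bush allometry of the simulated corpus: counts, areas, heights.

Reads the scene manifests written by 01_simulate_scenes.py, labels bushes as
8-connected mask components, computes areas in m², DEM-based max and median
heights against the nearest annotated ground point, and writes one inventory
CSV per site plus a pooled survey-style summary table and 0.5 m height
histograms under results/inventory/.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from moorberry.allometry import (
    bin_distribution,
    compute_bush_heights,
    compute_class_areas,
    label_bushes,
    round_half_up,
    summarize_inventory,
)
from moorberry.sceneio import read_scene

HEIGHT_EDGES = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scenes", type=Path, default=Path("results/scenes"))
    ap.add_argument("--out", type=Path, default=Path("results/inventory"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table_rows = []
    for manifest in sorted(args.scenes.glob("*/*_manifest.json")):
        scene = read_scene(manifest)
        records = label_bushes(scene.masks["blueberry"], scene.pixel_size_m)
        for stat in ("max", "median"):
            compute_bush_heights(
                scene.dem, records, scene.ground_points, stat,
                mask=scene.masks["blueberry"],
            )
        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
            args.out / f"{scene.site_id}_inventory.csv", index=False
        )
        compute_class_areas(scene.masks, scene.pixel_size_m).to_csv(
            args.out / f"{scene.site_id}_class_areas.csv"
        )
        for stat in ("max_height_m", "median_height_m"):
            bin_distribution(
                [getattr(r, stat) for r in records], HEIGHT_EDGES
            ).to_csv(args.out / f"{scene.site_id}_hist_{stat}.csv", index=False)

        s = summarize_inventory(records, scene.site_area_ha)
        table_rows.append(
            {
                "site": scene.site_id,
                "area_ha": round_half_up(s.site_area_ha, 2),
                "bush_count": s.bush_count,
                "bushes_per_ha": round_half_up(s.bushes_per_ha, 2),
                "bush_area_m2": round_half_up(s.total_bush_area_m2, 2),
                "area_per_bush_m2": round_half_up(s.mean_area_per_bush_m2, 2),
            }
        )
        print(
            f"{scene.site_id}: {s.bush_count} bushes, "
            f"{s.total_bush_area_m2:.2f} m2 total, "
            f"{s.mean_area_per_bush_m2:.2f} m2/bush"
        )
    table = pd.DataFrame(table_rows)
    table.to_csv(args.out / "inventory_table.csv", index=False)
    (args.out / "inventory_table.json").write_text(table.to_json(orient="records"))
    print(f"wrote {args.out / 'inventory_table.csv'}")


if __name__ == "__main__":
    main()
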