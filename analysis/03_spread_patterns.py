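"""Spatial spread of the incursion: clustering, density, hotspots, persistence.

Two inputs: (a) a survey-scale centroid pattern (400 x 400 m, 500 bushes at
the surveyed density) for the 3 m / 6 m distance clustering, the quartic
kernel density surface and the Gi* hotspot analysis; (b) the annotation
masks of the simulated corpus for 0-D persistence — disks grow at uniform
speed around uniformly sampled region points and the radii at which 1 / 10 /
50 / 90% of the initially distinct regions have fused summarize how spread
out the incursion is.  Writes tables and a persistence plot under
results/spread/.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from moorberry.sceneio import read_scene
from moorberry.spread import (
    cluster_points,
    gi_star,
    h0_persistence,
    kernel_density,
    sample_regions,
)
from moorberry.synthetic import generate_point_pattern, survey_pattern_config


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scenes", type=Path, default=Path("results/scenes"))
    ap.add_argument("--out", type=Path, default=Path("results/spread"))
    ap.add_argument("--ph-spacing", type=int, default=5)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    # --- survey-scale pattern: clustering, density, hotspots ---------------
    pattern = generate_point_pattern(survey_pattern_config(args.seed))
    rows = []
    for thr in (3.0, 6.0):
        table = cluster_points(pattern, thr)
        rows.append(table.summary())
        print(
            f"{thr:.0f} m clustering: {table.pct_grouped_3plus:.2f}% grouped "
            f"(3+), {table.n_singletons} singles, "
            f"largest group {table.largest_cluster_size}"
        )
        if thr == 3.0:
            events = []
            for cid in range(table.n_clusters):
                m = table.labels == cid
                events.append(
                    (
                        float(pattern.points[m, 0].mean()),
                        float(pattern.points[m, 1].mean()),
                        float(m.sum()),
                    )
                )
            hot = gi_star(events, neighborhood_m=25.0)
            pd.DataFrame([dataclasses.asdict(f) for f in hot.features]).to_csv(
                args.out / "hotspots.csv", index=False
            )
            print(f"hotspot bins: {hot.counts_by_bin()}")
    pd.DataFrame(rows).to_csv(args.out / "cluster_table.csv", index=False)

    density = kernel_density(pattern, cell_size_m=2.0, radius_m=15.0)
    np.savetxt(args.out / "density.csv", density.values, delimiter=",", fmt="%.6g")

    # --- persistence on the corpus annotation masks ------------------------
    ph_rows = {}
    for manifest in sorted(args.scenes.glob("*/*_manifest.json")):
        scene = read_scene(manifest)
        samples = sample_regions(scene.masks["blueberry"], args.ph_spacing)
        res = h0_persistence(samples, pixel_size_m=scene.pixel_size_m)
        ph_rows[scene.site_id] = {
            "region_count": res.region_count,
            "fused_fraction_radii_px": res.fused_fraction_radii,
            "fused_fraction_radii_m": res.radii_m(),
        }
        radii = ", ".join(
            f"{int(100 * f)}%: {r:.0f}px" for f, r in res.fused_fraction_radii.items()
        )
        print(f"{scene.site_id}: {res.region_count} regions; fused at {radii}")
    (args.out / "persistence.json").write_text(
        json.dumps(ph_rows, indent=1, default=float)
    )

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for site, row in ph_rows.items():
        pairs = sorted((float(f), r) for f, r in row["fused_fraction_radii_px"].items())
        ax.plot([r for _, r in pairs], [100 * f for f, _ in pairs], marker="o", label=site)
    ax.set_xlabel("merge radius (px)")
    ax.set_ylabel("fused regions (%)")
    ax.legend()
    fig.savefig(args.out / "persistence.png", dpi=110)
    print(f"wrote {args.out / 'persistence.png'}")


if __name__ == "__main__":
    main()
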