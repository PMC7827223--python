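# moorberry

Quantitative mapping of invasive blueberry (*Vaccinium corymbosum* ×
*angustifolium*) incursions in protected wetlands from annotated UAV
orthomosaics.

Raised bogs in their degeneration stages offer ideal conditions for feral
blueberries spreading out of commercial plantations, and ground surveys in
these protected areas are heavily restricted. Given a georeferenced RGB
orthomosaic (5–7 cm/pixel), a co-registered elevation model (DEM), per-class
binary annotation masks (blueberries, trees, yellow bushes, soil, water,
dead trees) and hand-annotated bush-centroid and ground-elevation points,
the package produces the full quantitative characterization a site manager
needs:

* **Allometry** — bushes are the 8-connected components of the blueberry
  mask; per bush the pixel area in m² and DEM-based heights
  `h = stat(DEM over bush) − z(nearest ground point)` for `stat ∈ {max,
  median}` (negative values clamped to 0: grass hassocks inflate apparent
  ground elevation). Site summaries report bush count, bushes/ha, total and
  mean area per bush, per-class area shares and the blueberry share of
  living vegetation.
* **Spread** — single-linkage distance clustering of bush centroids at 3 m
  and 6 m (share of bushes in groups of ≥ 3, singletons, largest group);
  quartic-kernel density surfaces `K(d) = 3/(πr²)(1 − d²/r²)²` in
  points/m²; Getis-Ord Gi* hotspot z-scores with fixed-distance binary
  weights binned at 90/95/99% confidence; and 0-D persistent homology of
  the annotated regions — disks grow at uniform speed around uniformly
  sampled region points, and the radii at which 1/10/50/90% of the
  initially distinct regions have fused summarize how far the incursion has
  coalesced.
* **Automatic detection** — the mosaic is tiled into 100 × 100 px
  multi-label patches; a dual-loss classifier (class-presence
  cross-entropy, blueberry weighted 8× soil and 4× other classes, plus a
  regression term on the blueberry pixel fraction) is trained with
  leave-one-mosaic-out rotation, 12 augmented copies per blueberry patch
  (flips, small rotations, Gaussian blur, contrast changes, elastic
  deformations) and soil-only patches downsampled to 50%. Positive coarse
  patches are refined into 4 × 4 grids of 25 × 25 sub-patches and
  re-classified, tightening the mask.
* **Evaluation** — TPR = TP/(TP+FN), ACC = (TP+TN)/(TP+TN+FP+FN),
  Dice = 2TP/(2TP+FP+FN) at patch and pixel granularity, and the GT-cover
  ratio |truth ∩ mask| / |truth|. The refined mask is a subset of the
  coarse mask, so GT-cover can only fall under refinement while Dice
  typically rises sharply.

Survey imagery of this kind is rarely deposited, so a seeded synthetic-scene
generator (`moorberry.synthetic`) renders wetland scenes with full ground
truth — soil covering ~87% of the frame with reddish confounder patches,
clustered blueberry bushes at ~1.2% area cover with canopy radii 16–100 px,
heights mostly below 0.5 m with a tail to 3 m, and hassock noise on the
DEM — making every stage testable end to end.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
corpus and write tables under `results/`:

```
python analysis/01_simulate_scenes.py --seed 1
python analysis/02_bush_inventory.py
python analysis/03_spread_patterns.py --seed 1
python analysis/04_classify_patches.py --seed 1
```

Output of the chain (seed 1):

```
S1: 1600x1600 px (0.64 ha), 9 bushes planted (9 after merging), blueberry 1.21%, soil 86.8%
S1: 9 bushes, 77.33 m2 total, 8.59 m2/bush
3 m clustering: 21.60% grouped (3+), 312 singles, largest group 11
6 m clustering: 58.40% grouped (3+), 160 singles, largest group 22
hotspot bins: {'none': 350, '99': 17, '90': 7, '95': 3}
S1: 9 regions; fused at 1%: 13px, 10%: 13px, 50%: 47px, 90%: 159px
S1: TPR 0.958, ACC 0.988, Dice 0.220 -> 0.613, GT cover 1.000 -> 1.000
pooled: TPR 98.61%, ACC 99.61%, refinement raised Dice 0.215 -> 0.613 while GT cover fell 1.000 -> 1.000
```

Reading this: each synthetic site carries ~1.2% blueberry cover; at 3 m
grouping about a fifth of the 500 surveyed centroids sit in clusters of
three or more, rising to ~58% at 6 m — the signature of clonal spreading
centres with a scattered background. Seventeen of the 377 collect-event
clusters are 99%-confidence hotspots. The classifier finds ~96–100% of
blueberry-containing patches per fold, and coarse-to-fine refinement
triples the pixel Dice (0.22 → 0.61) while giving up almost no annotated
blueberry pixels.

There is also a CLI mirroring the same workflow
(`moorberry simulate | allometry | spread | dataset | train | predict |
refine | evaluate | report`); every stage writes a `run.json` sidecar with
its argument hash and seed so runs are reproducible artifact by artifact.

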