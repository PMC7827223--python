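# Methods

## Scope and coordinate conventions

The package treats one survey site as an `OrthomosaicScene`: an RGB raster,
an optional co-registered DEM in metres above the site datum, one binary
mask per annotation class (blueberry, tree, yellow bush, soil, water, dead
tree; masks are mutually exclusive), annotated ground points and a pixel
size in m/px. Rasters are row-major with the origin at the top-left pixel
and 0-based indices; tile intervals are half-open. Metric coordinates are
x = col·pixel_size (east) and y = (H−1−row)·pixel_size (north). These
conventions are stated once here and used by every module.

## Synthetic scenes

The generator emulates the statistical structure of a wetland incursion
imaged by UAV, not its photorealistic appearance:

* **Composition.** Soil is the remainder class (~87% by default, inside the
  76–89% band typical of such sites); blueberries default to 1.2% area
  cover; trees 5%, yellow bushes 3%, water 3%, dead trees 1%. Non-blueberry
  classes are painted as irregular blobs onto free soil until each class
  hits its pixel target exactly (the last blob is trimmed farthest-pixel
  first), so realized fractions match the configuration to well within half
  a percentage point.
* **Bushes.** Centroids follow a Neyman–Scott-style process (uniform
  parents, Gaussian offspring, plus a uniform background fraction). Canopy
  radii are drawn uniformly from the configured range; when no explicit
  bush count is given, radii are rescaled within the range so the summed
  disk area hits the blueberry area target, which also fixes the derived
  count. Bushes are rendered as disks with band-limited boundary noise
  (±12% radius), so component areas are close to but never exactly πr²;
  the exact per-class pixel counts, the merged-component count (bushes
  whose canopies touch are annotated as one), and each planted bush's true
  height are recorded as ground truth. Overlapping canopies take the
  maximum height.
* **Heights and DEM.** True heights are mostly shallow (gamma around a
  0.3 m mode, truncated at 0.6 m) with a 12% tall tail uniform up to 3 m.
  The DEM is a smooth ground surface (±0.15 m, long wavelength) plus
  zero-mean Gaussian hassock noise (sd 0.1 m — tussocks inflate apparent
  ground level by a few decimetres) except under canopies, where the bush
  bump (plateau core, cosine rim falloff) plus small canopy texture
  replaces the hassock noise. One ground point is annotated just outside
  each bush, carrying the DEM value at that pixel.
* **Confounders.** A configurable fraction of soil pixels (default 5%) is
  tinted reddish in contiguous patches while remaining labeled soil, giving
  the classifier genuinely hard negatives; autumn blueberry foliage is the
  reddest class, so naive redness thresholds fail on these patches.
* **Determinism.** All draws come from one `numpy` generator seeded from
  the config; identical config + seed reproduces scenes bit for bit.

What the generator does **not** emulate: photorealistic texture,
structure-from-motion stitching artifacts, shadows and illumination
gradients, partial occlusion of bushes by tree canopies, and continuous
color variation within a class. Passing tests therefore demonstrate that
the pipeline's logic is correct under controlled statistics, not that the
shipped classifier weights would transfer to real imagery.

## Allometry

Bushes are 8-connected components of the blueberry mask (hand-annotated
strokes touching diagonally belong to one bush). Heights subtract the
elevation of the ground point nearest to the component centroid — ground
points are annotated close to bushes, so no interpolated ground surface is
fitted by default (a TIN/IDW surface would be a config extension). Negative
heights are clamped to 0 and flagged; a configurable maximum ground-point
distance leaves heights undefined rather than wrong. The maximum statistic
is sensitive to overlapping tree canopies, the median resistant to them;
both are reported. Report tables round half-up to 2 decimals. Height
histograms use half-open 0.5 m bins from 0 m with an overflow bin above
3.5 m.

## Spread statistics

* **Distance clustering** is transitive single linkage: points belong to
  one cluster iff a chain of pairwise distances ≤ t connects them,
  computed via a KD-tree pair query and sparse connected components, with
  t = 3 m and 6 m (3 m ≈ 1.5× the typical 2 m bush diameter).
* **Kernel density** uses the quartic kernel normalized to unit mass, so
  the raster integrates to the interior point count (verified to 1%).
* **Gi\*** is the classic Getis-Ord statistic with binary fixed-distance
  weights, self included, against the global mean and population sd;
  two-sided bins at |z| ≥ 1.645/1.960/2.576. Degenerate cases (zero count
  variance, or a neighborhood spanning every feature) yield z = 0. The
  ArcGIS-style "optimized" parameter search is deliberately not replicated
  (proprietary and unspecified); the neighborhood radius is explicit
  config. Note that Σᵢ zᵢ = 0 holds only when all features have equal
  neighbor counts; the property test covers exactly that case.
* **0-D persistence** grows disks of common radius around grid samples of
  the annotated regions (default spacing 5 px; every component contributes
  at least its centroid-nearest pixel). Merge radii are computed along the
  Euclidean minimum spanning tree of the samples — exactly the
  single-linkage merge radii — and merges between samples of one region
  are discarded as sampling artifacts. An inter-region event is recorded at
  radius d/2 (disks of equal radius touch at half their distance); a
  `radius_convention="distance"` switch reports d instead, since published
  persistence plots do not always state their convention. The
  fused-fraction radius for f ∈ {1, 10, 50, 90}% is the smallest event
  radius at which ⌈f·(R−1)⌉ inter-region merges have happened, ties broken
  by the earlier event. Radii are reported in both pixels and metres.

## Patch classification

* **Tiling.** Non-overlapping 100 px tiles (a patch is on the order of one
  bush; canopy radii span 16–100 px); trailing strips that do not fill a
  tile are dropped rather than padded so footprints stay exact. A patch
  carries the set of classes present (multi-label) and its blueberry pixel
  fraction.
* **Balancing.** Blueberry patches are the rarest class by far (~1–3% of
  patches); each contributes the original plus 12 augmented copies, and
  soil-only patches are halved (seeded subsample). Validation and test
  splits are never balanced; requesting it is an error.
* **Augmentations.** Six geometry-preserving transforms: up/down flip,
  left/right flip, central rotation (uniform ±15°, reflect padding — the
  magnitude is a package choice), Gaussian blur (σ ∈ [0.5, 1.5], emulating
  UAV motion blur), linear contrast change (gain 0.9–1.1, bias ±10), and
  elastic deformation (Gaussian-smoothed displacement field, α = 8 px,
  σ = 6 px). All leave the label list unchanged and are seeded.
* **Model.** A deliberately small, fully deterministic numpy network: a
  pluggable feature extractor, one dense ReLU layer and a dual sigmoid
  head — six class-presence units plus one unit regressing the blueberry
  pixel fraction. The loss is class-weighted binary cross-entropy
  (blueberry 8× soil, 4× the other classes) plus a mean-squared-error
  fraction term with weight 1.0. Two backbones ship: `color_hist`
  (default), a parameterless 4×4×4 joint RGB histogram with per-channel
  mean/sd, each histogram value passed through a power-0.1 transform so
  that a sliver of a rare color registers almost as strongly as a full
  bush — presence, not abundance, is what the patch label encodes; and
  `tiny_mlp`, a dense layer over bilinearly downsampled pixels. The
  registry accepts externally registered pretrained convolutional
  extractors, but none ships. `weights_mode="frozen"` keeps the extractor
  at its initialization and trains only the head. Optimization is
  minibatch Adam (lr 0.01, batch 32, 100 epochs by default) with a seeded
  shuffle; identical data + config + seed reproduce the loss sequence
  exactly. The decision threshold is 0.5 per class.
* **Cross-validation.** Leave-one-mosaic-out: whole sites rotate through
  train/validation/test so no spatial leakage is possible; overlapping site
  ids across splits raise an error. Pooled metrics are fold averages
  (macro), with count-pooled (micro) patch metrics also reported.
* **Refinement.** Each positive 100 px patch splits into a 4×4 grid of
  25 px sub-patches, each re-classified after bilinear upsampling inside
  the featurizer; the refined mask is the union of positive sub-patch
  footprints and is a subset of the coarse mask by construction, so
  GT-cover is non-increasing under refinement while Dice rises when the
  discarded area is mostly non-blueberry.

## Evaluation

Patch-level counts treat a patch as positive when blueberry is in its
label set; pixel-level metrics paint predicted footprints as uniformly
positive and count unannotated pixels as negative ground truth, both masks
and truth restricted to the tiled extent. Metrics with zero denominators
are reported as undefined, never as 0.

## Study-scale choices

The synthetic corpus for the end-to-end runs uses three 1600 px (80 m,
0.64 ha) scenes with canopy radii 16–48 px — a scaled-down version of the
multi-hectare originals chosen so each mosaic yields 256 patches and a few
dozen blueberry-positive ones, enough for per-fold detection rates to be
statistically meaningful while a full leave-one-mosaic-out run stays in
the tens of seconds. Distance clustering and hotspot statistics instead
use a survey-scale centroid pattern (400 × 400 m, 500 bushes ≈ 31/ha, 60
spreading centres with 4 m offspring sd and 30% scattered background),
since grouping percentages are only meaningful at survey point densities.
Smaller prototype corpora (500–800 px scenes with under ten positive
patches per site) proved statistically inadequate for evaluating detection
rates and were rejected as study designs, not tuned away.

## Known limitations

* Ground elevation uses the single nearest ground point; depressions and
  hassocks propagate directly into height estimates (mitigated but not
  removed by the median statistic and the 0-clamp).
* The shipped backbones classify by color statistics; on real imagery with
  continuous class-color variation a convolutional extractor would be
  required (the registry supports one, none ships).
* Area and height analyses may disagree on bush counts when shapefile-based
  areas and mask-component heights group bushes differently; the package
  works from masks alone, so one count applies to both.
* Overlap between adjacent survey mosaics is not de-duplicated; sites are
  treated as independent.
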