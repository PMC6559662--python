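# Methods

## Problem and model

The package maps three ground classes in a vineyard scene — trellised
grapevine canopy, bermudagrass (*Cynodon dactylon*) patches, and bare soil
— from a co-registered multiband raster (RGB or R-G-NIR) plus a digital
surface model, and turns the weed map into a site-specific treatment grid.
The central modeling assumptions are:

* **Height separates vine from everything else.** Vines trained on a
  vertical trellis stand on the order of 1.5 m above the soil, while
  bermudagrass is prostrate (< 0.1 m); spectral information alone cannot
  separate the two green canopies, DSM relief can.
* **Greenness/NIR separates weed from soil at the vegetative stage.**
  Vegetative bermudagrass is green-dominant with high NIR reflectance;
  bare soil is a brighter, spectrally flat brown. A single well-chosen
  vegetation index is then bimodal over the inter-row and an automatic
  Otsu split classifies it. This assumption breaks for winter-dormant
  (straw-colored) bermudagrass, which is out of scope.
* **Weed management operates on grid cells, not pixels.** The decision
  unit is a row-aligned cell matched to implement working width; per-cell
  weed-coverage percentage drives treat/no-treat decisions.

## Index selection

For each index applicable to the camera the two classes' per-pixel values
are compared by one-way ANOVA with Tukey's HSD at α = 0.05 (equivalent to
the F-test for two groups, retained for its familiar reporting) and by
M = (μ₁ − μ₂)/(σ₁ + σ₂) with sample standard deviations. Ranking uses |M|
with the class order fixed as (bermudagrass, bare_soil): the sign of M
only records which class sits higher, and published rankings report
magnitudes. M is computed on pixel samples, not per-frame means, because
it describes the separation of the two class histograms. Ties in |M|
break on registry (publication-table) order with a logged warning. The
report rounds M to 2 decimals and attaches the conventional bands
(|M| > 1 moderate, |M| > 2 good).

Two printed index formulas in the source literature are typographically
corrupted. MSR defaults to the established modified simple ratio
(NIR/R − 1)/(√(NIR/R) + 1), with the printed no-square-root variant — which
is algebraically identical to MRVI up to sign — available behind the
registry flag `use_printed_msr`. TVI1 is reconstructed as
sign(NDVI + 0.5)·√|NDVI + 0.5|, consistent with the transformed vegetation
index family. VEG is implemented exactly as printed,
G/(R^0.667 · B^0.333). Indices are evaluated on the native radiometric
scale of the input (DN or reflectance); values, but not Otsu-based
classifications of a single index, depend on that scale. Each registry
entry declares its behaviour under multiplying all bands by k > 0
(invariant, linear, or neither) and a polarity stating which side of a
threshold is vegetation; NLI is *not* scale-invariant (the squared NIR
term breaks homogeneity) and is tagged accordingly.

Pixels where an index denominator vanishes (WI with R = G, VARI with
G + R = B) are masked and excluded from histograms and object means rather
than clamped, to avoid fabricating values.

## Vine detection

* `tile_size` = 0.5 m chessboard tiles; `dsm_sd_threshold` = 0.15 m;
  `height_min` = 0.4 m; `soil_window` = 5 m; soil reference quantile 0.10.
  With ~1.5 m canopy against < 0.1 m weeds the margin between classes is
  wide, so none of these is critical; all are exposed in the `vine:`
  config block.
* Tiles whose within-tile DSM standard deviation (population sd) exceeds
  the threshold become candidates; a tile half canopy / half soil at 1.5 m
  height difference has sd 0.75 m, five times the threshold.
* Pixel-level refinement runs inside the candidate tiles **dilated by one
  tile**. A canopy strip wider than the tile can cover a tile completely,
  leaving near-zero relief variance inside it; such interior tiles are
  flanked by high-variance edge tiles, so a one-tile dilation makes their
  pixels reachable without opening the whole scene to refinement.
* The soil reference is the 10th percentile of DSM over non-candidate
  area, computed per `soil_window` window and bilinearly interpolated from
  window centers back to pixels; windows without soil fall back to the
  nearest window with soil (logged). Comparing each pixel's height to this
  local reference makes the mask exactly invariant to DSM offsets and, on
  a uniform ramp, shifts the reference by a near-constant amount, which is
  why ≤ 5° slopes leave the mask essentially unchanged.

## Segmentation and classification

Multiresolution segmentation follows the published Baatz–Schäpe
formulation: objects carry per-band sum/sum-of-squares, perimeter (4-face
count), and bounding box; the merge cost is
(1 − shape)·Δh_color + shape·Δh_shape with h_color = Σ_b w_b·n·σ_b and
h_shape mixing compactness (p√n) and smoothness (n·p/p_bbox); a merge is
allowed while cost < scale². Defaults scale 5, shape 0.3, compactness 0.5,
spectral bands weighted 1 and the DSM 0. Merging is globally
cheapest-first with lazy heap invalidation — the global minimum pair is
necessarily a mutual best fit — and deterministic: ties on cost resolve by
label order, and region labels are compacted in scan order afterwards.
Object-count equivalence with proprietary implementations is not promised;
the contract is the partition properties and the downstream classification
accuracy.

For domains above 3·10⁵ pixels, initial seeds are regular 2 × 2 pixel
blocks (4 × 4 above 5·10⁶) instead of single pixels. At 2 cm pixels a 2-px
block is 4 cm — far below the ~1 m weed-patch scale — so the effect on the
classified map is confined to half-block boundary jitter, while making
field-scale scenes tractable; small scenes (and all unit tests of the
merge contract) use single-pixel seeds.

Otsu thresholding uses a 256-bin histogram over the value range. The
between-class variance is scored on integer bin indices (an affine map of
the bin centers, so the argmax is unchanged) which keeps the arithmetic
exact for count histograms; across the empty-bin plateau that separates
well-split modes the variance is constant, and the tie resolves to the
plateau midpoint — the natural split point for a bimodal histogram. The
returned threshold is the upper edge of the lower class's last bin, mapped
back to index units. By default the histogram is built from area-weighted
object means ("no-vineyard objects" are the classification unit);
pixel-level thresholding is available via `level="pixel"` for ablation.
Classification then puts an object on the weed side iff
polarity·(mean − threshold) > 0, with polarity taken from the index
registry (higher ExGR/GNDVI = vegetation) rather than inferred, so
behaviour on near-degenerate scenes is deterministic. Degenerate inputs
(constant index, < 2 objects) raise informative errors.

## Validation

The confusion matrix is area-based over pixels whose reference label is
bermudagrass or bare soil; reference vine/unknown pixels are excluded, and
pixels the map classed as vine inside the evaluation area (a 2 × 2 matrix
cannot hold them) are excluded and logged. OA = 100·trace/total;
PA(c) = 100·diag(c)/reference-total(c); OE(c) = 100 − PA(c), so PA + OE is
exactly 100 by construction. Ground-truth splitting for index selection
vs validation happens at the sampling-frame level (default 25 % / 75 %,
round-half-up on the analysis side) to avoid spatial leakage.

## Prescription

The grid is aligned to the vine-row azimuth — given explicitly or
estimated as the principal axis of the vine-pixel coordinates — with the
long cell side along the rows. Cells are defined over the inter-row
(not-vine) domain; partial edge cells are kept and area-weighted so
treated + untreated area equals the gridded area exactly. Coverage is
100·(weed area)/(not-vine area) per cell — vine canopy must not dilute
weed coverage — with a config flag to use the full cell area instead.
Thresholds: treated at t = 0 iff coverage > 0 (strict presence), at t > 0
iff coverage ≥ t; this makes treat flags and savings monotone in the
threshold. Because the appropriate savings denominator (sprayed inter-row
vs whole gridded cell area) is a reporting choice, the savings report
emits both, labeled.

## Synthetic scenes

The generator emulates the study system: east–west rows, 2.5 m inter-row
and 1.3 m intra-row spacing, 0.6 m-wide canopy strips at 1.5 m height with
smooth jitter, weed patches as Gaussian-smoothed thresholded noise blobs
(patch-radius distribution sets the smoothing scales) confined to the
inter-row, terrain as base + slope + smooth roughness, and per-class
per-band Gaussian spectra on a reflectance-like 0–1 scale. The patch
threshold is the quantile of the smoothed field over the inter-row that
meets the coverage target, so realized coverage tracks the target to well
within ±10 % relative (with a bounded retry guard). Default class spectra
were chosen once as plausible vegetative-stage values — weed
green-dominant with high NIR, soil brighter and flat — such that
greenness and NIR-normalized indices are clearly bimodal (|M| > 2); a
`spectra_contrast < 1` "hard mode" shrinks class separation to exercise
misclassification paths.

What the generator does **not** emulate — shadows, mixed boundary pixels,
radiometric vignetting, co-registration error between bands and DSM,
within-class spatial correlation of reflectance, dormant-season weed color
— means passing tests demonstrate the correctness and internal consistency
of the algorithms under the stated geometry and spectral contrast, not
field-level accuracy on real orthomosaics.

## Problem sizes and determinism

Headline runs use a 30 × 30 m scene at 2 cm pixels (1500 × 1500, the
pixel scale of the source orthomosaics) for the end-to-end accuracy,
area and savings numbers, 16 × 16 m at 4 cm for the coverage-recovery
sweep (3 targets × 3 seeds), and 12 × 12 m at 2 cm for separability and
slope checks. Every stochastic step (scene synthesis, pixel sampling,
frame splitting) takes an explicit seed; two runs with the same
configuration and seeds are byte-identical.

## Known limitations

* The merge engine is O(n log n) in initial regions but pure Python;
  very large scenes rely on block pre-aggregation (see above).
* Vine detection assumes approximately linear local terrain within the
  soil window; terraced or strongly undulating fields would need a
  smaller window.
* The weed/soil split assumes both classes are present in the inter-row;
  a completely weed-free field makes the Otsu split degenerate, which is
  reported as an error with guidance rather than a silent all-soil map.
* CRS handling is deliberately strict: inputs on different CRSs raise;
  the package never reprojects.
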