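# Methods

## Pipeline model

`phenopot` assumes a "sensor-to-plant" acquisition geometry: a camera on a
planar gantry sweeps a planned route over stationary pots, producing
overlapping top-view frames, each tagged with its gantry position (mm), a
timestamp and a mm-per-pixel scale (default 1.067 mm/px, a typical value
for an industrial camera ~2.3 m above the bench).  Pots, not plants, are
the detection target: pots are rigid, circular and stationary, so matching
a plant to itself across growth points reduces to matching its pot once.
The pipeline therefore detects pots on the earliest acquisition day and
re-crops the same frame region on every later day.

All traits are measured only inside the pot circle (the *phenotyping
region*).  Leaves of neighbouring plants can cross pot boundaries late in
growth; clipping to the pot circle gives every plant-day the same
measurement support and makes dynamic traits comparable across the series.

## Detection backend and semantic filtering

A detector is any callable `CameraFrame → list[Detection]` with boxes in
normalized frame coordinates.  The bundled baseline runs a Canny edge
detector (σ = 1.5) and a circular Hough transform over radii within ±8% of
the nominal pot radius.  Two numerical choices matter:

* **Confidence** is not the raw Hough accumulator value (which loses
  10–20% to radial discretization even on a perfect rim) but the fraction
  of 360 angular bins around the candidate circle backed by an edge pixel
  within ±1 px radially.  A clean rim scores ≈ 0.97, comfortably above the
  0.9 filtering threshold; textured background scores ≪ 0.9.
* **Radius** is refined to the *outermost* radius whose angular support is
  ≥ 97% of the best, because a pot rim produces two concentric edge
  circles (inner and outer wall) and the pot's nominal diameter is the
  outer one.  Without this step the detector intermittently locks onto the
  inner wall and biases the diameter low by the rim width (~5%).

Semantic filtering is: drop confidence < threshold (default 0.9) → greedy
NMS by descending confidence (IoU threshold 0.45; the source conventions
fix only the confidence threshold, so the NMS IoU is configurable) →
strict containment in the ROI.  The default ROI is the frame inset by one
nominal pot radius per side, which guarantees every retained box is a
complete pot.  Containment is strict (a box touching the ROI boundary is
dropped), so a frame can only contribute pots that sit at least two pot
radii inside it.

Localization maps each detection to global mm via
`global = gantry + (pixel − frame_centre) × scale` on both axes (image y
and gantry y aligned; a `y_flip` flag covers installations with opposite
conventions).  Detections closer than half a pot diameter merge into one
pot — pots cannot physically overlap more than that — and the
representative sighting is the one nearest its frame centre, where lens
distortion is least.  Variety/plant indices come from the nearest
planting-layout cell; a merged pot farther than half the grid spacing from
every cell becomes an "unmatched" error record rather than a silent guess.

## Segmentation backend and post-processing

A segmenter is any callable `crop → probability map in [0, 1]`.  The
baseline uses chromatic vegetation indices: excess green ExG = 2g − r − b
for green foliage, its negation (excess purple) for anthocyanin-dominated
varieties, or an automatic choice ('auto') that picks whichever index puts
the smaller pixel fraction in its upper half — the plant is always the
minority class of a pot crop.  The index is rescaled to [0, 1] between its
1st percentile and the **median of candidate plant pixels** (pixels above
30% of the index range).  Selecting the upper reference by value rather
than by count matters twice: a seedling may cover well under 1% of the
crop, so any bulk percentile would miss it entirely; and using the crop
maximum instead would sit 3–4 noise standard deviations above the typical
leaf pixel and drag it toward the binarization threshold, costing ~10% of
plant pixels for dark foliage.  Crops whose index range is below 0.05
yield an all-zero map, so uniform backgrounds produce empty masks.

Post-processing binarizes strictly above a fixed threshold (default 0.5;
the source conventions state a fixed value without naming it), labels
4-connected components (4-connectivity avoids diagonal bridges between
neighbouring leaves; switchable to 8), keeps the largest, and intersects
it with the pot circle.  Clipping happens *after* component selection so
selection sees the whole plant.  An empty mask is a valid result.

## Static traits

Lengths are computed in pixels and converted once at output (1 cm = 10 mm).

* PA = pixel count × (scale/10)².
* PP = Crofton perimeter estimate (4 directions) of the hole-filled mask.
  A traced boundary polygon with √2 diagonal steps overestimates smooth
  outlines by ~5–6% (a rasterized r = 100 disk measures 664.6 px against a
  true 628.3), while the Crofton estimator is within ~0.3%; holes are
  filled first so internal pores do not inflate the outer perimeter.
  Boundary-length estimates are resolution-limited: the 2% agreement with
  analytic truth holds for plants resolved beyond roughly 2000 px.
* CA/CP and AXL/AXS are the area/perimeter of the convex hull and the
  side lengths of the minimum-area rotated rectangle, both computed on
  pixel **corner** points (pixels as unit squares).  This makes an
  axis-aligned w×h pixel rectangle measure exactly w×h and guarantees
  CA ≥ PA identically; hulls of pixel centres would undershoot by half a
  pixel per side.
* PAR = PA / (π r_pot²) with the pot circle as the circumscribed region:
  the fill ratios describe how far the canopy fills the pot, so the pot
  circle is the natural reference.  (A variant using the plant's own
  minimum enclosing circle would answer a different question — canopy
  compactness — and CAR already covers that.)  Without a pot circle PAR
  is reported as NaN.
* Color means are taken over mask pixels: raw R, G, B; H, S, V from the
  hexcone conversion with H in degrees × 255/360 and S, V × 255 (all three
  on [0, 255]; achromatic pixels have H = 0); ExG = 2g − r − b on
  chromatic coordinates r = R/(R+G+B) etc., with black pixels contributing
  0.  ExG is reported unclamped (green foliage typically lands in [0, 2]);
  clamping to [0, 1] would discard the very contrast the index exists for.

## Dynamic traits

For a static trait SI over a window [t₁, t₂] with both endpoints sampled:
GR = (SI(t₂) − SI(t₁))/(t₂ − t₁), and AC = Σ SI(t)/(t₂ − t₁) with the sum
over **integer days t₁..t₂ inclusive**, SI linearly interpolated between
acquisition days.  The daily-inclusive reading is the default because
accumulation values of a few hundred cm² against a ~800 cm² pot area are
consistent with an average daily level and inconsistent with an 8-point
sum divided by 34; the sampled-days-only variant remains available as
`mode='sampled'`.  A literal consequence of the inclusive sum: a constant
series SI = c over [0, T] gives AC = c·(T+1)/T, not c.  Windows not
aligned to sampled days raise an error — no extrapolation — and plants
observed on fewer than two days are excluded from series assembly with a
warning, with missing days recorded per series.

## Evaluation statistics

* **Friedman test**: within each block (one dynamic trait), treatments
  (varieties) are ranked ascending — rank 1 = smallest — with average
  ranks for ties; χ² = 12/(nk(k+1))·ΣR_j² − 3n(k+1), divided by the tie
  correction C = 1 − Σ(t³−t)/(n(k³−k)); p from the χ²(k−1) upper tail.
  On the bundled three-variety tables the correction moves χ² from 5.375
  to 6.143 (geometric) and 10.393 to 10.582 (color), and ascending ranking
  is what reproduces the published mean ranks.  If every block is a
  complete tie (C = 0), the statistic is defined as 0 with p = 1 and
  flagged degenerate.  A pooled per-trait rank summary
  (`pooled_rank_report`) ranks all 30 GR-/AC- columns within each variety;
  its tie rule is configurable because published variants of that summary
  do not follow the average-rank convention (a duplicated column pair
  prints 29 where average ranks give 28.5), so it is a descriptive report,
  not a tested reproduction.
* **Clustering**: trait columns are z-scored and compared by squared
  Euclidean distance; merging follows *within-groups* average linkage —
  the pair minimizing the mean pairwise distance within the merged cluster
  — implemented directly since standard 'average' linkage minimizes only
  the between-cluster mean.  Merge heights are that within-group mean.
* **PCA** is an eigendecomposition of the trait correlation matrix;
  eigenvalues sum to the number of traits, contributions are λ/m × 100%,
  components with λ > 1 are retained, and loadings are eigenvectors × √λ
  (component–trait correlations) with each component's dominant loading
  made positive.
* **kNN grading** standardizes features on each training fold, classifies
  by Euclidean majority vote (k configurable, default 5; the distance and
  k are not fixed by the source conventions) under stratified 4-fold
  cross-validation with a seeded shuffle; `folds = n` switches to
  leave-one-out.
* **Color grading charts** sort varieties ascending by a trait (ties
  broken by variety id), record the value range, and mark five boundaries
  at ranks ⌈j·N/5⌉ with the representative variety and value at each.

## Synthetic scenes: what they emulate, and what they do not

Each scene renders one global canvas per acquisition day — floor texture
(low-amplitude achromatic noise plus faint bench grid lines), pots as dark
annular rims with noisy soil interiors, and plants as polar rosettes
r(θ) = R(t)·(1 + a·cos kθ), a ∈ [0, 0.6), with per-pixel Gaussian leaf
color noise (σ = 8 by default).  Frames are crops of that canvas at the
route positions, which guarantees a pot looks identical in every frame
that sees it; supplemental frames centred on any pot the base route does
not contain with two-pot-radii margin guarantee every pot is detectable
somewhere.  R(t) follows a logistic r_max/(1 + e^(−g(t−t₀))); the default
variety generator draws r_max ∈ [90, 125] mm, g ∈ [0.10, 0.16]/day,
t₀ ∈ [4, 8] d, giving initial radii of ~20–30 mm (month-old transplants
are seedlings of that size, not sprouts) and keeping the lobed silhouette
inside the 160 mm pot radius.  Default acquisition days are
{0, 5, 9, 13, 17, 22, 26, 30, 34}, i.e. 4–5 day intervals across a 34-day
vegetative window.  A fixed integer seed determines every pixel.

Ground truth is computed from the same rasterized masks by an
independently coded brute-force path: pixel counting, a hand-written
monotone-chain hull and rotating calipers on pixel corners, an explicit
hexcone HSV conversion, and the analytic rosette area πR²(1 + a²/2) and
arc length ∫√(r² + r′²)dθ.  Tests compare the scipy/shapely/skimage
measurement path against this oracle.

The generator deliberately omits: shadows and specular highlights,
perspective and lens distortion, soil-moisture and litter clutter,
occlusion between neighbouring plants, leaf serration beyond the cosine
lobes, and diurnal color drift.  Passing tests therefore demonstrate that
the post-processing, measurement and statistics stages are correct given
reasonable detector/segmenter outputs — not that the bundled classical
baselines would match a trained CNN on real greenhouse imagery.  Published
CNN-era figures that depend on real annotated data (detection mAP,
segmentation F1, real-data correlation/PCA tables, the 86.78% kNN accuracy
and the CW–AXL R² = 0.88) are out of desk-reproducible scope for the same
reason; the machinery that produced them (correlation, PCA, kNN grading,
line fits) is implemented and validated on constructions with known
answers instead.

## Problem sizes and determinism

Tests and the acceptance script run scenes at 2.134 mm/px (half the
reference sensor resolution) with 512–768 px frames and 2×2 or 4×4 grids
— sizes chosen so the full suite completes in a couple of minutes while
pots remain ~150 px across and seedlings stay above the resolution floor.
The end-to-end check uses a 4×4 grid over 8 time points at the full
1.067 mm/px scale.  Every stochastic component (scene noise, variety
draws, fold shuffles) flows from explicit integer seeds; identical
configurations are bit-identical across runs.

## Known limitations

* The Hough baseline assumes near-circular, rim-visible pots at a known
  nominal radius; heavily overgrown rims (leaves crossing the rim on most
  of its circumference) would suppress its confidence below threshold.
* The vegetation-index baseline assumes foliage is chromatically separable
  from background; it will not separate green plants from green moss or
  algae-covered soil.
* Detected radii are integer-quantized, so pot-diameter estimates carry a
  ±1 px (≈ 1.4% at the test scale) quantization error.
* Within-groups linkage heights are not guaranteed monotone for adversarial
  inputs; the flat-cut helpers (`cut`, `cut_k`) behave as scipy's fcluster
  does in that case.
* `accumulation_rate` interpolates linearly between acquisition days; no
  growth-curve fitting or smoothing is performed.
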