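# Methods

## Problem setting

Dermoscopy images show a pigmented lesion — darker, roughly elliptical but
irregular — on lighter skin, often with a smooth intensity gradient at the
border and artifacts such as thin dark hairs. The task is to produce a
binary lesion mask whose boundary is compared against a dermatologist's
manually drawn border. All grids are 0-based `(row, col)` with the origin
at the top-left pixel; images are H×W×3 uint8 (rectangular images are
supported throughout — nothing in the clustering requires square inputs).

## Binarization (pre-processing)

The density-based clusterer consumes a binary image, so a thresholding
step precedes it. The default is deliberately simple and documented:
Rec.601 luminance `round(0.299R + 0.587G + 0.114B)`, Otsu's threshold
(the t ∈ [0, 254] maximizing the between-class variance of the partition
{≤ t}/{> t} on the 256-bin histogram, computed by an exhaustive vectorized
scan; ties break to the smallest t for determinism), and *dark* polarity
(intensity ≤ t is positive), since lesions are darker than skin. Every
piece is overridable (`channel`, `method=fixed` + threshold, polarity). A
constant image has no separating threshold and is rejected rather than
guessed. No hair or bubble removal is attempted before clustering: hairs
appearing as false positives is part of the behavior being studied, not a
defect to engineer away.

## DBSCAN on the pixel grid

Region queries use a precomputed disc stencil — all integer offsets with
`dx² + dy² ≤ eps²` — truncated at image borders; with `eps = 5` the
interior neighborhood holds exactly 81 pixels. Per-pixel neighborhood
counts are obtained in one pass by convolving the mask with the stencil
kernel, which makes the core test O(1) per pixel.

Clustering scans row-major from (0, 0). Each unclassified positive pixel
is tried as a seed: if its neighborhood count is below `min_pxl` it is
provisionally noise; otherwise a new cluster (IDs 1, 2, … in
first-assignment order) grows by a FIFO queue of core pixels — every
queued core pixel's positive neighbors join the cluster, neighbors that
are themselves core are enqueued, and provisional-noise pixels encountered
are absorbed as border members. A border pixel reachable from two clusters
goes to whichever cluster reaches it first in this deterministic order;
this is the classic DBSCAN tie-break and the one ambiguity an order-free
description of the algorithm cannot pin down, so the test oracle checks
border pixels for *reachability from their assigned cluster* rather than
for one canonical label. Background pixels keep a reserved label distinct
from positive-pixel noise.

Lesion selection: the largest cluster (policy `all` gives the union), with
interior holes filled via background flood-fill, because the manual border
is a filled closed curve and the lesion is a solid region. Both choices
are defaults, not claims about how any particular study reduced clusters
to one region.

Limiting behavior used as a correctness anchor: with `min_pxl = 1` every
positive pixel is core (its neighborhood contains itself), and for
`eps ∈ [√2, 2)` the neighborhood graph is exactly 8-adjacency, so clusters
coincide with 8-connected components.

## Fuzzy c-means

Standard Bezdek updates (see README for the formulas), with these
numerical choices:

* **Initialization**: seeded uniform-random membership matrix with
  normalized rows. Randomizing U instead of the centroids is equivalent up
  to one half-step and keeps the update order centers-then-memberships.
  Fits are bitwise reproducible per seed.
* **Singularity rule**: a point coinciding with one or more centers gets
  its membership mass split equally among the coinciding centers (the
  closed form divides by zero there).
* **Convergence**: stop when `max |U^(k+1) − U^(k)| < tol` (default
  1e-5) or after `max_iter = 300` iterations; hitting the cap sets a
  non-converged flag instead of raising.
* **Objective**: recorded every iteration; alternating minimization makes
  the trace non-increasing, which the tests assert to 1e-9 slack.

Image segmentation clusters raw RGB triples (d = 3, no spatial
coordinates); spatial coherence is recovered afterwards by the
largest-component and hole-fill steps. The threshold *T* (percent) marks a
pixel unclassified when its maximum membership is below T/100; raising T
therefore never classifies more pixels. The lesion cluster is the one with
the minimum-luminance center — the standard dermoscopy heuristic —
overridable by explicit index. `c = 5`, `m = 2`, `T = 30` are the default
operating point.

## Manual-border ground truth

"Second-order B-spline" is read as a *degree-2 periodic B-spline with
uniform knots, using the picked points as de Boor control points* (the
most common reading; an interpolating-spline variant could be swapped in
behind the same interface). The curve is sampled densely
(`samples_per_segment`, default 32 — doubling it changes the rasterized
area by < 0.5%), drawn as a closed unit-thickness polyline, and filled by
flood-filling the background from the image border and complementing,
which sidesteps even-odd ambiguities on raster grids. A self-intersecting
sampled curve makes the fill undefined and is rejected, naming the first
offending segment pair; endpoint touches between non-adjacent segments
count as intersections, since a simple closed curve never revisits a
point. Control points live in plain-text two-column files (row col, `#`
comments, 0-based).

## Evaluation

Border error `100·(FP+FN)/(TP+FN)` equals `100·Area(auto ⊕ manual)/
Area(manual)` identically; the suite checks the identity on random pairs.
It is unbounded above (disjoint masks with twice the manual area give
300%). Aggregates are unweighted per-image means, matching
benchmark-table convention. Undefined metrics (empty manual mask for
border error; zero denominators for precision/recall) are reported as
missing and excluded from means — silently clamping to 0 or 1 would bias
aggregates. CSV reports round to 2 decimals; the library API keeps full
precision.

## Synthetic generator

The lesion boundary is star-convex: `r(θ) = e(θ)·(1 + w(θ))` with `e(θ)`
the rotated-ellipse radius and `w(θ)` a seeded mixture of up to five
sinusoids whose total amplitude is bounded so r stays positive. This makes
the exact mask computable analytically per pixel, which is what metric
tests require. The image linearly blends lesion over skin color across
`edge_softness` pixels, then adds hairs and clipped Gaussian noise. Ground
truth is defined pre-noise and pre-hair, matching manual-border semantics:
the dermatologist outlines the lesion, not the artifacts.

Defaults (160×160 image, 45×35-pixel lesion, luminance contrast ≈ 120 gray
levels, noise σ = 5, no hairs) define the "easy" benchmark regime; the
"fuzzy" preset widens the gradient (18 px) and noise (σ = 8), and "hairy"
adds four dark quadratic-Bézier strokes spanning the image so a typical
hair crosses the centered lesion — the configuration in which hairs attach
to the lesion cluster and appear as pure false positives. What passing
tests show: the pipeline recovers high-contrast, moderately noisy,
star-convex lesions to ≤ 10% border error and behaves correctly under the
stated artifact model. What they do not show: performance on real
dermoscopy images with low contrast, non-star-convex shapes, bubbles,
rulers, or black frames, none of which the generator emulates.

## Problem sizes

The benchmark harness uses 20 seeded 160×160 synthetic images per run, the
clustering-oracle sweep 200 random grids up to 50×50 against an O(n²)
brute-force closure, and the spline geometry check a radius-100 circle
from 32 control points — sizes at which every reference oracle is exact
and cheap while still exercising all code paths.

## Known limitations

* The binarization preceding DBSCAN is a documented default; published
  masks produced with an unknown thresholding cannot be reproduced
  bit-for-bit.
* Cluster→lesion reduction (largest cluster / darkest FCM center) is a
  heuristic; multi-focal lesions would need `policy=all` or an explicit
  cluster index.
* The FCM threshold *T* is interpreted as a percent cutoff on maximum
  membership; other defuzzification readings exist.
* No spatial regularization inside FCM; heavy noise fragments clusters
  before the post-processing can repair them.
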