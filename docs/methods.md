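# Methods

## Problem and approach

Automated delineation of the border of a pigmented skin lesion in a
dermoscopy-style RGB image. The package treats border detection as
density-based clustering of pixels and provides three layers:

1. **Reference DBSCAN** (`ndlesion.dbscan_ref`) with pluggable pixel
   metrics. A pixel is *core* when its ε-neighborhood (query pixel
   excluded, closed ball `d ≤ ε`) holds at least `MinPts` pixels; clusters
   are maximal density-connected sets; everything else is noise.
2. **FDBLD** (`ndlesion.fdbld`), the boundary-accelerated variant. Each
   cluster carries a boundary Γ — the polygon union of the convex hulls of
   the ε-neighborhoods discovered so far. A member whose distance to every
   ring of Γ exceeds the band width has its entire neighborhood inside the
   already-covered region, so its region query is provably redundant and
   skipped. The band width is ε in the spatial modes and the spatial reach
   of ε (see below) in ND mode.
3. **ND-FDBLD** (`metric="nd"`), which clusters *all* pixels of the color
   image directly — no thresholding pre-processing — under the normalized
   color+spatial distance

   d(i,j) = sqrt( (1/w1)·(w3·ΔR² + w4·ΔG² + w5·ΔB²)/(3·255²)
                + (1/w2)·(Δx² + Δy²)/(ω² + h²) )

   with the constraint 1/w1 + 1/w2 = 1 (defaults w1 = w2 = 2,
   w3 = w4 = w5 = 1). 3·255² normalizes the three 8-bit channels; the
   squared image diagonal ω²+h² normalizes the spatial part. With default
   weights d < 1 for any pixel pair of the image. We chose ω²+h² over the
   alternatives (ω·h, max(ω,h)²) because it keeps the spatial block ≤ 1
   and symmetric in the two dimensions; the choice only rescales ε.
   A multispectral generalization accepts n channels with per-channel
   weights and normalizers and reduces exactly to the RGB form at n = 3.

The **spatial reach** of ε is r = ε·sqrt(w2·(ω²+h²)): since the color
block is non-negative, any ND-neighbor lies within r pixels. Region
queries use a uniform grid bucketed at r (or at ε for spatial metrics),
so each query scans a 3×3 cell block.

## Correctness of query skipping

In the spatial/binary mode the skip is exact, and FDBLD provably equals
DBSCAN: a convex hull of points inside an ε-disc stays inside the disc,
so every foreground pixel covered by Γ was returned by some fired core
query and is already labeled; a member deeper than ε below Γ's rings
therefore has a fully labeled neighborhood. Two implementation details
matter and were found the hard way:

* **Γ keeps its holes.** Filling holes enlarges Γ, makes points near an
  uncovered (never-queried) hole look like deep interior, and breaks the
  equivalence on donut- and lace-like clusters. Γ is kept as the exact
  union of the hulls, and the leading-point band measures distance to
  interior rings too.
* **Degenerate hulls disable skipping for their cluster.** Collinear
  neighborhoods are inflated to thin rectangles (half-width ε/4) so
  member containment stays defined; the inflation margin may cover
  non-member pixels, so such clusters fire all queries. This is rare and
  costs only speed.
* **The pending list is LIFO.** With a FIFO wavefront every member is
  popped while still sitting on the Γ frontier (measured pop-time
  boundary distances are ~0) and nothing can ever be skipped. Depth-first
  discovery lets Γ overtake the backlog; on a solid 20×20 square at
  ε = 1.5, 125 of 400 queries are skipped. Membership is a reachability
  closure and is independent of the processing order, which the oracle
  tests confirm.

In ND mode the 2-D hulls live in a projection of a 5-D metric, so the
interior of Γ is not guaranteed to be labeled. Hull-based auto-labeling
is therefore disabled (membership accrues only from fired queries), the
band is widened to the spatial reach, and agreement with ND-DBSCAN is
*measured* rather than assumed: it is exact on images whose clusters are
color-homogeneous, and `skip=False` gives exact DBSCAN semantics always.

## Lesion pipelines

* **binary** (baseline): luminance (ITU-R 601 weights) → intermeans
  threshold (iterate T ← midpoint of the two class means from the global
  mean until |ΔT| < 0.5 gray levels; ties at T go to the dark side so the
  lesion keeps its boundary pixels) → foreground = dark pixels → spatial
  FDBLD (defaults ε = 1.5, MinPts = 5) → the union of all clusters that
  survive the filters.
* **nd** (headline): all pixels → ND-FDBLD → filters → the darkest
  surviving cluster (lesions are dark). The ND path never computes a
  threshold; a test poisons intermeans and verifies it.

Cluster filters: clusters whose bounding box is flush with the image
frame over more than 25% of its perimeter are peripherals (image-border
regions, e.g. vignette corners or structures that run off-frame), and
clusters below 1% of the image area are specks; both are dropped. Ties
in mean luminance go to the larger cluster. All thresholds sit in
`SelectionConfig`. This selection rule is this package's own
reconstruction; the method's published form states only a two-label
(lesion / non-lesion) output and the peripheral notion.

The mask's outline is exported as pixel-edge polygons (pixel (x, y) owns
the unit square [x, x+1]×[y, y+1]); holes are preserved so that
rasterizing the contour reproduces the mask exactly.

Evaluation uses pixel counts against a ground-truth mask MB:
precision = tp/(tp+fp), recall = tp/(tp+fn), and the XOR border error
BE = 100·(fp+fn)/(tp+fn), reported in percent (it may exceed 100).
Precision of an empty prediction is NaN, never 0, so empty masks are not
rewarded.

## Parameter defaults and how they were chosen

ε and MinPts have no universal values; they were tuned once on synthetic
phantoms (grids over ε, MinPts and the w1/w2 balance on easy and
low-contrast suites) and then frozen:

| mode   | ε    | MinPts | notes                                        |
|--------|------|--------|----------------------------------------------|
| binary | 1.5  | 5      | 8-neighborhood of a solid region is core     |
| nd     | 0.05 | 70     | tuned for ~96×96 images (reach ≈ 9.6 px)     |

The ND defaults scale with image size only partially: the spatial reach
grows with the diagonal, so the expected neighborhood count grows with
image area. For images far from ~100 px across, MinPts should be rescaled
roughly with the area of the reach disc.

MinPts in ND mode does the border work: in homogeneous regions a pixel's
color-gated reach disc holds well over 70 pixels, while in the blurred
lesion/skin transition only a thin iso-color strip qualifies, so ramp
pixels fail the core test and the two regions do not chain together.
Lowering MinPts (or raising ε) merges lesion and background through the
ramp; raising it erodes the detected lesion.

## The phantom generator

`ndlesion.synthgen` generates dermoscopy-like phantoms with exact ground
truth: a uniform skin-colored background (default RGB 224,172,138), one
darker star-shaped lesion r(θ) = r0·(1 + Σ_k a_k sin(kθ+φ_k)) with
harmonics k ≤ 8 scaled by an irregularity parameter (area always lands in
5–60% of the image and fully interior), Gaussian per-channel noise,
border blur of configurable radius, and optional dark anti-aliased hair
strokes from the lesion interior to an image edge. The ground truth is
the *pre-blur* shape, mirroring evaluation against crisp manually drawn
borders. `contrast` is the ratio of the skin/lesion mean-luminance gap to
the per-channel noise σ; σ is derived from it unless overridden.
Difficulty presets (fixed once): easy (contrast 15, blur 1.0,
irregularity 0.25), low-contrast (lesion RGB 160,114,93 → gap ≈ 58 gray
levels, contrast 5, blur 2.5, irregularity 0.35), hairy (easy + 3
strokes). Everything is deterministic under the seed; suites are
regenerable bit-for-bit from their JSON manifest. Default phantom size is
96×96, large enough for the ND reach geometry while keeping a 50-phantom
benchmark in minutes on one core.

What the phantoms do **not** model: illumination gradients and vignetting,
multimodal skin texture, inhomogeneous lesion pigment, bubbles, rulers
and black frames. This matters for interpreting the benchmark below.

## What the benchmark does and does not show

On the fixed low-contrast suite the ND pipeline achieves a median border
error around 6–7% without any pre-processing, and the skip mechanism
saves ~40% of region queries on solid shapes. However, the binary
intermeans pipeline is *slightly better* on these phantoms (mean BE ≈ 5%
vs ≈ 6.5%). That is a property of the phantom, not a refutation of the
ND design: with a spatially uniform background and a uniform lesion, the
two luminance histograms are unimodal and the intermeans threshold lands
on the blur-ramp midpoint — which is exactly the true border — so global
thresholding is close to Bayes-optimal here. The ND cluster instead stops
where the core test fails on the ramp, systematically ~1 px short. The
documented advantages of clustering color directly arise on real images
where a single global threshold has no correct value (illumination
variation, multimodal skin, pigment fading toward the lesion margin);
passing phantom tests shows correctness and stability of the machinery,
not superiority on clinical data.

## Numerical and degenerate-input conventions

* Ties at the intermeans threshold go to the dark (lesion) class; a
  constant image is degenerate and returns its own value as threshold.
* Cluster ids are 1..K in creation order; noise is −1; seeds scan in
  row-major order, so all outputs are bit-reproducible.
* Undefined ratios (empty prediction/ truth) are NaN or raise, never 0.
* Degenerate convex hulls inflate by ε/4; empty inputs raise.
* Masks are {0,1} in memory, 0/255 on disk; grayscale images are promoted
  to RGB by replication so ND mode is total.

## Known limitations

* ND-mode skipping is conservative but unverified territory for images
  with strong color gradients inside a cluster; use `skip=False` when
  exact DBSCAN(ND) semantics matter (the package tests do).
* The selection rule assumes one dominant dark lesion; multiple lesions
  need `top_k > 1` and review.
* Hairs crossing the lesion merge dark strokes into the lesion cluster
  (the known failure mode of this method family); no artifact removal is
  provided.
* Runtime is dominated by polygon unions for very large ND clusters;
  images much beyond ~256×256 call for coarser ε or the plain DBSCAN
  reference.
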