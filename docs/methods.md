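# Methods

This note records the models behind each pipeline, the parameters that
matter, and the numerical choices made where the design was genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Image model and conventions

All pipelines operate on calibrated 2D intensity planes (`ImageFrame`) or
ordered z-/t-stacks (`ImageStack`).  Coordinates are 0-based pixel indices
with x = column, y = row, origin top-left; areas are reported in µm² via
`pixel_size²` and lengths in µm.  Calibration is always supplied by the
caller — TIFF resolution tags come in too many dialects to trust silently.
All randomness (phantoms, any stochastic step) flows from one explicit
integer seed; the default is 0, never wall-clock, so identical
configuration reproduces images and CSVs byte for byte.

Manual artefact correction is supported non-interactively: an optional
per-image exclusion mask is applied as a hard foreground exclusion before
any measurement, keeping runs reproducible.

## Stellate invasion pipeline

A stellate spheroid is one dense aggregate with strands of cells invading
the surrounding matrix.  The stages:

1. **Grey conversion** — unweighted channel mean, rounded half-up.
2. **Local background reduction** — morphological rolling ball: grey
   opening with a disc structuring element, subtracted (white top-hat).
   The image is padded edge-replicate by one ball radius first; without
   this the opening leaves a slope artefact one radius wide along the
   borders.  *The ball radius must exceed the radius of the largest object
   of interest*: any object the element fits inside is absorbed into the
   background estimate and erased.  The stellate default is therefore
   250 µm (above a typical ~150 µm core radius), while the tube pipeline,
   whose objects are ~12 µm wide, uses 50 µm.  Brightfield frames are
   intensity-inverted first so positive objects are uniformly bright.
3. **Foreground detection** — pixels strictly above an Otsu (default) or
   fixed threshold; the threshold used is logged.  A constant image has no
   Otsu threshold and raises a degenerate-histogram error.
4. **Density image** — Gaussian-smoothed foreground indicator (σ default
   20 µm, reflective boundaries), i.e. the local foreground fraction in
   [0, 1].  The density is computed on the binary mask, not on grey
   intensity: the mask convention makes the two zone thresholds
   illumination-invariant.
5. **Zone split** — inner core = hole-filled largest connected component
   of {density ≥ d_hi}; outer core = hole-filled largest component of
   {density ≥ d_lo} minus the inner core; periphery = remaining
   foreground.  All three are intersected with the foreground, so they
   partition it exactly (an invariant checked on every construction).
   Defaults d_hi = 0.75, d_lo = 0.35 are calibration choices — density-
   relative cut-offs, not absolute intensities.  The largest-component
   rule reflects the assay design of one aggregate per well; alternates
   are logged.
6. **Read-outs** — inner-core circularity 4πA/P² (see below) and the
   three zone areas.

## Circularity and sphericity estimators

Circularity needs a perimeter, and digitised boundaries bias naive
estimators in shape-dependent ways: a raw marching-squares contour
overestimates a disc's perimeter ~5% (staircase excess), while Crofton
projection estimators are accurate on discs but poor on axis-aligned
rectangles.  The package extracts the 0.5 iso-contour (sub-pixel marching
squares) and low-pass filters the vertex chain with a circular Gaussian
(σ = 2 vertices) before summing segment lengths: the staircase excess is
removed while straight edges stay essentially exact.  The result is
clamped to [0, 1].

Sphericity ψ = π^⅓(6V)^⅔ / A uses the exact voxel-count volume and a
marching-cubes isosurface at 0.5 for the area.  Binary masks are first ×3
supersampled (nearest neighbour) and lightly Gaussian-smoothed (σ = 0.7
original voxels): marching cubes straight on a binary mask inflates the
area of smooth objects (45° staircase facets), while heavier smoothing
rounds the edges of genuinely angular objects.  This setting keeps both
regimes accurate; voxels are assumed near-isotropic (resample anisotropic
stacks first).  Supersampling multiplies memory 27-fold, which is
negligible for per-object masks but worth noting for whole-stack input.

## Organoid live/dead cytometry

Dead cells (ethidium channel) are found by the union of two engines, each
producing a segmentation mask that is merged for the final detection:

* **Engine 1, dot-like structures** — maxima of the scale-normalised
  Laplacian-of-Gaussian response at scale `cell_diameter/2`.  A maximum is
  kept only if (a) its intensity falls by ≥ `centre_drop` (default 0.3, a
  calibration choice) of its above-background amplitude within one radius
  — the "bright centre, radially decreasing" profile — and (b) its
  amplitude exceeds 5 robust sigma (1.4826·MAD) of the image, so noise
  maxima are rejected without any hand-set intensity floor.
* **Engine 2, stained areas** — plain intensity threshold (fractional
  thresholds are relative to the image maximum, making detection invariant
  to global intensity rescaling).  Components smaller than a disc of half
  the cell diameter are noise specks and contribute no point; surviving
  component centroids not already claimed by an engine-1 maximum become
  additional points.

Live cells (calcein channel) use engine 2 alone.  Spheroids are detected
by a **double threshold on intensity and area**: threshold → hole-fill →
connected components → drop components below `min_area` (default: a disc
of three cell diameters — a spheroid must exceed a few cells).  Points on
a spheroid's boundary pixel count as inside (deterministic tie-break).
Per-spheroid statistics are area, circularity, live/dead point counts and
mean channel intensity over member dot footprints.  Z-stacks are reduced
by maximum intensity projection before analysis; there is no per-plane 3D
segmentation.

## Tube-network analysis

The binarised tube mask is reduced to a 1-pixel 8-connected topological
skeleton.  Pixels with ≠ 2 skeleton neighbours become node pixels;
adjacent node pixels merge into one node; segments are traced between
nodes with geodesic length (1 per axial step, √2 per diagonal, × pixel
size) — endpoint distance would under-measure curved tubes.  Then,
iteratively: terminal segments shorter than `prune_len` (default 10 µm)
are pruned; nodes left with degree 2 are contracted (their two segments
merge); and junction pairs joined by a segment shorter than `prune_len`
are merged into one junction.  The last rule matters because a thick
X-crossing skeletonises into two nearby Y-junctions; merging restores the
planted topology and preserves the Euler relation
*faces = segments − nodes + components*.

Classification follows the endpoint rule: extremity = degree 1, junction =
degree ≥ 3, master segment = both endpoints junctions, master junction =
junction incident to ≥ 1 master segment.  Meshes are the enclosed
background faces of the *binarised mask* (not the skeleton); faces
touching the image border are not meshes.

The angiogenesis index is the arithmetic mean of the six parameter ratios
treated/control.  Mean-of-ratios is the canonical reading; the CLI group
mode instead averages parameters within each group before forming ratios
(both coincide for a single image pair).  Any zero control parameter makes
its ratio undefined and raises an error naming the parameter.

## Spot tracking

Detection: scale-normalised LoG maxima at scale `diameter/2`, minimum
separation half a diameter, peak intensity filtered to a window (defaults
mirror the acquisition this was designed for: diameter 18 µm, window
30–230, with 20 µm maximum jumps, gap size 5 and 20 min frames).  Maxima
are refined to sub-pixel positions by a 3-point parabolic fit of the LoG
response per axis; without refinement, pixel quantisation alone puts
several percent of error on per-frame speeds at 1 µm pixels.  No further
"quality" filter is applied; the intensity window is the only spot filter.

Linking is globally optimal per frame pair, not greedy: squared
displacements within `max_dist` enter a gated assignment problem (the
standard 4-block construction where leaving a point unmatched costs the
gate).  Gap closing runs afterwards, ascending gap length, bridging a
track end to a later track start when the displacement is at most
`max_dist × (gap + 1)` — the classic two-pass tracker design.  Every
detection belongs to at most one track.  Mean speed averages displacement
over elapsed time across consecutive detections, so a bridged gap
contributes one displacement over its full elapsed time.

Note that frame-to-frame optimal matching is memoryless: two particles
meeting head-on on the same line can exchange identities if the swapped
assignment is cheaper at the crossing frame.  Resolving that requires
motion models, which are out of scope.

## Scalar scores

Tumour volume: V = π/6 (d₁·d₂)^{3/2} with both calipers in mm, giving mm³
((d₁·d₂) in mm² raised to 3/2 is the dimensionally consistent reading of
the ellipse-volume formula).  IHC: the percent-positive axis is the
right-closed partition 0 → 0, (0, 25] → 1, (25, 50] → 2, (50, 75] → 3,
(75, 100] → 4 — exhaustive and order-preserving, matching the usual
integer bin labels except for their gap between 75 and 76, which this
continuous reading closes — summed with the 0–3 intensity grade.

## Phantom generator: what it emulates and what it does not

* **Stellate** — hard-disc core plus radial chains of hard-disc cells
  (one cell per 25 µm of strand by default, starting 20 µm past the rim so
  core and invader truths are disjoint), multiplicative planar
  illumination (±10% by default), Poisson shot noise plus Gaussian read
  noise (σ 20 on a 700-count amplitude).
* **Organoid field** — rejection-packed discs (radius 30–60 µm, 20 µm
  edge separation) with Gaussian puncta (σ = diameter/4: bright centre,
  radial decay) for live/dead cells, separated by two diameters within a
  spheroid; the truth records exactly what was planted, which may be
  fewer puncta than requested for small spheroids.
* **Tube lattice** — jitterable rectangular lattice of dilated
  centrelines; the truth stores the generating graph (positions, degrees,
  edge lengths, face count and open areas computed from the *rasterised*
  tube width, which exceeds the nominal width by one centreline pixel).
* **Track movie** — constant-velocity particles with reflective walls,
  optional per-frame positional jitter and scheduled or random missed
  detections; rendered as Gaussian spots.

These phantoms share the statistical structure each stage assumes
(Poisson–Gaussian noise, smooth illumination, known geometry) but not the
texture of real data: no Matrigel texture, no optical PSF, no z-blur, no
cell-shape variability, no photobleaching.  Passing tests therefore
demonstrate algorithmic correctness and noise robustness at the stated
SNRs, not performance on arbitrary real images — parameter defaults
(thresholds, ball radii, density cut-offs) remain calibration choices on
real data.

## Problem sizes used in tests and the acceptance script

Phantoms are 512² (stellate, organoid), ≤ 360² (tube lattices) and 256²
(track movies, 20 frames); recovery statistics use 10 stellate seeds, 20
organoid fields and 20 movies, and 3D morphometry uses radius-20 balls and
20-voxel cubes.  These sizes give stable statistics while keeping the full
suite in the low minutes on one CPU.

## Known limitations

* One stellate aggregate per image; multi-spheroid stellate fields are out
  of scope.
* Tube analysis reports only the six parameters above, not the full
  vocabulary of twig/isolated-element statistics some macros produce.
* Tracking is 2D, without motion models or MSD analysis.
* Sphericity assumes near-isotropic voxels.
* The IHC intensity grade is an input, not measured from staining images.
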