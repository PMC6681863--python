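# Methods

## Problem and model

An infrared meibograph of the everted upper eyelid shows the tarsal
conjunctiva as a bright band crossed by vertically oriented bright
stripes (the meibomian glands) separated by narrow darker intergland
tissue.  Atrophy leaves wider gland-free regions (dropout).  The
pipeline classifies every ROI pixel as gland region, reflection, or
dropout, and reduces the eyelid to one row of quantities: dropout-area
percentage (DOA), gland count, mean gland length/width (mm), relative
length (% of local eyelid height), and a shape-irregularity score.

DOA is defined on pixel counts:

    DOA = 100 * (N_pxROI − N_pxGL − N_pxR) / N_pxROI

`N_pxGL` counts the *gland region* — the gland mask closed with a
radius-20 px disk, so background corridors narrower than ~40 px
(intergland tissue, anatomically narrower than the ~20 px gland width)
are absorbed, while wider corridors (true dropout) are not.  `N_pxR`
counts specular reflections (intensity > 200, strict), which are
excluded from both the gland region and the dropout.  The three classes
are kept disjoint: reflection pixels are removed from the closed gland
region before the formula is applied.

## ROI detection

The frame is split at the argmax of the row-mean intensity profile
smoothed with a 31-row moving average; the bright band guarantees the
argmax falls between the two boundaries.  A frame whose smoothed
profile never exceeds its median by 5 intensity units is rejected as
unusable (`FlatImageError`).

*Upper boundary* (on the upper half): grayscale erosion with a
radius-10 disk removes lashes and gland texture; unsharp masking
(amount 1, σ = 30 px Gaussian low-pass) and a 40 × 40 px median filter
leave a smooth wide structure; Otsu binarization and a horizontal Sobel
give edge components, those under 500 px are dropped, each survivor is
fitted with a quadratic in the column coordinate, and the curve with
the smallest strictly positive quadratic coefficient (convex, opening
downward in image coordinates) is kept.

*Lower boundary* (on the lower half): after a σ = 1.5 px denoising
blur, a 9 × 9 local-entropy filter responds strongly where the window
straddles the band/lid-margin step.  Per column, the *bottom-most*
local maximum with prominence ≥ 10% of the column's range **and**
height above the column's mid-range marks the boundary candidate; the
height gate rejects low-entropy noise bumps below the lid, and taking
the last peak rejects the glandular texture above.  Candidates are
joined (3 × 12 horizontal dilation, radius-6 disk closing), components
under 500 px dropped, and the widest component fitted with a degree-4
Chebyshev series on the rescaled column interval.  The degree-4
coefficient is constrained to ≤ 0 (concave): because the basis is
orthogonal, the constrained least-squares solution is the unconstrained
fit when admissible and otherwise the degree-≤ 3 fit with the top
coefficient zeroed.

*Refinement*: the region between the curves (half-open rows,
`upper(x) ≤ y < lower(x)`) seeds morphological Chan-Vese evolution on
the 9 × 9 local-standard-deviation transform (the band is textured, the
surround flat).  Numerical choices: 100 iterations maximum, smoothing
weight 2, evolution on a 2× decimated grid, convergence declared when
the mask changes by < 0.1% of its area between 10-iteration
checkpoints (typical convergence ≤ 30 iterations).  The std transform
smears the texture boundary outward by about half its window, so the
converged mask is eroded by a radius-4 disk before the largest
connected component is returned.

## Gland segmentation

The grayscale image (reflections suppressed, below) is band-passed with
a difference of Gaussians, σ = 2 px minus σ = 30 px — the unique
band-pass formed from the two stated low-passes.  Both blurs are
*normalized convolutions restricted to the ROI*; an unmasked wide blur
would mix the dark surround into the band and manufacture a positive
response strip just inside the boundary.

Thresholding is local-mean adaptive over a 35 × 35 px window with
threshold `local_mean + (1 − sensitivity) · spread`, where `spread` is
the standard deviation of the in-ROI response and `sensitivity = 0.8`
by default.  Sensitivity → 1 admits more pixels as foreground; the
margin stays positive so that texture-free dropout (response ≈ 0)
yields no foreground — a threshold below the local mean would mark half
of any flat region and percolate into spurious giant components.  A
5 × 3 median filter smooths gland outlines; components below 800 px or
with moment-ellipse orientation outside [40°, 140°] (horizontal lid
edges) are removed; 8-connectivity is used throughout, and labels are
numbered left to right by centroid column.

**Reflection suppression.** Saturated specular blobs otherwise sever
the glands they sit on into stacked fragments during thresholding.
Before the band-pass only, pixels above the reflection threshold
(dilated by 2 px for rim artifacts) are filled by linear interpolation
along their column, using rim values denoised with a σ = 2 px 1-D blur;
glands run vertically, so a column-wise fill continues the interrupted
structure.  The DOA still counts reflections from the original image.

**Fragmentation.** For each labeled object the column-wise pixel-count
profile is scanned for significant lobes (local maxima with prominence
≥ 20% of the profile maximum; each lobe is an apparent gland) and the
valleys between them.  A split is attempted when the lobe count exceeds
NlTH = 1 — i.e. more than one apparent gland — or the orientation is
more than OTH = 50° off vertical.  Cuts at the valley columns seed a
marker watershed on the object's distance transform, so every
foreground pixel is reassigned and none created or lost.  The split is
accepted only if more than NoTH = 1 fragments result, every fragment is
within O2TH = 50° of vertical, and every fragment's moment length/width
ratio is ≥ RTH = 3; otherwise the object passes through unchanged.
Accepted fragments are re-examined until nothing triggers, which makes
the operation idempotent.  The decision diagram behind these five
thresholds is a reconstruction — only the threshold names and values
are published — and the lobe reading of Nl was chosen because a
minima count can never trigger on a two-gland fork with NlTH = 1.

## Morphometrics

Length and width are the major/minor axis lengths of the ellipse with
the object's normalized second central moments (per-pixel variance
includes the +1/12 unit-square term; a uniform bar of geometric length
L therefore reports 2L/√3 ≈ 1.15 L, which is the standard convention
and matches an exact ellipse).  Relative length divides by the eyelid
height at the gland's centroid column, evaluated from the fitted
boundary curves (mask row extent for manual ROIs); oblique glands can
exceed 100% and are flagged.  The default scale 0.02 mm/px makes a
20 px gland ≈ 0.4 mm wide and is documented as approximate — the
instrument vendor does not publish the value.

For irregularity, the gland's outer boundary (0.5-level contour) is
intersected exactly with rays from the mass center at 1° steps.  When a
ray crosses the boundary more than once the outermost crossing is used
and a `NonStarShapedWarning` is emitted.  Radii are normalized by their
maximum (a circle profiles to 1 everywhere; config offers mean
normalization).  The reference envelope is the per-angle mean ± 1
sample SD over a population of regular glands; the score is the
trapezoidal integral over angle (degree units) of the profile's excess
above the upper limit plus its deficit below the lower limit.  The
eyelid-level score uses the per-angle mean profile of all detected
glands; per-gland scores are also reported.

The package ships an envelope built from **200 synthetic regular
glands** (smooth silhouettes, lengths ~400 ± 50 px, widths ~22 ± 4 px)
— a stand-in for a clinically curated population, labelled as such.
Scores against it are only meaningful for glands whose aspect ratio
resembles that population; users should rebuild the envelope from their
own reference glands via `build_envelope`.

## Grading and agreement

The Meiboscore preset reserves grade 0 for DOA exactly 0 and uses
(0, 32], (32, 65], (65, 100].  The objective preset uses [0, 16),
[16, 32], (32, 59], (59, 100], boundary conventions taken literally.
`otsu_class_limits` fits new limits by exact multi-level Otsu: DOA
values are histogrammed into 101 one-point bins and every combination
of cut points is searched exhaustively with prefix sums (≲ 1.7 × 10⁵
combinations for four classes), guaranteeing the global
within-class-variance minimum rather than a recursive approximation.
Cohen's κ is unweighted — (p_o − p_e)/(1 − p_e) — with the conventional
Landis–Koch verbal bands; a helper reconstructs κ from marginal grade
counts plus an agreement total for comparison with published summaries.

## Synthetic data generator

The generator renders the structures the pipeline is sensitive to, at
the acquisition scale (1360 × 1024 px frames, ~500 px central band
height tapering toward the canthi, 30 glands of 20 ± 2 px width by
default — intergland gaps ≈ 22 px, consistent with the anatomical
premise that intergland tissue is narrower than a gland).  Glands have
super-Gaussian cross profiles (amplitude 75 above a base of 95, over a
background of 30), mild lateral sinuosity, and span 98% of the local
band height.  Tissue carries fine vascular-scale mottling (σ ≈ 1.2 px
correlation, SD 8): visible to the local-std transform that drives
Chan-Vese, but carrying almost no energy in the gland-scale band-pass —
mirroring real dropout, which is smooth at gland scale yet textured at
vessel scale.  Dropout is carved as contiguous column spans whose ROI
area matches the requested fraction (clinical dropout is regional, not
salt-and-pepper); the truth DOA follows the dropout formula applied to
the truth counts exactly.  Reflections are saturated ellipses painted
last; a smooth horizontal illumination gradient (span 20) and Gaussian
sensor noise (SD 5) complete the frame.  One `default_rng(seed)` stream
drawn in a fixed order makes output byte-identical per seed.

What the generator does *not* emulate: eyelashes and skin below the
lid, depth-of-field blur, real conjunctival microstructure, curved or
branching glands, and acquisition artifacts other than saturation.
Passing the recovery tests therefore demonstrates the pipeline's
internal consistency at realistic geometry and noise, not clinical
accuracy.

## Accuracy characteristics

On the generator's study conditions (dropout 0/20/50/80%, 20 seeds
each, default geometry) the pipeline recovers DOA with a mean absolute
error ≈ 3–4 percentage points and a consistent *positive* bias: the
detected ROI includes tarsal tissue beyond the gland tips and lateral
to the outermost glands, which the gland-region closing cannot cover.
The direction matches the method's behaviour on clinical images, where
subjectively dropout-free lids measure a nonzero DOA.  The bias grows
mildly at high dropout because truncated gland stubs fail the 800-px
and orientation filters.  Automatic ROI masks overlap the true band at
Jaccard ≈ 0.95; gland counts are exact in ≥ 90% of no-dropout runs
across sparse (5) to dense (30) gland populations.

## Problem sizes in the test suite

The statistical tests run the full pipeline at the native 1360 × 1024
frame size: 80 runs for the recovery sweep and 60 segmentation-only
runs for count recovery.  The I/O and report tests use a 700 × 520
frame with 15 glands, which preserves the gland-to-gap geometry at a
quarter of the pixel count.

## Known limitations

- Parameters are calibrated for the reference resolution; other
  instruments need rescaled structuring elements and thresholds (all
  exposed in the YAML config).
- The fragmentation control flow is a reconstruction around the five
  published thresholds.
- The shipped irregularity envelope is synthetic; clinical use requires
  a user-supplied reference population.
- Lower-eyelid images and longitudinal image matching are out of scope.
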