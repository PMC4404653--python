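# Methods

This note records the measurement model behind `stalkscan`, the parameter
choices that matter, what the synthetic benchmark does and does not emulate,
and the numerical decisions a maintainer would want to know about.

## Imaging model and calibration

Input scans are 8-bit RGB rasters of bright stalk transections on a dark
background (scanner lid open). The only physical metadata used is the scan
resolution: `px_per_cm = dpi / 2.54`, kept at full precision internally
(800 dpi → 314.96 px/cm; the conventional "315 px/cm" is a rounded report).
16-bit inputs are divided by 257 onto the 8-bit scale because every threshold
in the chain assumes 0–255; grayscale inputs are replicated to three channels
so the green-channel rind step degrades gracefully rather than failing.

## Foreground segmentation and morphometry

Otsu's threshold is computed over integer intensity levels (the native 8-bit
grid) with foreground strictly above the level and the smallest maximizing
level on ties. This makes the threshold bit-exactly reproducible and
shift-equivariant under integer offsets, which the peak detector relies on.
A histogram with fewer than two occupied integer bins is treated as constant
(degenerate), so float-rounding jitter on a flat region cannot manufacture a
threshold.

Holes are filled before the debris filter: pith highlights can land below a
global threshold in dark scans, and unfilled holes would corrupt the area.
Debris removal keeps 8-connected components with ≥ 15 000 px and
moments-ellipse eccentricity ≤ 0.99; both bounds are inclusive and the filter
is idempotent. 8-connectivity was chosen because hand-cut sections can hang
together by single-pixel diagonal necks.

Three shape measures per section:

- **Area**: pixel count / px_per_cm², exact by construction.
- **Mean diameter**: twice the mean centroid-to-boundary distance (boundary =
  object pixels with a background 4-neighbor). The 4·A/P alternative was
  rejected as perimeter-noise-sensitive on ragged hand-cut outlines.
- **Perimeter**: length of the sub-pixel traced outer contour with every 5th
  vertex kept. Raw pixel-step tracing (unit/√2 steps) overestimates smooth
  digitized outlines by ~5–6%; the stride-5 polyline is within 0.4% on
  circles and ellipses and 0.15% on squares, comfortably inside the 2–3%
  agreement targeted against closed-form shapes.

Objects are ordered top-to-bottom then left-to-right, with centroid rows
grouped into bands wider than half the typical object height before sorting
by column — plain lexicographic ordering would let millimeter-scale vertical
jitter shuffle the left-to-right order of a scan row, breaking index-based
override files.

## Rind thickness

The green channel is smoothed with an isotropic Gaussian of
σ = `filter_width` × 0.02 × D, where D is the section's mean diameter in
pixels. Tying σ to the diameter makes the default `filter_width = 1.5`
transfer across species whose stalks differ several-fold in size; the useful
range is roughly 1–2.5, with larger widths suppressing rind texture more
aggressively at the cost of a slightly smaller recovered pith. Smoothing is
implemented as normalized (mask-weighted) convolution over the object only:
filling the outside with any constant measurably biases the boundary (up to
~7 px inward with a mean fill at width 2.5 on a 260/200 px test annulus),
while masked weighting keeps the bias within ~1 px at the default width and
~4 px at width 2.5. The residual width-dependent bias is inherent to
thresholding a heavily smoothed profile (curvature plus finite-rind
truncation), which is why the segmentation-path accuracy target is 5 px
rather than the 2 px the pure geometry (distance transform on exact masks)
achieves.

Otsu's threshold is taken over in-object smoothed intensities only — the dark
background would otherwise dominate the histogram. The largest above-threshold
component, hole-filled, is the pith; a flag is raised when the pith touches
more than 20% of the outer boundary (failed rind suppression). Thickness is
the mean over outer-boundary pixels of the exact Euclidean distance to the
nearest pith-boundary pixel; the distance-transform evaluation equals the
O(N²) brute-force nearest-neighbor computation to 10⁻⁶ relative error and is
measured from the outer boundary inward (the two directions differ for
eccentric piths; the outer-inward convention is implemented literally).

## Bundle detection

The counting chain is Gaussian convolution at the bundle scale → anisotropic
diffusion → flat-fielding → non-maximum suppression within the pith.

- **Bundle-scale smoothing**: σ = w_b/2 with w_b = 0.03 cm (≈ 9.4 px at
  315 px/cm), matching typical maize bundle footprints; *Miscanthus* needs a
  smaller width. In the pipeline the convolution is weighted by the pith mask:
  the dark rind otherwise bleeds into the smoothed field near the pith
  boundary, displacing or swallowing peaks of boundary-region bundles and
  seeding spurious rim maxima.
- **Perona–Malik diffusion**: 4-neighbor explicit scheme, per-pair fluxes
  applied antisymmetrically (total intensity conserved to rounding),
  reflecting boundaries, dt ≤ 0.25 for stability. Defaults κ = 0.5,
  100 iterations, dt = 0.2. The conduction threshold sits deliberately
  *between* the gradient scales present after bundle-scale smoothing:
  parenchyma-texture gradients (≲ 0.2 gray/px) diffuse away while bundle
  edge gradients (0.7–2.7 gray/px) are preserved, turning bundles into
  near-uniform bright spots on a flattened background — the contrast
  enhancement this stage exists for. A large κ (tens of gray levels) makes
  the step an ordinary linear blur on this field and measurably degrades
  the detection false-discovery rate.
- **Flat-fielding**: scanner illumination varies smoothly across a section;
  a ±15% linear gradient is enough to push dim-side bundles below any global
  threshold (recall drops to ~83% without correction). The background is
  estimated by mask-weighted Gaussian convolution inside the pith at
  4× the suppression radius — well above the bundle spacing, so bundles
  average out — and subtracted, re-centered on the pith mean.
- **Non-maximum suppression**: a detection is a pith pixel maximal within a
  disc of the suppression radius (default = bundle width) that exceeds the
  in-pith Otsu level by `min_prominence`. Ties resolve toward the smaller
  (row, col), and greedy suppression (highest value first) guarantees no two
  peaks closer than the radius; output order is deterministic. The default
  prominence is 1.0 gray level — background bumps at the quantization scale
  are rejected without costing dim true bundles. The pipeline additionally
  recomputes the Otsu level on the pith eroded by half a bundle width and
  uses the larger of the two levels: pixels within half a bundle width of the
  pith boundary dip toward the rind, and on sections with few bundles that
  dark tail drags the full-pith Otsu level into the background mode,
  flooding the detector with false maxima.

Manual bundle centers (from the JSON sidecar, replacing interactive clicks)
are dropped if outside the pith or within the suppression radius of an
automatic detection. Density is total count over pith area in cm².

Measured on the synthetic benchmark (two independent 20-image sets): mean
per-image recall 92.7% and 94.1%, mean false-discovery rate 4.1% and 7.7%,
at one-to-one matching within 8 px. The residual misses are mostly dim
bundles adjacent to much brighter ones, whose peaks merge at the fixed
smoothing scale, plus the dimmest bundles on low-illumination edges — a
"consistent though minor undercounting" regime.

## Bundle size

Each detected center yields a 40×40 px patch (reflection-padded and flagged
at image edges). Homomorphic enhancement takes log(1+I) (the +1 tolerates
zero pixels), applies a Gaussian high-emphasis transfer in the 2-D DFT
domain — gains 0.5 (low) to 1.5 (high), cutoff 8% of the patch side — and
exponentiates back; the output is min-max rescaled to [0, 255]. With equal
gains the operation is the identity up to that monotone rescaling. Because
the output is rescaled, the meaningful effect measure is the ratio of
illumination amplitude to bundle contrast: it falls ~30% at the default
gains and >70% under strong suppression (gain_low ≈ 0.05), monotonically in
the low gain.

The fit is baseline + A·exp(−½ qᵀΣ⁻¹q) with a full 2×2 covariance
(bundles are visibly elliptical and oriented), initialized from intensity
moments of the central half of the patch and bounded so the fitted center
stays within a quarter patch of the detected center and the footprint fits
the patch — neighboring bundles inside the 40 px window would otherwise
capture the fit. A fit counts as converged only if the optimizer succeeded,
the amplitude is positive, σ_minor ≥ 0.5 px, and the model explains ≥ 20% of
the patch variance (rejecting pure-noise and uniform patches). The reported
area is the 2σ level ellipse, A = π(2σ_a)(2σ_b); the multiplier is a config
parameter (`contour_sigma`) for users who prefer other level conventions.
On model-generated blobs the fit recovers σ to <1% noiseless and <10% median
area error at 5% amplitude noise. Fits through the homomorphic path measure
the *enhanced* blob, whose effective width is slightly reshaped by the
high-emphasis transfer; sizes are therefore comparable within a processing
convention, not absolute tissue areas — which is also true of the level-set
convention itself.

## Synthetic benchmark

The generator renders what the detection chain actually has to cope with:
antialiased discs (4× supersampled edges) with a darker rind annulus; 60–220
rotated-Gaussian bundles rejection-sampled in the pith at ≥ 16 px spacing
(2× the largest bundle radius), boosts 45–75 gray levels, σ_major 2.2–4 px;
correlated parenchyma texture (amplitude 4 at 3 px scale); a ±15% planar
illumination gradient; i.i.d. σ=5 pixel noise; and debris rendered to
exercise both filter clauses (thin strokes with eccentricity > 0.99, blobs
well under 15 000 px). A single seeded generator drives every draw, so equal
specs give byte-identical images, and the returned ground truth (masks,
centers, per-bundle shape parameters) is consistent with the rendering by
construction.

It does **not** emulate: section-thickness halo effects (thick cuts shadow
at the rim), physical damage and insect feeding, stain variation, bundle
sheath substructure, within-section intensity drift other than a plane, or
optical blur beyond edge antialiasing. Passing the benchmark therefore
demonstrates the pipeline's behavior under controlled nuisance factors, not
performance on damaged or poorly prepared real sections — on real scans the
sample preparation quality dominates.

## Degenerate inputs and failure isolation

Constant images (no Otsu threshold), contrast-free interiors (no pith/rind
split), empty piths, and unfittable patches raise typed errors at the module
level; the batch driver catches them per object, logs, leaves the affected
trait fields missing (NaN), and continues — a phenotyping batch must survive
individual bad sections. Zero pith area writes a bundle density of 0 (with a
warning) rather than NaN to keep CSV consumers simple. Re-running an
identical batch reproduces the trait CSV byte-for-byte; there is no hidden
randomness anywhere in the measurement path.

## Problem sizes used in the shipped checks

The quantitative checks run on 760² single-section images (20 per benchmark
set), 600² multi-object scenes, 200-blob fit-recovery batches, and ≤ 10⁴
boundary-pixel masks for the brute-force distance oracle — sizes chosen so
the full suite completes in a few minutes on one CPU while every claim is
still measured, not assumed.
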