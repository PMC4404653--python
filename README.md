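# stalkscan

Semi-automated phenotyping of grass stalk cross-sections from flatbed-scanner
images.

Hand-cut transections of maize, sorghum, or *Miscanthus* internodes laid on a
document scanner (lid open, dark background, typically 800 dpi RGB) carry a
surprising amount of anatomical information: stalk diameter, rind thickness,
pith area, and the number, density, and size of the vascular bundles scattered
through the pith. These traits matter for stalk strength, biofuel suitability,
and water/nutrient transport, but measuring them under a microscope is far too
slow for genetic studies with thousands of samples. `stalkscan` extracts all of
them from scan images automatically, with file-based overrides where a human
needs to intervene, and ships a synthetic-scan generator with exact ground
truth so every stage is testable without real scans.

## Method

For each scan (possibly holding a dozen sections at once):

1. **Segmentation** — luminance grayscale, Otsu's threshold *t* maximizing the
   between-class variance over the 256-level histogram (foreground > *t*),
   hole filling, then a debris filter that removes connected components
   smaller than 15 000 px or with moments-ellipse eccentricity
   e = √(1 − (b/a)²) > 0.99. Each surviving object is cropped by its tight
   bounding box and measured: area A/s² (s = px/cm = dpi/2.54), mean diameter
   as twice the mean centroid-to-boundary distance, and traced-contour
   perimeter.
2. **Rind thickness** — the green channel is smoothed by mask-weighted
   Gaussian convolution with σ = w · 0.02 · D (D = section diameter in px,
   w the `filter_width` knob, default 1.5), suppressing the darker rind while
   keeping the bright pith. Otsu's threshold over the in-object smoothed
   intensities yields the pith mask; rind thickness is the mean Euclidean
   distance from each outer-boundary pixel to the nearest pith-boundary pixel
   (exact distance transform).
3. **Bundle count and density** — the grayscale is convolved with a Gaussian
   about one bundle wide (σ = w_b/2, w_b = 0.03 cm by default), sharpened by
   Perona–Malik anisotropic diffusion
   ∂I/∂t = ∇·(g(|∇I|)∇I), g(d) = exp(−(d/κ)²),
   flat-fielded inside the pith, and bundle centers are found by non-maximum
   suppression over a disc neighborhood, keeping in-pith peaks above the
   in-pith Otsu level. Density = count / pith area; manually picked centers
   from a JSON sidecar are merged in without double counting.
4. **Bundle size** — a 40×40 px patch around each center is enhanced by
   homomorphic filtering (log → 2-D DFT → Gaussian high-emphasis transfer
   H(f) = g_l + (g_h − g_l)(1 − e^{−|f|²/2σ_f²}) → inverse → exp), a rotated
   2-D Gaussian with baseline is least-squares fit, and the bundle area is
   the 2σ level ellipse, A = π(2σ_a)(2σ_b), converted to cm².

All tunables live in `PipelineConfig` / a YAML config file; every run can
write a provenance sidecar with the effective parameters and crop boxes.

## Worked example

Render a synthetic 140-bundle section and measure it:

```sh
$ stalkscan synth example.tif --seed 5 --n-bundles 140
wrote example.tif (760x760, seed 5)
$ stalkscan analyze example.tif --out traits.csv
1 transections from 1/1 scans -> traits.csv
$ cat traits.csv
source_id,transection_index,area_cm2,mean_diameter_cm,perimeter_cm,rind_thickness_cm,pith_area_cm2,bundle_count,bundle_density_per_cm2,mean_bundle_area_cm2,n_manual_bundles
example.tif,0,2.48024,1.77417,5.60426,0.16836,1.62692,140,86.0521,0.00227973,0
```

The rendered section has outer radius 280 px and a 50 px rind at 800 dpi
(314.96 px/cm), i.e. a true diameter of 1.778 cm and rind of 0.159 cm; the
measured 1.774 cm diameter and 0.168 cm rind agree to the smoothing scale of
the boundary estimate. The detected count of 140 equals the rendered count,
with 133 detections matching true bundles one-to-one within 8 px (95% recall
and precision on this seed; across many seeds mean recall is ≈93% with ≈5%
false discoveries). Bundle areas of ≈2.3 × 10⁻³ cm² sit in the expected range
for maize-like sections.

The same `analyze` command takes real TIFF/PNG scans (dpi from file metadata
or `--dpi`), multiple files at once, a `--config` YAML for species-specific
parameters, and an `--overrides` sidecar for crop adjustments and manually
added bundles.

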