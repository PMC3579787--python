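# Methods

## Model

A nematode on an agar surface is modeled as a solid of revolution: a tube
of varying radius r(s) swept along a smooth planar backbone of arclength
L. The only shape assumption is radial symmetry of the cross-section, so

  V = ∫₀ᴸ π r(s)² ds.

The pipeline estimates L as the length of the worm's medial axis and
r(s) as the orthogonal distance from that axis to the contour, then
integrates by summing conical frustums between samples spaced h pixels
apart. The frustum sum is exact for piecewise-linear radius profiles
(cylinders, cones) and second-order accurate otherwise; its error is the
taper curvature missed between samples.

## Pipeline stages and parameters

| parameter | default | units | role |
|---|---|---|---|
| `ball_radius_px` | 50 | px | rolling-ball radius for background estimation; must be well above the worm half-width and well below the illumination wavelength |
| `light_background` | true | — | brightfield convention (dark worms on bright agar) |
| `threshold_algorithm` | `"minimum"` | — | only the Minimum method is built in |
| `area_min_px2`, `area_max_px2` | 100, 10⁶ | px² | candidate area band; bounds far from any plausible worm |
| `prune_ratio_min` | 0.8 | — | minimum pruned/total skeleton length; rejects heavily branched blobs, tolerates tip spurs |
| `extension_window_px` | 5 | px | points used to fit tip tangents and tangent window for radius normals |
| `interval_px` | 10 | px | radius sampling interval; stable from 5 px up to ~10% of worm length |

**Background subtraction.** Sternberg's rolling ball (a true spherical
structuring element, not the paraboloid shortcut) estimates the
background of the inverted image; the estimate is subtracted and its
global mean added back, so output is bright worms on a flat dark field.
Inversion happens once — the output is deliberately left in the
bright-objects convention the thresholding stage expects. Two geometric
regimes bound the radius choice: shading with wavelength ≫ radius is
removed exactly (the opening of a plane is the plane), while a worm of
width w causes an irreducible under-worm background bulge of
r − √(r² − w²/4) (≈2.8 intensity units at r = 50, w = 33), which is why
re-subtraction is only idempotent to ~1 unit when the ball is
comfortably wider than the worm.

**Minimum thresholding.** The 256-bin histogram is smoothed with the
window-3 moving average (edges repeated) until exactly two *strict*
local maxima remain (plateaus never count — this makes "exactly two"
decidable), capped at 10,000 passes; monotone or uniform histograms
raise and the image is skipped. The threshold is the valley t with
y(t−1) > y(t) ≤ y(t+1) strictly between the peaks; among qualifying
valleys the lowest count wins, ties to the smallest t. Foreground is
8-connected, background 4-connected; contours come from Moore boundary
tracing with a repeated-state stopping rule.

**Skeleton to path.** Thinning uses Lee's topological method. Skeleton
pixels become a graph with edge weights 1/√2; a diagonal edge is dropped
whenever one of its orthogonal bridging pixels is also on the skeleton,
since otherwise every corner of a thin digital curve forms a spurious
3-cycle and the cycle test would reject every worm. After that pruning
of the adjacency structure, a genuine cycle means a self-touching worm
and the object auto-fails (it is rejected, not repaired). The heaviest
endpoint-to-endpoint path is found by two Dijkstra sweeps from
degree-one nodes, which is exact on trees; equal-weight ties resolve to
the path whose starting endpoint is smallest in (row, col), so output is
deterministic.

**Staircase correction.** The chain-code length of an 8-connected
digitization overestimates smooth-curve arclength by roughly 4–5% at
generic orientations. The pruned path coordinates are therefore smoothed
with a 5-point moving average (window shrinking symmetrically at the
ends, so the tips stay fixed) before tangent extension and measurement.
This brings length recovery on phantoms from ≈ +4% to within ±0.7% and
also stabilizes the tip tangent fits. Reported lengths remain the
Euclidean sum over the (smoothed, subpixel) path.

**Tip extension and radius sampling.** Tip directions are the leading
principal component of the last `extension_window_px`+1 path points,
oriented outward; the tip marches in 0.5 px steps until the first sample
leaves the mask. Radii are sampled at arclengths 0, h, 2h, … plus the
exact end; normals (perpendicular to a ±5 px central-difference tangent)
march both ways in 0.25 px steps, and each one-sided distance is the
midpoint between the last inside and first outside sample — the literal
first-outside distance would bias radii by about +0.2 px, ~2% of volume
at adult scale. The radius is the mean of the two sides (robust to the
skeleton sitting slightly off-center); width is their sum. Both tips get
explicit r = 0 samples, so the closing segments are cones — consistent
with a worm whose width vanishes at head and tail, but deliberately
wrong for flat-ended objects like rectangles. Pixel membership uses
half-up rounding; banker's rounding would bias the two sides of a
symmetric object differently. Average width excludes the two zero tip
samples (otherwise it is biased low by construction); mid width is taken
at the sample nearest L/2.

## Phantoms: what they emulate and what they do not

The generator renders the stated model directly: natural cubic spline
backbone (chord-length parameterized, arclength by dense 0.25 px polyline
summation), radius profile r(u) = r_mid(4u(1−u))^0.3 (nearly uniform
mid-body, short tapered tips, zero at both ends), a pixel is worm iff its
center lies within r(u*) of the backbone (u* = nearest dense sample), a
tilted-plane illumination ramp of configurable peak-to-peak amplitude,
and seeded additive Gaussian noise clipped to [0, 255]. Default
proportions follow the two developmental stages used for precision work:
young adults (~720 µm long, ~30 µm mid radius) and arrested L1 larvae
(~205 µm, ~10 µm). Scales of 1.5 and 0.5 µm/px put these at a few
hundred pixels, typical of a stereomicroscope at the corresponding zooms.

Phantoms have hard two-level edges: no depth-of-field blur, no
partial-volume boundary pixels, no agar meniscus obscuring L1 heads and
tails, no touching or tangled animals, no motion blur. Consequently a
green recovery test establishes the geometric correctness of the
skeleton/radius/volume chain under noise and shading — it does not
establish robustness to defocus or to the segmentation boundary shifts
that real optics produce. Noise alone cannot flip a pixel across the
threshold at the default 140-unit contrast; geometry, not noise,
dominates phantom-to-phantom variation, and the self-intersection check
(backbone stretches farther apart than 4·r_max in arclength must stay
2·r_max apart in space) rejects tangled specifications rather than
rendering them.

## Statistics

Skewness and excess kurtosis use the moment definitions g₁ = m₃/m₂^{3/2}
and g₂ = m₄/m₂² − 3 with mₖ the biased central sample moments. The
unequal-n comparison subsamples the larger group (pooled across
replicates — total-count balancing; per-replicate balancing is a
plausible alternative reading) down to the smaller without replacement,
runs an equal-variance two-sided Student's t-test, repeats 1000 times
under one seeded generator, and Bonferroni-multiplies the median p,
capping at 1. Slope comparison fits two OLS regressions and refers
(b₁ − b₂)/se to Student's t with n₁ + n₂ − 4 df, where
se² = s²_p(1/Sxx₁ + 1/Sxx₂) pools the residual mean squares; a zero se
with unequal slopes (noiseless data) reports p = 0. Power analysis
solves 1 − β = 1 − F_nct(t_{1−α/2, 2(n−1)}; 2(n−1), (δ/σ)√(n/2)) for
real n by Brent's method on [2, 10⁷] (tolerance 10⁻⁶) and returns the
ceiling; at the ceiling the achieved power is verified ≥ 1 − β.
δ and σ are both expressed as fractions of the control mean, so σ is the
sample CV.

## Numerical choices and degenerate inputs

- Histograms with fewer than two nonzero bins, or that never reach
  bimodality within the smoothing cap, raise a no-threshold error; the
  caller logs and skips the image.
- Zoom scales interpolate linearly between recorded entries and refuse
  to extrapolate outside the recorded range.
- Profiles with a single sample return volume 0 with a warning; empty
  masks, constant-x regressions, zero-variance moment inputs all raise.
- CSV floats are written at full repr precision and re-read with
  round-trip parsing, so write→read is lossless; JPEG is accepted on
  input (luminance-converted) but never written.
- All randomness (phantom noise, subsampling) flows through explicitly
  seeded generators; reruns of the measurement path are byte-identical.

## Known limitations

- Touching, overlapping or self-intersecting worms are rejected, not
  untangled; the review sidecar is the intended recourse.
- The Minimum method is the only built-in thresholder; images whose
  corrected histogram is not bimodal (empty fields, debris fields) are
  skipped rather than force-thresholded.
- Radius sampling assumes the normal ray exits the mask within 10³ px;
  pathological masks raise rather than hang.
- Very short worms (path shorter than the tangent window) cannot be
  measured and fail with a reason string rather than a crash.
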