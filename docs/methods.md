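# Methods

This note documents the models, numerical choices and limitations behind
`retvasc`. Coordinates are (x = column, y = row), 0-based, pixel centers at
integer coordinates, y increasing downward; intensities are floats in [0, 1];
all lengths are pixels of the working frame (the canonical frame is
1024 × 1024 px) unless stated otherwise.

## Field-of-view detection and preprocessing

A fundus photograph shows a bright, roughly circular field of view (FOV) on a
dark background, often truncated flat where the circle overruns the sensor.
Detection thresholds the max-channel intensity at 5% of its robust (99th
percentile) maximum, keeps the largest connected component, and fits a circle
(algebraic least squares) to the component's boundary pixels, excluding
pixels on image edges and on detected flat truncations. A clipping line is
declared on an image edge when at least 2% of boundary pixels lie on it, and
is placed at the extreme occupied row/column. Half a pixel is added to the
fitted radius because boundary pixel centers sit inside the true circle.
On rendered test scenes this recovers the planted circle center within
0.1 px and the radius within 0.1%.

Cropping maps the tight square around the bounded region (circle ∩
half-planes, clipped to the frame) onto the target square via a similarity
transform (`forward(p) = scale·p + offset`); images are resampled
bilinearly, label masks nearest-neighbor. Contrast enhancement is the
center-surround form `clip(gain·(I − G_σ(I)) + offset, 0, 1)` per channel,
with gain 4, offset 0.5 and σ = 0.05 × target size by default — the
classical unsharp family for fundus images; all three constants are
configurable and not asserted to match any particular device pipeline.
Before blurring, interior content is mirrored across the FOV boundary
(reflection across flat clipping lines, then radial reflection across the
circle), and the exterior is blacked out afterwards; this avoids the bright
halo a dark exterior would otherwise inject at the rim. The cropped and
enhanced images stack to the six-channel input used by downstream
segmentation models.

## Vessel graphs

Binary masks (artery = labels {1,3}, vein = labels {2,3} of the 4-level
encoding) are thinned with topology-preserving skeletonization
(scikit-image). Holes under 64 px are filled first: at vessel scale they are
aliasing artifacts and would otherwise become skeleton rings. Skeleton
pixels with ≥3 neighbors are branch pixels, clustered by 8-connectivity into
one node at their centroid; pixels with exactly one neighbor are endpoints;
maximal chains between node pixels become segments whose endpoints coincide
with node positions. Pruning removes terminal segments and tiny loops
shorter than 15 px and re-merges degree-2 chains, iterating to a fixed
point (idempotent). The 15 px default removes the "fishtail" spurs thinning
leaves at blunt stroke ends (observed up to ~12 px for calibers near 16)
while leaving real terminal branches untouched.

**Calibers.** Raw skeleton pixels jitter up to half a pixel off the vessel
axis. Each segment's polyline is smoothed with a moving average whose window
grows with the vessel caliber (11 px minimum, ~1.2 × caliber for thick
vessels, two-pass), and the caliber at each point is then measured as the
distance between the two 0.5-level crossings of the bilinearly interpolated
mask along the local normal (sub-pixel perpendicular profile). Unlike a raw
distance-transform read-out, this does not depend on where the mask boundary
falls relative to pixel centers, so widths are consistent across
orientations (±0.7 px worst case on rendered strokes of 3–14 px) and across
resampling (2× upsampling changes the read-back ratio by <3%). Points within
one representative (median) caliber of a segment tip are flagged and
excluded from caliber statistics, because strokes taper there.

## Centerline metrology

Chain-code arc lengths of pixel skeletons overestimate true lengths by up to
~8% (staircase effect), and raw second differences of quantized coordinates
are useless for curvature. All length/curvature measurements therefore use a
canonical centerline: the polyline resampled at 1 px arc-length spacing and
smoothed with a 29-sample moving average. On this line:

- **Tortuosity** is arc/chord of the canonical polyline (straight lines read
  1.0000 ± 0.0004; digitized arcs match the closed form `φ / 2 sin(φ/2)` to
  <0.3%).
- **Curvature** uses Savitzky–Golay first/second derivatives (window 25,
  cubic) of the canonical polyline:
  `κ = (x'y'' − y'x'') / (x'² + y'²)^{3/2}`. The per-segment feature is
  mean |κ| × 10³ over the interior, excluding the combined filter half-span
  (27 samples) at each end where end-handling attenuates the estimate;
  segments shorter than 80 px are skipped for curvature and inflection
  aggregation because their interiors cannot clear the filter span and the
  estimate would measure junction hooks instead of vessel geometry (the
  20 px eligibility used for tortuosity is too permissive here).
- **Inflections** count sign changes of the additionally smoothed (9-sample
  boxcar) signed curvature, with hysteresis at a 5 × 10⁻⁴ px⁻¹ noise floor —
  set above the ~1–2 × 10⁻³ px⁻¹ quantization noise a perfectly straight
  digitized vessel shows, so straight vessels count zero.

Thick curved vessels leave slow (~60 px wavelength, ~0.3–0.6 px amplitude)
thinning wiggles in their skeletons that no reasonable smoothing window can
remove; per-segment mean |κ| on short wide segments is therefore accurate
only to ~±5–7%, while long segments (arcades, ~400 px) are stable to ~±1%.
Median aggregation over segments absorbs the per-segment noise.

**Bifurcations.** At each degree-3 branchpoint the two thinner incident
branches (by local caliber over the first 20 px; ties broken toward the
smaller angle with the parent) are the daughters. Each branch direction is
the principal axis (total least squares) of the centerline window starting
one parent-caliber past the node (skipping the junction-distorted stretch)
and extending 60 px, stopping one caliber short of a free tip. Degree ≥ 4
nodes are skipped and counted in diagnostics. Recovery accuracy on planted
trees is ~0.5°, and the estimate moves <1% under 90° lattice rotation.

**Temporal angle.** Centerline crossings of the circle of radius 1.5 DD
about the disc center are collected on the temporal half-plane (the side
containing the fovea); the maximum-caliber crossing above and below the
disc–fovea axis are the arcade representatives and the feature is the angle
they subtend at the disc center. Missing when either side has no crossing.

**CRE.** Segment widths in the measurement zone are the median caliber of
in-zone centerline points per segment; the six largest enter the iterative
pairing (sort, combine largest with smallest by `c·sqrt(w1²+w2²)`, carry the
median element when the count is odd). With fewer than six zone vessels the
available ones are combined (a single width is its own equivalent).

## Regions

The optic disc is summarized by the centroid and equivalent diameter
`DD = 2·sqrt(area/π)` of the largest disc-mask component. The CRE zone
defaults to the classical zone B, radii [1.0, 1.5] × DD from the disc
center (0.5–1.0 DD from the margin); the arcade sampling circle is 1.5 DD.
The ETDRS grid places rings of 1/3/6 mm diameter about the fovea, with the
two outer rings split into four quadrants by the diagonals; the mm scale
uses the nominal 1 DD = 1.8 mm when no device calibration exists. All radii
and the mm-per-DD rule are configurable; they are literature-standard
defaults, not claims about any specific legacy pipeline.

## Keypoint heatmaps

A keypoint is encoded as `H(p) = exp(−‖p−kp‖²/2σ²)` (peak normalized to 1 —
MSE-trained consumers are amplitude-sensitive, so the constant is part of
the contract), with σ = 50 px on a 512 × 512 raster by default. Decoding
takes the raw argmax (row-major first occurrence on ties, no sub-pixel
refinement); flat heatmaps are flagged low-confidence.

## Evaluation

Dice is `2|A∩B|/(|A|+|B|)`, defined as 1 (with a warning) when both masks
are empty so per-image averages over sets with legitimately empty classes
stay meaningful. Artery/vein label rasters are compared after the
crossing-merge (label 3 counts for both classes). Feature agreement pairs
tables by image id and reports per-feature MAE and Pearson r over non-missing
pairs (r is missing when either side is constant). Significance of an MAE
difference between two candidate pipelines uses a two-sided sign-flip
permutation test on paired differences of absolute errors (10⁴ seeded
permutations, add-one p-value); the test choice is a documented substitute —
the convention in the field's reports is usually unstated.

## Synthetic scenes

The generator plants parametric fibers whose properties have closed forms or
quadrature values: two thick arcade arcs per class (circle through three
control points; randomized by *rigid rotation* about the disc center so the
planted crossing angle varies while the arc curvature stays fixed), six
"spoke" arcs per class interleaved in the nasal band carrying the planted
CRE width set, and small temporal trees of straight branches with planted
bifurcation angles. A sinusoidal spoke mode (displacement A·sin(2πt/λ))
provides planted inflection counts by construction; the default mode is
constant-curvature arcs so every planted curvature is exact.

Construction rules that make recovery well-posed, chosen once at design
time:

- Within one class, fibers keep ≥3 px of stroke clearance (checked at
  construction; infeasible random draws are rejected and redrawn from the
  same stream, keeping determinism per seed). Artery–vein crossings are
  allowed and produce label-3 pixels, as in real images.
- Stroke ends taper linearly (full width down to a third over one caliber):
  blunt caps would leave thinning fishtails at any scale.
- Three spokes per class share the class's modal width, giving the pooled
  caliber distribution a wide plateau at its median, so the planted median
  is not a knife-edge statistic.
- Spoke bend radii alternate between a strongly curved (R ≈ 215–245 px) and
  a gently curved (R ≈ 450–520 px) triple, so the two arcades — identical in
  curvature and measured most stably — occupy the central ranks of the
  per-class curvature distribution.

Planted feature values are computed from the generating curves (arc lengths
and sinusoid integrals by quadrature; stroked areas analytically with the
taper correction), never from rasters. Default study conditions: 1024 px
frame, FOV radius 0.46–0.49 of the frame (0.52–0.58 in edge-clipped draws),
disc at 0.32–0.34 of the width with DD ≈ 115–140 px, fovea 2.35–2.6 DD
temporal to the disc, arcade angles 55–68° per side (veins ≥59°, keeping the
rotated arcade clear of the vein trees), calibers ~3–17 px. Scenes are
deterministic: identical configs give bit-identical outputs.

What the generator does **not** emulate: photorealistic texture, pathology
(hemorrhages, exudates, neovascularization), broken or fragmented
segmentations, caliber variation along a vessel, and vessel trees of
realistic depth. Passing recovery tests therefore demonstrates the
correctness of the measurement chain on clean geometry, not robustness to
real segmentation noise; the degradation module (blur, vignette, mask
dropout) probes the input side but its outputs are not part of the recovery
claims.

## Problem sizes and tolerances used in validation

FOV recovery uses 50 scenes at 512 px (center within 2 px, radius within 1%,
clip lines exact); chain recovery uses 25 scenes at 1024 px (tortuosity
median 1%, caliber median 1 px, bifurcation count exact, bifurcation angle
mean 5°, density 0.5 points, CRE 5%, temporal angle 3°, curvature median 5%
on constant-curvature scenes); invariance uses 10 scenes compared after
90° lattice rotation (<2% feature change, temporal angle <3°) and after 2×
bilinear upsampling (caliber/CRE double ±5%, curvature halves ±5%,
tortuosity/angles unchanged ±2%). For rescaled frames every pixel-valued
measurement parameter scales with the frame (`BiomarkerConfig.scaled`),
which is what makes the measurement the same computation on the rescaled
lattice. Observed worst-case margins are typically 2–10× inside these
tolerances.
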