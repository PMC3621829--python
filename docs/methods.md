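# Methods

This note documents the models behind `cytofocus`: what the virtual scanner
simulates, how each classifier is defined, which constants matter, and what
the synthetic experiments do and do not demonstrate about real slides.

## The virtual slide

A slide is a deterministic function of a config and a seed. Its parts:

- **Geometry.** Default extent 1884 × 1884 µm — the native 4096-pixel scan
  width at 0.46 µm px⁻¹ — with a cell circle of 0.85 × the extent standing in
  for the 22 mm ThinPrep deposition circle at desk scale. Coordinates are
  physical µm, origin top-left, x along columns.
- **Focal surface.** A control grid of z heights (default 4 × 4) spanning the
  slide, rescaled to the requested peak-to-peak range and evaluated
  bilinearly. Bilinear interpolation attains its extrema at grid nodes, so
  the evaluated range equals the request exactly. The default range is
  20 µm; the six-slide z survey that motivates the design measured
  11.8–29.5 µm, and its coarse control grid reflects that cover-slipping
  perturbs cell heights only slowly across the slide. Cell-layer heights
  sit near 100 µm, mimicking focus heights normalized against the
  objective's z origin.
- **Cells.** Uniform positions inside the circle (polar square-root
  sampling); radius 7–16 µm; stain classes hematoxylin-only, p16 (DAB) and
  Ki-67 (Fast Red) mixed 70/18/12; 15 % of records render as overlapping
  ellipse clusters. Each record carries an appearance seed so its rendering
  is identical at every focus height.
- **Dust.** Specks of 2–7 µm at a configurable density (default 10 mm⁻²)
  anywhere on the slide, on a plane 60 µm nearer the objective than the mean
  cell surface. The offset is a free parameter of the simulation: the
  two-layer separation is qualitatively documented but its physical distance
  is not, so the default is simply large compared with any cell-layer range.

### Rendering and defocus

Stains absorb: rendering composes per-structure transmittances
multiplicatively against bright glass (background gray 235), which handles
overlapping cells naturally. Each structure is painted as an anti-aliased
ellipse whose *absorbance depth* (peak grayscale step) is specified
directly — cytoplasm 0.035–0.055, nucleus 0.055–0.075 in [0, 1] luma units —
with fine multiplicative granularity (chromatin texture, ~1.6 px scale)
carrying the crisp detail. Stain chroma is decoupled from depth by using
saturated absorber colors, so pale material still has measurable hue.

Two properties of this design are deliberate and load-bearing:

1. **Gentle outlines, sharp texture.** A Canny detector run on a defocused
   image counts the thinned ridge of any boundary whose gradient still
   clears the threshold; because a blurred ring's circumference grows with
   the blur radius, *high-contrast outlines make the edge count rise before
   it collapses*. Real pale cytology has low-contrast outlines and
   fine-grained chromatin, and with depths as above the boundary ridges
   extinguish within one 2 µm defocus step while the in-focus count is
   dominated by texture — making the edge count monotone in defocus, as the
   classifier assumes.
2. **Defocus = Gaussian blur, σ = 1.2 px µm⁻¹, capped at 9.6 px.** The slope
   follows the geometric blur of a 0.75-NA objective (disc radius ≈ NA·Δz,
   i.e. ~1.6 px µm⁻¹ at this sampling; σ about 0.7 × that). The cap encodes
   that beyond ~8 µm of defocus the image carries no usable structure;
   rendering farther out of focus changes nothing measurable. A real point
   spread function (rings, contrast reversal) is out of scope — Gaussian
   blur is monotone in defocus, which is the property every classifier
   here relies on.

Renders are 8-bit. Optional additive Gaussian noise exists but defaults to
0 so that flat-field examples are exactly flat.

## Focus-point validity filter

Segmentation thresholds the luma image (Rec. 601 weights) at the
background level minus a 2-level guard; the background level is estimated
per image as the intensity-histogram mode, falling back to 230 when the
mode is implausibly dark. The three criteria:

- **size** — any connected component ≥ 200 px (a small superficial-cell
  nucleus at 20×). When strips are downscaled by a factor f the threshold
  defaults to 200/f² so the physical-area semantics survive.
- **edge** — scikit-image Canny with σ = 1.41 and absolute high threshold
  0.07 on the [0, 1] grayscale; the hysteresis low threshold is 0.4 × the
  high one (the ratio is a package choice; only the high threshold is
  prescribed). Valid iff ≥ 1 edge pixel.
- **color** — object pixels are converted to HSV and counted per stain
  class; valid iff any class reaches 10 pixels. Counting is per class;
  the pooled count is also reported. Hue intervals may wrap the circle.

The default HSV table is re-derived from stain chemistry and calibrated to
the synthetic palette (hematoxylin hue 0.50–0.75; cytoplasm 0.45–0.75 at
low saturation; DAB 0.03–0.14; Fast Red wrapping 0.90–0.03). The
saturation floors (0.035) sit just above the achromatic level so that
dust — rendered exactly gray — and the faint chromatic halos of heavily
defocused cells both fail. All intervals are config-overridable: the
contribution is the rule's structure, not its constants, which must be
recalibrated per stain protocol.

## Sharpness scoring

Features per cell tile (64 px default, grayscale in [0, 1]):

| feature | definition | default constants |
|---|---|---|
| edge_count | Canny edge pixels | same constants as the validity filter |
| gradient_score | RMS Sobel gradient magnitude | — |
| diff_sharpened | mean abs. difference to unsharp-masked copy | radius 2, amount 1 |
| diff_blurred | mean abs. difference to Gaussian-blurred copy | σ = 2 |
| blur_metric | Crété-Roffet perceptual blur in [0, 1] | re-blur size 51 |

Two numerical choices deserve a note. The gradient score is the *RMS*
rather than the mean gradient: the mean |∇| is a total variation, which can
grow under blur as an object's edge ring widens, whereas the L2 norm of the
gradient decreases monotonically under Gaussian blur. The blur metric's
re-blur kernel (51) must exceed the largest blur scale to be resolved —
with the default 11 the metric saturates around σ ≈ 5 and loses ordering.
A constant tile has every feature 0 and blur_metric defined as 1.

The classifier is an SVC with Gaussian RBF kernel at scaling factor
σ = 1 in the K = exp(−‖x−y‖²/2σ²) convention (gamma = 0.5) on z-scored
features; standardization uses the training statistics and is stored with
the model, which serializes as a single versioned bundle embedding its
feature configuration (a model refuses to load against a mismatched one).
Training requires both classes; the balanced synthetic training set renders
the in-focus class at focal errors ≤ 2 µm (within a plausible depth of
field) and the out-of-focus class at 8–15 µm.

Scoring divides the scanned area into a 4 × 4 grid, detects cells per
region on an 8× downscaled overview (Otsu on luma; an object is a cell if
≥ 25 % of its pixels fall in a stain class — dust and debris fail), samples
up to 200, excludes huge clusters (> 4 Mpx) and very small cells (< 200 px,
reusing the nucleus constant, which the source procedure leaves
unquantified), classifies full-resolution tiles and records the percent
in-focus. Regions with no detected cells are excluded from the slide mean
and never trigger refocusing; a strict mode dividing by all 16 regions is
available for the literal reading of "divided by the total number of
regions". All region and slide scores live in [0, 100].

## Scan workflow

The loop bounds are: 12 initial points; "more than five" valid points
required (≥ 6, strict inequality per the flowchart); +12 points per failed
focus iteration capped at 85 (the largest point count observed in
practice); 5 focus iterations per attempt; 2 restarts after exhausted
attempts (the restart clause has no stated bound; two keeps total focus
iterations ≤ 15); 7 scan rounds; pass threshold 90. "Completely out of
focus" is operationalized as slide score < 30 with ≥ 12 failing regions —
the three slide states are named without numeric boundaries, so these are
package constants. Each focus iteration is judged on its own valid count,
matching the flowchart's per-iteration test.

The focus map is piecewise-linear over the Delaunay triangulation of the
valid points with nearest-point extrapolation outside the hull (exact at
the data points; one or two points degenerate to nearest-neighbor).
Partial refocusing places new points only inside failing regions
(intersected with the cell circle) and merges the new valid points into
the map before re-scanning.

The virtual scanner's autofocus is a deterministic contrast competition
over the probe strip's footprint: stained cells out-contrast translucent
dust, so the probe locks the cell surface whenever at least ~50 µm² (one
small nucleus) of cell material lies in the footprint, and otherwise
falls to the coverslip plane (dust specks or bare glass). This reproduces
the two-layer z scatter of real dusty slides while keeping capture
reproducible; measured z carries 0.25 µm Gaussian noise. An earlier
probabilistic capture model (dust wins with probability proportional to
local coverage) was replaced because it let rare dust locks coincide with
large in-frame cells, which no contrast-maximizing autofocus would do.

Repeat-scan reproducibility runs the whole workflow n times with
independent RNG substreams and reports the sample coefficient of
variation of the final scores.

## Z-profile analysis

Layer separation is a largest-gap bisection on sorted z with the gap
required to exceed 3× the pooled within-cluster standard deviation
(singleton clusters contribute no spread); below that guard the sample is
a single layer. The cluster nearer the objective is labeled dust. The
reference analysis separated layers by visual inspection, so the guard
factor is a package constant. Statistics use the sample (n−1) standard
deviation, with sd = 0 for a single point; `layers_needed` is
⌈range/spacing⌉ with a floor of one layer.

## What the synthetic experiments show — and what they don't

Passing the synthetic suite demonstrates that the *decision logic* is
correct under the stated optics: the filters implement their definitions,
the features order defocus correctly, the SVM separates classes that are
separable by construction, the workflow terminates within its bounds and
reacts to region failures, and dust-plane heights never reach the focus
map while the color filter is active. It does **not** demonstrate
real-world accuracy levels: synthetic classes are cleanly separated
(accuracies near 100 %), whereas the real-data evaluations that motivated
the design report 98.6 % for the focus filter and 94.8 % for the cell
classifier against human review — those figures are reproduced here only
as arithmetic on the published contingency tables, because the underlying
imagery was never deposited. Wall-clock scan times are hardware-bound and
not modeled. The simulator also omits optical aberration, vignetting,
sensor noise (beyond the optional Gaussian term), JPEG artifacts, and
out-of-plane cluster thickness.

Problem sizes in tests and the acceptance script are desk-scale choices:
1–1.9 mm slides with 120–1200 cells, 200-strip filter evaluations,
800+800-cell training runs, and 10-repeat Monte-Carlo estimates. Two
printed-value discrepancies in the published tables are documented rather
than reconciled: the focus-filter PPV prints 98.9 % while its counts give
1086/1097 = 99.0 %, and the cell-classifier specificity prints 95.9 %
while its counts give 859/889 = 96.6 %; the package always reports exact
quotients.

## Known limitations

- The Gaussian defocus model has no phase effects; features that exploit
  PSF structure cannot be studied with it.
- The 8-bit pipeline quantizes heavily defocused tiles to near-flat
  staircases; below that floor, orderings of curvature-based statistics
  (e.g. Laplacian variance) are noise, which is why the blur model caps σ.
- Region-level re-scanning is simulated by re-scoring the whole slide with
  the updated focus map; per-region imagery deltas are not tracked.
- The per-class vs pooled reading of the 10-pixel color rule is resolved
  as per-class (the stricter reading); the pooled count is exposed in the
  verdict for comparison.
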