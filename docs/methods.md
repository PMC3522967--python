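# Methods

This note records the models, conventions and numerical choices behind
`dielvision`, and what the synthetic validation does and does not show
about real chamber imagery.

## Capture model

An experiment is a photoperiod program: start/end datetimes, day and
night lengths summing to 24 h (default 16 h/8 h), and an acquisition
rate in images per hour (default 6, i.e. one frame per 10 min). The
total image count is `days × images_per_hour × 24`; a fractional day
span is counted on hours. Phase is anchored with **lights-on (dawn) at
the start time**, an arbitrary but fixed convention; period intervals
are half-open, so an instant exactly on a boundary belongs to the period
that begins there. Period labels inside `build_schedule` are derived
from the capture index, not the stored timestamp, because `timedelta`
quantizes to microseconds and would otherwise mislabel boundary
instants. The first instant of each period carries a transition marker
(`T_nd` night→day, `T_dn` day→night); the marker at index 0 denotes the
nominal dawn opening the experiment and has no preceding period, so the
correction stage ignores it. Night-flash and pre-switch durations are
carried in the plan for provenance but do not shift capture instants —
they model illumination hardware timing outside this package's scope.

## Segmentation

Preprocessing supports up to four smoothing/morphology operations
(average, median, Laplacian, sharpen, custom odd-sized mask; grayscale
dilation/erosion/opening/closing), each with its own kernel size and
iteration count, executed in configured order via `scipy.ndimage`.
Roberts/Sobel edge detection is available as extra preprocessing for
organs with intricate outlines, but segmentation always proceeds by
thresholding — edge maps are never used as the mask. The default chain
is median 3×3 + opening, a conservative choice for high-contrast chamber
frames.

The three global thresholds are computed from the 256-bin histogram:

* **Otsu** maximizes between-class variance ω₀ω₁(μ₀−μ₁)²;
* **Kapur** maximizes the sum of the two classes' Shannon entropies;
* **Kittler–Illingworth** minimizes the minimum-error criterion
  1 + 2(ω₀ln σ₀ + ω₁ln σ₁) − 2(ω₀ln ω₀ + ω₁ln ω₁).

Foreground is `pixel > level` (organ brighter than background, matching
IR night imaging; a config flag inverts polarity). Determinism demands a
tie rule: the **lowest level attaining the optimum**, with a 1e-9
relative tolerance so algebraically tied levels whose criterion values
differ only in floating-point noise cannot flip the choice. Kittler's
class variances are floored at **1/12** — the quantization variance of a
single gray level — which keeps the criterion defined for
delta-distributed classes (e.g. clean two-level synthetic frames);
candidate levels with an empty class are skipped in all three methods.
The same floor and tie rule are applied by the brute-force criterion
scans the tests use as oracles.

Blobs are 8-connected components (standard for foreground analysis),
labelled in raster order of first pixel, each measured in full and then
filtered by optional min/max bounds on area, compactness, length and
perimeter. Coordinates are 0-based with origin at the top-left pixel
center, x rightward, y downward; bounding rectangles are reported
inclusive. Blob masks are stored cropped to their bounding box purely
for speed — features are reported in frame coordinates.

## Shape features

* **Area** — pixel count (× scale² when calibrated).
* **Perimeter** — the 4-direction Crofton estimator
  (`skimage.measure.perimeter_crofton`). This choice is load-bearing:
  compactness must be ≈1 for discs, and the naive 8-connected chain-code
  boundary length inflates a rasterized disc's compactness to ~1.6,
  while Crofton-4 gives ~1.01 (bias shrinking with radius). The residual
  ~1% disc bias is asserted in the tests.
* **Angle** — principal-axis orientation from second central moments,
  counterclockwise from the horizontal image axis in [0°, 180°); the
  moment computation flips y so "counterclockwise" matches the
  on-screen geometry. Isotropic masks (e.g. squares) have no defined
  axis; they report 0° with a degeneracy flag.
* **Length** — full extent of the pixel-center projections onto the
  principal axis, +1 px for the pixel footprint. The organ-length usage
  this matches is a flower's limb-to-tube extent; skeleton or curved
  lengths are out of scope.
* **Compactness** — C = p²/(4πA), computed from the estimators above.
* **Motion vector** — Euclidean distance of each centroid from the
  *first-frame* centroid (fixed origin, per the definition); missing
  frames propagate NaN.
* **Growth velocity** — forward difference of the measured series over
  the capture interval. The defining relation is stated ambiguously in
  the field ("distance between two measures" vs a length series); the
  forward difference `(l_{j+1} − l_j)/Δt` is implemented, which makes
  `Σ v_jΔt` telescope exactly to the total change.

## Adaptive ROI

Table-style vertex expressions for the adaptive ROI reduce to a
symmetric outward expansion of the blob's circumscribed rectangle by
MGX horizontally and MGY vertically, clamped to the image. (The
per-vertex formulation in the source material contains sign
inconsistencies; the symmetric expansion is the evident intent.) Margins
default to 20 px and should be set to at least the maximum expected
per-frame growth + displacement per axis — three times that maximum is a
comfortable safety factor. Containment then holds by induction: if the
blob moved/grew by ≤ (MGX, MGY) since the previous frame, it is still
inside the previous ROI.

Blob identity across frames is **largest area**, with nearest-centroid
tie-breaking when candidates are within 10% of the largest; the pipeline
tracks one user-selected organ, so no general matching is attempted. An
empty ROI triggers one recovery pass — re-segment the full frame and
adopt the blob nearest the last known centroid (an organ can slip out of
a clamped ROI at the image edge) — and a frame where that also fails is
recorded as missing, never interpolated. The ROI follows the rectangle
both ways, shrinking with a senescing organ.

## Illumination-transition correction

Dual day/night illumination changes the gray statistics abruptly at
every transition, and every pixel-counting variable (area, length,
centroid, perimeter) inherits a step. With n night samples, d day
samples, K1 = V_{n+1} − V_n the observed night→day jump and K2 the mean
successive difference within the night period (K3/K4 the day→night
analogues), the corrected series offsets all post-transition samples by
**−K1 + K2** (resp. −K3 + K4), offsets accumulating across transitions
in time order. Taken at face value, the source formulas add K1 + K2,
which would *enlarge* the discontinuity they demonstrably remove; the
implemented sign convention is the one that reproduces the documented
continuous output, and is flagged here as an interpretation. Correction
is forward-only (no retroactive adjustment of pre-transition samples)
and requires every period to hold at least 2 samples so its mean step
exists.

Numerics: each cumulative offset is quantized to the ulp grid of the
series' top binade before being applied. Adding an arbitrary double
offset breaks bit-level equality of successive differences in roughly
three quarters of cases; with the quantized offset, integer-valued
pixel-count series keep their within-period successive differences
**bit-for-bit**, as do fractional series (centroids) that stay within
one floating-point binade. The quantization error is below one part in
10¹² of the data magnitude.

## Rhythm read-outs

**Accumulated growth** sums positive increments only, anchored at 0, so
measurement dips from an organ turning toward the camera never reduce
accumulated totals. **Binary growth patterns** cut the accumulated area
and length series into fixed intervals — default 48 samples = 8 h at 6
images/hour, three cells per day — and flag an interval 1 iff the series
grows by more than 1% of its total range (the epsilon guards against
noise-driven false positives; the flags are invariant to constant
shifts). Intervals with length growth but no area growth count as
proximo-distal vs lateral **decoupling events**. Formal rhythmicity
statistics (periodograms, cosinor) are deliberately not included; the
corrected and accumulated series are exported for external analysis.

**Organ ranking** scores candidate tracks by visibility (fraction of
frames with a valid measurement; threshold 0.8), occlusion (maximum
fractional bounding-box overlap with any other organ in any frame;
threshold 0.5) and activity (variance of the motion vector); survivors
are ranked most-active-first, the preference for nutation studies.

## Calibration

The target is a 10 × 10 grid of 5 mm-radius circles. Its stated circle
"separation" of 10 mm is read as the **edge-to-edge gap**, giving a
20 mm center pitch — a 10 mm center pitch would make 5 mm circles touch,
which no printable target does and blob detection could not resolve.
Center detection reuses the segmentation chain (Otsu with automatic
polarity — the minority Otsu class is taken as the circles — plus
compactness < 1.3 and area-consistency filters); centers are
intensity-weighted centroids, ordered row-major by y-clustering then x.
Per plane, scale_x is the pitch divided by the mean horizontal neighbour
spacing (scale_y down columns; anisotropy is allowed since CCIR video
pixels need not be square), and the residual is the RMS deviation from
the ideal grid after a least-squares similarity fit, in mm. Queries at
an arbitrary sample distance interpolate linearly between bracketing
planes; extrapolation outside the calibrated range is refused. No lens
distortion model is fitted, and only a scale per plane is stored (not a
homography) — the source system records nothing richer.

## Synthetic chamber

The generator renders a single organ — ellipse or superellipse
(exponent 4 by default, cladode-like) — by an analytic
point-in-boundary test at pixel centers with **no anti-aliasing**, so
the ground-truth pixel area is the exact foreground count; the analytic
(continuous) area is recorded alongside, and for grid-aligned
superellipses the two can differ by several percent because flat sides
graze whole pixel rows. Semiaxes grow linearly with independent x/y
rates (so length and area growth can decouple); nutation is a sinusoidal
vertical centroid displacement `A·cos(2πt/P)` (starting at the crest, so
peak displacement from the first-frame origin is 2A); an optional dawn
pulse applies a step offset in position/angle during the first frames of
each day period, emulating the post-dawn movement burst real flowers
show. Day and night frames draw separate fore/background gray levels
(defaults 200/40 day, 140/15 night, ≥20 gray-level contrast enforced);
Gaussian noise is added and clipped to [0,255]; all randomness flows
through the seed and frame index, making runs bitwise reproducible.

A pure gray-level shift cannot perturb pixel counts in a noise-free
binary rendering, so the measurement discontinuity real dual-camera
systems show is emulated explicitly: `apparent_size_jump_px` dilates the
*rendered* organ boundary in night frames (default 0) while ground truth
stays the undilated organ. This is the knob the transition-correction
validation turns.

What the simulator does **not** emulate: photometric gradients, shadows
and occlusion, organ deformation beyond affine growth+rotation, leaf
texture, defocus, or multi-organ scenes beyond static distractor discs.
Passing tests therefore demonstrate the algorithmic contracts
(containment, recovery, correction continuity, parameter recovery), not
segmentation robustness on real plants.

## Validation problem sizes

The end-to-end suites use frame sizes of 200–320 px and sequences of
24–1008 frames: the transition-correction check runs the full 7-day,
6 images/hour program (1,008 frames); adaptive-ROI containment uses 100
frames; growth recovery one day at 6/hour, noise-free and at gray-noise
sd 5. The organ is placed so its centroid-Y series stays within one
floating-point binade, which is what lets the bit-for-bit invariant
hold for fractional series (see above). The simulator's default frame
is 768 × 576, the CCIR camera resolution.
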