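# Methods

This note documents the models, algorithms and numerical choices in
`actimage`, which recognizes martial-arts unit actions (blocks,
punches, strikes, kicks) from full-body inertial motion capture by
encoding each action as an RGB image and classifying the images with a
small convolutional network.

## Data model

A **motion profile** is a uniformly sampled tensor `(T, J, 6, 3)`: per
frame and joint, six data types — position (m), velocity (m/s),
acceleration (m/s²), orientation (rad, as a rotation vector), angular
velocity (rad/s), angular acceleration (rad/s²) — each a 3-vector.
The default joint set has 23 named full-body segments sampled at
240 Hz, matching commercial IMU motion-capture suits.  Frame indices
are 0-based and segment intervals half-open; the final sample time is
`t_f = (T − 1)/f_s`.  The CSV interchange format stores one column per
`{joint}.{dtype}.{axis}`; the JSON sidecar's sample rate is
authoritative and the time column is derived from it, which avoids
float-drift disputes on read.

## Representative velocity and segmentation

The **representative velocity** at frame `t` is the arithmetic mean of
the speed magnitudes of the four end-effectors,

    V_rep(t) = ¼ (|v_lh| + |v_rh| + |v_lf| + |v_rf|),

the joints whose speeds best reflect strike and kick dynamics.  A
recording session — twelve repetitions of one action separated by
rest — is segmented by thresholding a smoothed V_rep:

1. centered moving average over `smoothing_window` (default 0.25 s);
2. mark frames above `threshold_fraction` (default 0.10) of the
   smoothed peak — a *relative* threshold, so segmentation is
   invariant to subject amplitude and unit rescaling;
3. merge above-threshold runs separated by less than `min_gap`
   (default 0.2 s), a single-threshold stand-in for hysteresis that
   bridges the momentary velocity dips at movement reversals;
4. drop runs shorter than `min_duration` (default 0.3 s);
5. pad each run by `padding` (default 0.1 s) and clip/merge.

Defaults were chosen so that a rectangular velocity burst is recovered
exactly up to smoothing blur, and all are exposed in
`SegmenterParams`.  A motionless session returns an empty list rather
than an error.

## Time warping

Let `s(t)` be the normalized cumulative representative velocity over a
segment, `s(t) = ∫₀ᵗ V_rep dτ / ∫₀^{t_f} V_rep dτ`.  Two
reparameterizations are implemented:

- **expand_fast** (default): output rows are uniform in `s`; row `i`
  samples the input at `s⁻¹(i/(n_rows−1))`.  Intervals of rapid
  motion, which accumulate velocity quickly, receive proportionally
  more output rows — the slow-motion effect that magnifies strike
  dynamics in the image.
- **literal_eq7**: row `i` samples at `s(t_i)·t_f` on a uniform output
  grid — the direct composition `p(t_warp)`.  This is the algebraic
  inverse of the above and *compresses* fast intervals; it is kept
  behind a flag because the formulation is ambiguous between the two
  readings, and only expand_fast produces the expanded bright region
  the method is designed around.

Quadrature is trapezoidal by default with a left-Riemann option
matching a plain accumulation loop.  All channels are resampled with a
natural cubic spline; query times are clamped to `[0, t_f]`.  A
zero-motion segment warps to the identity.  The map is made strictly
monotone across zero-velocity plateaus by blending in a linear ramp
with weight 1e-9, which perturbs source times by at most ~1e-9·t_f.

## Action images

An image has `n_rows` time rows and `6·J` columns (per joint: the six
data types in fixed order); the x/y/z components map to R/G/B.
Columns are min-max normalized **per axis** over the segment
(`per_axis`, default), so every non-constant column attains 0 and 1
and the mapping is invariant to positive affine rescaling of any
channel.  The alternative `shared_x_denominator` rule divides all
three channels by the x-axis range without subtracting the minimum
(clipped to [0, 1]); it reproduces a published formulation verbatim
but does not generally fill [0, 1], so it is non-default.  Constant
columns render as `constant_fill` (default 0 — dark means "no
information").  A `global` normalization scope (pooled extents via
`combine_extents`) is available for cross-segment comparability.

Because velocity channels are signed, zero velocity normalizes to
mid-range and large speeds of either sign map to the pixel extremes;
the "bright region" diagnostics (`velocity_brightness`,
`bright_row_count`) therefore measure extremeness `2|pixel − ½|` over
the non-constant velocity channels — the pixel-level proxy for motion
magnitude.

## Classification network

Four convolution blocks (5×5, 3×3, 3×3, 3×3 kernels; 16, 32, 64, 128
channels; stride 1, valid padding, bias; ReLU; 2×2 max pool stride 2)
followed by flatten → dense(128) → ReLU → dense(n_classes) → softmax.
The engine is implemented directly in NumPy (im2col convolutions,
seeded He-normal initialization, Adam, softmax cross-entropy) so that
training is deterministic and bit-reproducible given a seed on CPU.
Analytic parameter counts (`k_h·k_w·c_in·c_out + c_out` per
convolution, `n_in·n_out + n_out` per dense layer) are exposed and
tested against exhaustive enumeration of the instantiated tensors;
for the published geometry the middle layers count 4640, 18 496,
73 856 and 819 328 parameters.

Training modes: stratified 5-fold cross-validation (default; one
model per fold, pooled out-of-fold predictions) or a stratified 70/30
holdout.  Folds derive from a seeded shuffle, so two runs with the
same labels and seed use identical folds — the property the paired
experiment harnesses rely on.

## Metrics

Per-class TP/TN/FP/FN are one-vs-rest counts from the confusion
matrix; accuracy = (TP+TN)/N per class, which is why per-class
accuracies near 0.99 can coexist with much lower precision/recall.
Macro values are unweighted class means (class sizes are near-equal
under the protocol, so micro/macro differences are negligible).
Zero-denominator cases yield 0 with a warning.

## Synthetic data generator

The generator emulates the collection protocol — 40 subjects × 16
actions × 12 repetitions, 23 joints at 240 Hz, ~1 s rest between
repetitions (7680 labeled segments at defaults) — so every stage is
testable without access to recorded human data.

Each action template specifies, per involved joint, keyframes on a
normalized phase axis: rest → chamber → strike target (→ re-chamber
for kicks) → rest, with a designated *fast interval* covering the
strike.  Positions follow piecewise minimum-jerk interpolation
(quintic blend `10τ³ − 15τ⁴ + 6τ⁵`, zero velocity/acceleration at
keyframes), the standard smooth human-movement primitive; velocity and
acceleration channels are its exact analytic derivatives, with each
repetition's duration snapped to the sampling grid so the channels are
consistent with the frame spacing.  Angular channels use a secondary
rotation-vector keyframe set through the same machinery.  Subject
identity enters as amplitude and timing scale factors drawn once per
subject (fractional sd `subject_variability`, default 0.05);
repetitions add small amplitude jitter and ~1.5 cm keyframe jitter.
A6 (body punch) and A8 (face punch) are deliberate near-duplicates
differing only in the hand target height.  A separate
`fast_contrast_templates` set makes the strike direction — visited
only during a short fast interval — the sole class difference, to
probe the benefit of warping in isolation.

Noise injection adds zero-mean Gaussian noise per channel with
standard deviation `(pct/100)` × that channel's RMS over the profile
(RMS rather than the mean, which is near zero for signed channels; a
range-based scale is available for comparability studies).  Noise is
injected into motion profiles *before* warping and rendering, so the
velocity-derived warp map is perturbed too.

What the generator does **not** emulate: skeletal constraints (joints
move independently along straight minimum-jerk paths), coordinated
whole-body motion (uninvolved joints hold the standing pose),
biomechanically realistic speeds (amplitudes are deliberately moderate
so that discrete-derivative checks at 240 Hz remain
truncation-dominated), sensor drift, or soft-tissue artifacts.
Passing tests therefore demonstrate correctness of the pipeline and
the qualitative behavior of warping under controlled conditions, not
performance on recorded human Taekwondo data.

## Problem sizes and tunables used in tests and scripts

The reduced end-to-end benchmark is 5 subjects × 16 actions × 3
repetitions (240 segments), rendered at 64 rows over the 8-joint
subset (48 columns — the smallest width at which the fourth
convolution block still sees a 3×3 input), trained with Adam at
learning rate 2e-3, batch 16, 15 epochs, 5-fold CV (convergence
plateaus there; longer training begins to overfit the small folds).  The warp
comparison uses 4 fast-contrast classes × 4 subjects × 3 repetitions
with a 70/30 holdout; the noise study uses 8 actions × 3 subjects × 3
repetitions at 0/1/3 % noise under 5-fold CV.  Full-protocol
cardinality checks stream sessions one at a time (a materialized
640-session dataset would need >10 GB).  The joint subsets are
end-effector-centric: `reduced_4` = hands + feet, `reduced_8` adds
forearms and lower legs — the representative velocity already
privileges exactly these joints.

## Known limitations

- The CNN engine is CPU-only and sized for small images; it is not a
  general deep-learning framework.
- Segmentation is offline (whole-session); streaming segmentation is
  out of scope.
- Orientation is a rotation vector, adequate for the synthetic
  templates but not a general attitude representation (no unwrapping
  across ±π).
- The generator's class separability is optimistic relative to human
  data; absolute metric values on synthetic benchmarks should not be
  compared with results on recorded datasets.
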