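# Methods

This note documents the models and procedures implemented in `skitech`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Sensor model and conventions

Two 20 Hz streams are assumed: a 3-axis gyroscope on one arm (deg/s) and
a 3-axis accelerometer on the chest (m/s²; raw, gravity-inclusive — no
gravity subtraction is attempted, so baseline offsets encode posture).
With the chest sensor upright, x is perpendicular to the transverse
plane, y to the sagittal plane and z to the coronal plane.  Readers
convert declared units (`g`, `rad/s`) to these canonical units.

Streams are stored on the uniform nominal-rate grid.  Input gaps wider
than twice the nominal interval become NaN rows tracked as half-open
index spans; this keeps cycles, dropouts and features in a single sample
coordinate system.  Any cycle overlapping a missing span of either sensor
is excluded (EXC) rather than classified.

## Arm-axis calibration

Mounting misalignment of the arm sensor is compensated by a
principal-axes transform: the eigen-decomposition of the zero-meaned
angular-rate covariance defines the calibrated frame, with the dominant
eigenvector as the y-axis (arm-swing axis), the second as x and the least
as z, with signs adjusted so the matrix is a proper rotation.
Eigenvectors have arbitrary sign, so the y direction is disambiguated by
requiring the dominant peaks of the heavily filtered y signal to be
positive (arm extended behind the skier); the skewness of the filtered
projection decides, falling back to comparing the magnitudes of its
extrema, and keeping the raw sign on an exact tie.  If the dominant axis
carries less than 50% of the total variance the motion is too isotropic
to orient: a warning is emitted and the identity rotation used.
Calibration operates on the raw (unfiltered) signal; filtering follows.
The chest sensor is never calibrated — its mounting is assumed robust.

## Gaussian filtering

Both filters are zero-phase Gaussian convolutions specified by their
time-domain standard deviation: 0.25 s (5 samples) ahead of cycle
detection, 0.0875 s (1.75 samples) ahead of feature extraction.  The
kernel is truncated at 4σ and boundaries are handled by reflection
padding, which avoids the edge transients that constant padding would
turn into spurious peaks.  A series shorter than the kernel support is
rejected.  NaN samples are linearly interpolated before filtering so they
do not propagate; cycles over such spans are excluded anyway.  The
filter's continuous-domain gain at frequency f is
`exp(-(2π f σ)² / 2)`, which the tests verify on impulse and sinusoid
inputs.

## Cycle detection

Cycles are delimited by local maxima of the filtered arm-gyro y signal.
The peak criteria are implementation choices (no thresholds are inherent
to the definition): prominence at least 0.25 × the 90th percentile of
|signal − median(signal)| — median-centered so that detection is
invariant to constant offsets — and minimum peak separation 0.5 s, since
no skiing cycle is shorter than that.  Complete cycles tile the
peak-to-peak region exactly; the leading and trailing partial segments
are kept but flagged and not classified.  No maximum duration is imposed:
long cycles across arm-quiet spans (tuck, some turns) are legitimate and
duration is a classification feature.

## Feature vector (94 elements)

Per cycle, each chest axis segment is resampled to 30 points by linear
interpolation over 30 equally spaced positions on `[start, end−1]` in
sample coordinates ("decimation" of long cycles is the same
interpolation); endpoints are preserved exactly, and a 30-sample cycle
reproduces itself.  Elements 1–90 are the concatenated x, y, z blocks;
element 91 is the original cycle length in samples; elements 92–94 are
the per-axis normalized sums, implemented as the segment sum divided by
the cycle length (the per-axis mean) — the normalization basis was an
open choice, and dividing by length removes a duration dependence that
element 91 already carries.  Feature standardization (z-scoring with
training-set statistics) deliberately lives inside the classifier, not
here, keeping stored feature files raw.

Mirror augmentation negates the y block and the normalized y sum (the y
mean flips with the signal, so it is negated for consistency), keeping
label and everything else; it is an involution and doubles the training
set.

## Classifier

Architecture `94 → 50 → 10 → 20 → 8`, tanh hidden activations, softmax
output, cross-entropy loss.  Training uses scikit-learn's MLPClassifier
with the deterministic L-BFGS solver and L2 weight decay; the
Bayesian-regularization training scheme of the original MATLAB toolbox is
approximated by that decay, with the strength chosen on the validation
set from the grid {1e−4, 1e−3, 1e−2}.  Rather than multiplying the fit
count by the grid size, restart r uses `alpha_grid[r % 3]`; the default
20 restarts therefore also sweep the grid, and the selected model is the
restart maximizing validation accuracy (ties: lower validation
cross-entropy, then lower restart index — all restart records are kept so
selection optimality is assertable).  Input features are z-scored with
training-set statistics stored in the model; binary problems are
converted to an equivalent two-output softmax layer so the in-package
forward pass is uniform.  With fixed seeds the procedure is reproducible
bit-for-bit at the model-file level (versioned JSON with explicit class
ordering, weights and normalization constants).

Class imbalance is not reweighted, matching plain training; prediction
ties break by the canonical class order DIA, DK, DP, TCK, HRB, TRN,
tDIA, fDIA.

## Evaluation

Confusion matrices store labeled classes in columns and classified
classes in rows.  Sensitivity is `100·TP/(TP+FN)` over a class's column,
precision `100·TP/(TP+FP)` over its row, accuracy `100·trace/total`;
margins with zero support are reported as not applicable rather than 0.
EXC cycles never enter the matrix — they are tallied separately before
accuracy is computed.  Percentages render to one decimal; underlying
values keep full precision.  A post-hoc class-merging helper (e.g.
pooling DIA, tDIA, fDIA and HRB into one diagonal-family class) supports
coarser analyses.

## Synthetic sessions

The generator emulates the qualitative per-class signatures at 20 Hz:

| class | arm gyro | chest accelerometer |
|-------|----------|---------------------|
| DIA   | swing pulses, 1.4 s cycles | 2 kick spikes/cycle on x |
| DK    | swing pulses, 1.5 s | 1 kick + sagittal z oscillation |
| DP    | swing pulses, 1.2 s | no kicks, strong z oscillation |
| TCK   | flat interior, ~5 s cycles | flat, crouched baseline |
| HRB   | swing pulses, 1.3 s | kicks + strong lateral y oscillation |
| TRN   | weaker pulses, irregular | sustained lateral (centripetal) y offset |
| tDIA  | swing pulses | 3 kicks + rising z edge |
| fDIA  | swing pulses | 3 kicks + falling z edge |

The arm-gyro y signal is a positive Gaussian pulse at *every* cycle
boundary (arm extended behind) and a shallower pole-plant trough
mid-cycle; peaks are deliberately taller than troughs, as in real
arm-swing recordings, which is what makes the calibration sign rule
reliable.  Entering or leaving a tuck involves an arm swing, so tuck
spans are delimited by boundary pulses while their interiors stay flat.
A 1 s lead-in/lead-out pad makes the first and last ground-truth
boundaries interior peaks.  Noise is additive i.i.d. Gaussian per axis
with standard deviation `noise × per-axis template amplitude`
(default noise = 0.1); an optional mounting rotation of the arm sensor
exercises calibration.  The optional 1 Hz GNSS track integrates per-class
speeds and climb rates (fast descending tuck, slow climbing
diagonal/herringbone, heading wiggles in turns) with a first-order
heart-rate response.

All template amplitudes are implementation constants chosen once so the
classes are separable in the 94-feature space at the default noise level
(between-class centroid distance > 3× within-class spread); they are
**not** calibrated against recorded data, whose absolute amplitude scales
are unknown.

## Benchmark sizes and runtime

The default benchmark trains on 200 ground-truth cycles per class
(mirror-augmented to 3 200 vectors), validates on 50 per class from an
independent session and tests on 50 per class from a third session with
a 10° arm-mounting misalignment, scored through the full detection
pipeline with detected cycles matched to ground truth by midpoint
containment.  These sizes give stable near-ceiling accuracies while the
whole benchmark (20 restarts) completes in a few seconds on one CPU.

## What passing tests show — and what they do not

The synthetic benchmark demonstrates that the pipeline is internally
consistent: boundaries are recovered to ±2 samples under noise,
calibration undoes known mounting rotations to well under 1°, features
separate the constructed classes, and training/selection behave
deterministically and optimally.  It does **not** demonstrate field
accuracy on real skiing data: real cycles vary biomechanically within a
class, labels carry expert disagreement (the diagonal-vs-herringbone
boundary is a grey area), transition and herringbone cycles are rare, and
athletes produce movements outside every predefined class.  Reported
field accuracies for this kind of two-sensor pipeline are in the low-to-
mid 90s percent, with the rare classes substantially weaker — perfect
synthetic scores should be read as a correctness check, not a performance
claim.

Other known limitations: no magnetometer fusion or orientation tracking;
a single constant clock offset (no drift) between IMU and GNSS; linear
interpolation as the only resampling scheme; no probability calibration;
tuck spans are only delimited when an arm swing marks their edges.
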