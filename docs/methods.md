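# Methods

`nursehar` implements a complete recognition pipeline for complex,
care-type activities from a single tri-axial accelerometer: data
ingestion and cleaning, label-preserving augmentation with class
balancing, two-step statistical feature extraction, feature selection, a
multi-branch 1-D CNN fused with a random forest, and leave-one-subject-out
evaluation. This note records the model choices, parameter meanings and
defaults, the synthetic study conditions, and known limitations.

## Data model and ingestion

The unit of classification is the *segment*: one contiguous window of
(ax, ay, az) samples carrying exactly one activity label and one user
label. Two CSV dialects are supported. The segment-keyed dialect joins
sensor rows to labels on an integer segment id; the timestamp-keyed
dialect assigns a sample at time *t* to a label interval when
`start_time <= t <= finish_time` (closed on both ends, so boundary
samples belong to the interval). All timestamps are normalized to float
seconds before sorting, and sorting is stable so equal keys keep their
file order. Missing acceleration values are imputed by per-column means;
when a train/test split exists, the training means are applied to the
test side so no test statistic leaks into a fitted quantity. Samples
covered by no label are dropped and counted, never imputed with a null
class. Overlapping label intervals are an error by default, with an
opt-in first-wins policy, since the data contract does not define an
owner for doubly claimed samples.

Long segments are sliced into fixed windows (default 60 samples, stride
60, i.e. 1 s at 60 Hz without overlap); shorter segments are kept whole
and flagged, or dropped on request. Windowing happens before
augmentation, so augmented copies are already model-sized; augmentation
always precedes filtering.

## Augmentation operators

Five label-preserving operators act on a segment's `(n, 3)` sample
matrix. None of them changes the segment length or labels.

- **Jitter** adds i.i.d. Gaussian noise `N(mu, sigma)` per cell.
  Default `sigma = 0.03 x` the signal's standard deviation.
- **Scaling** multiplies each cell by an independent draw from
  `N(1, 0.1)` — multiplicative sensor noise.
- **Magnitude warping** multiplies all three axes elementwise by one
  shared random curve varying around one.
- **Time warping** resamples each axis along a warped time base: the
  shared random curve is cumulatively averaged, rescaled to span the
  original index range `[0, m-1]`, and the signal is linearly
  interpolated back onto the integer grid. A curve whose cumulative sum
  is not strictly increasing is redrawn (cap 10); a constant curve
  yields an affine warp, i.e. the identity.
- **Rotation** right-multiplies every sample row-vector by an axis-angle
  rotation matrix with axis drawn by normalizing a uniform `[-1,1]^3`
  vector and angle uniform in `[-pi, pi]`. The matrix is orthogonal, so
  the per-sample vector magnitude is preserved to machine precision —
  magnitude-derived features are rotation-invariant by construction.

Random curves are natural cubic splines through `phi + 2` knots drawn
from `N(mu, sigma)` at equally spaced positions over the segment's index
range. Defaults: `phi = 4`, knots `N(1, 0.2)` for both warps. One curve
is shared across the three axes of a segment so inter-axis geometry is
preserved. These parameter values follow common practice in wearable
time-series augmentation; all are configurable.

**Class balancing** groups segments by class and cycles each group's
originals through the configured operator chain (a pair such as MW+TW
composes left to right) until every class holds exactly `A` segments;
originals are kept unmodified and augmented copies carry their operator
name as provenance. The pipeline default sets `A` to 3x the majority
class count of the training fold, the enlargement factor that works best
in our reference workflow; balancing to the majority (factor 1) is a
config change. Each augmented segment gets its own counter-keyed RNG
substream, so the output is reproducible regardless of processing order.

## Filtering and the intermediate feature set (IFS)

Each axis is denoised by a running median (window 5, edges shrink) and a
zero-phase order-3 low-pass Butterworth at 20 Hz — the band of human
motion. Zero-phase (forward-backward) application avoids phase
distortion at the cost of squaring the magnitude response. When the
cutoff reaches Nyquist (e.g. 4 Hz data) the Butterworth stage is
mathematically void and is skipped with a warning rather than silently
misconfigured.

The 13 per-sample IFS columns are: the three filtered axes; the vector
magnitude `sqrt(ax^2+ay^2+az^2)` (orientation-free); per-axis velocity
and displacement by first- and second-order cumulative trapezoidal
integration (`dt = 1/fs`, initial value 0); and per-axis orientation
angles `theta_a = arctan(a / sqrt(b^2 + c^2))`, computed via `arctan2`
so a zero denominator gives ±pi/2 and the all-zero sample maps to 0.
Angles capture wearing tilt without needing a gyroscope or a gravity
estimate.

## Final feature set (FFS) and MSUM

Each IFS column is reduced to 9 statistics — sd, average, max, min,
variance, median absolute deviation, MSUM, energy, interquartile
range — for 13 x 9 = 117 named features per segment. Conventions: sd and
variance use the population (`ddof = 0`) definition so `var = sd^2`
exactly; energy is the *mean* of squared values so it is
length-invariant; `mad = median(|x - median(x)|)`; IQR uses
linear-interpolation quantiles. A constant column yields well-defined
zeros, never an error.

**MSUM** summarizes oscillation structure beyond max/min/mean: locate
all strict interior relative extrema (a flat plateau counts once, at its
first index), pair every relative maximum with its *second* successive
relative minimum and every minimum with its second successive maximum,
and average the absolute value gaps over all pairs; extrema lacking a
second successor are skipped and an extremum-free series scores 0.
Because extrema strictly alternate, the partner of the i-th extremum is
the (i+3)-th; every extremum is paired independently (the pairing does
not restart after a match). The "distance" is the vertical gap of signal
values, not a Euclidean (time, value) distance, matching the definition
by endpoint subtraction. Pair gaps are accumulated with correctly
rounded summation (`fsum`), so the value is independent of enumeration
order and can be compared exactly against a brute-force oracle.

## Feature selection

Three stages, all fit on training folds only: (1) Pearson pruning —
scan upper-triangle pairs in canonical column order and drop the later
column of any surviving pair with `|r| > 0.9` (the threshold is
configurable; the scan is greedy, so it is deterministic and
idempotent); zero-variance columns have undefined correlation and are
retained but flagged. (2) Rank survivors by random-forest mean decrease
in impurity, after sorting rows into a canonical order so the ranking
does not depend on how the table was assembled. (3) Evaluate accuracy
with the top-k features over a grid (every k to 60, then strides of 5)
and keep the smallest k strictly above `max(curve) - epsilon`
(`epsilon = 0.005` default); if no k clears the strict bound — e.g. a
strictly increasing curve with `epsilon = 0` — the full set is kept. The
strict inequality makes a curve that merely touches the plateau from
below keep growing until it clears it.

## Stacked CNN

Each input channel — by default the three filtered acceleration axes and
the three angle channels — enters its own sub-model:
`conv(32 filters, kernel 16) -> batch-norm -> ReLU -> maxpool(2)` then
`conv(16, 16) -> batch-norm -> ReLU -> maxpool(2)`. Flattened sub-model
outputs are concatenated, passed through dropout `p = 0.25` and a dense
softmax. Separate pathways stop dissimilar channels (linear acceleration
vs. tilt angle) from being mixed by the first convolution, which is the
point of the architecture; a two-branch mode (one acceleration branch,
one angle branch) is available as the alternative reading. The block
order conv -> norm -> activation -> pool is the common modern layout.

Training: Adam at learning rate 0.001, batch size 32, categorical
cross-entropy, at most 500 epochs, early stopping when validation
accuracy has not improved for 100 epochs, best-validation weights
restored. The evaluation protocol defines no inner split, so a
stratified 20% of the training segments is carved per fold, seeded. The
network is implemented directly in NumPy (the analytic gradients are
verified against numerical differentiation in the test suite), runs
single-threaded, and is exactly reproducible: initialization, shuffling,
dropout masks and the validation split all flow from one seeded
generator. With 60-sample inputs the two conv/pool stacks need at least
49 samples; shorter model inputs raise a shape error stating the
minimum. Variable-length segments are truncated or edge-padded to the
model length for the CNN path only — the forest consumes the
length-invariant FFS.

The random forest (500 trees, default depth, seeded) consumes the 117
statistical features; its hyperparameters are configurable since the
reference workflow does not pin them.

## Fusion and evaluation

Class probabilities are fused as `S(y) = sum_i beta_i P_i(y)` with
`beta = 2` for the CNN and `1` for the forest; the argmax of S is the
prediction, ties breaking to the lowest class index. The betas are not
normalized — argmax is scale-invariant. Metrics are accuracy and
macro-averaged precision/recall/F1 (reported in percent), plus a
confusion matrix with true classes as rows.

Evaluation is leave-one-subject-out cross-validation (LOSOCV): one fold
per user; augmentation, imputation statistics, feature selection and
model fitting are fitted on the training users only, and augmentation is
never applied to held-out data. Fold metrics are averaged and confusion
matrices summed. Every fold records which segment ids fed each fitted
statistic, and `assert_no_leakage` verifies the held-out user's segments
(and anything augmented from them) appear in no pool — leakage is
asserted absent, not assumed.

## Synthetic study conditions

The generator emulates the structure of wearable nurse-care recordings
without reproducing any real recording. Each (activity, user) pair has a
motif: a two-harmonic sinusoid mixture whose base frequency
(0.8 + 0.7a Hz for activity index a) and per-axis amplitudes (uniform
0.3–0.9, harmonics 0.1–0.4) depend only on the activity, superposed on a
unit gravity offset and rotated by the user's wearing tilt (random unit
axis, angle 0.15–0.6 rad) — the same axis-angle forward model as the
rotation augmentation. Per-segment phase jitter (sd 0.5 rad) and
additive Gaussian noise (sd 0.05 g) supply intra-class variability.
Defaults: 4 activities x 4 users at 60 Hz, segment lengths 60–120
samples, 12 segments per class assigned round-robin over users; the
class-count vector is the imbalance dial (the imbalance experiment uses
40:40:40:4, i.e. 10:1). Missing values can be injected cell-wise i.i.d.
One RNG substream per segment, keyed by a counter, makes generation
order-independent and bit-reproducible.

Because the user effect is a pure rotation, the magnitude channel is
identical across users at zero noise while angle channels carry the user
signal — mirroring how orientation-free and orientation features behave
on real wearable data, and making both feature families informative.

What the generator does *not* emulate: non-stationary activity
composition within a segment, sensor drift and saturation, non-uniform
sampling, label noise, and realistic inter-activity confusability.
Passing the identifiability checks therefore shows the pipeline is
correct and leak-free under known separable conditions, not that it
attains any particular accuracy on real recordings.

## Experiment sizes and numerical choices

The identifiability experiment runs the fused ensemble once over 4
LOSOCV folds (48 windowed segments) and a 20-repeat label-permutation
control; the control and the 10-seed imbalance comparison use the
random-forest branch, since chance level under permutation is
model-independent and the balancing direction does not depend on the
deep branch — this keeps each experiment a few minutes on one CPU at
forest sizes of 200–500 trees. Degenerate inputs are defined, not
errors: constant series score zero on all dispersion statistics,
all-zero samples have zero angles, and a forest trained on one class
puts all probability mass there. Filter edge effects are handled by
`filtfilt` padding capped below the segment length.

## Known limitations

- The CNN is CPU-bound NumPy; it is sized for 60-sample windows and a
  handful of channels, not for large-scale training.
- LOSOCV with `target="user"` is structurally degenerate (the held-out
  identity never occurs in training); it is supported for its artifact
  contract, and meaningful user identification requires a within-user
  split, which the harness does not currently provide.
- The saturation-selection protocol refits forests over the whole k
  grid; with nested LOSOCV it is the most expensive stage and is off by
  default in the end-to-end pipeline.
- Augmented copies inherit the window length; augmentation of unwindowed
  variable-length segments is supported but untested against real
  recordings.
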