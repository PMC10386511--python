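# Methods

`groomkit` recognizes and times the grooming behavior of a small insect
filmed top-down in a dish. The pipeline has five stages: per-frame
body-region localization through a pluggable detector, inter-frame ROI
stabilization, 3D-convolutional classification of 16-frame units,
run-length merging of unit labels into a timed ethogram, and comparison
of that ethogram against manual annotation. A synthetic scene generator
stands in for real footage so that every stage is testable end to end.

## ROI stabilization

An object detector localizes the insect body in every frame, but its
boxes jitter in size and position even when the animal is motionless,
which would shake the field of view under the video classifier. The
stabilizer compares the Euclidean distance between the *raw* box
centers of consecutive frames

    d = sqrt((x_t - x_{t-1})^2 + (y_t - y_{t-1})^2)

with a pixel threshold (default 80, chosen from the threshold sweep
described below). When `d < threshold` (strict) the previous frame's
window is carried over unchanged — same origin, same size — so that a
non-walking run of frames yields crops of identical geometry. When
`d >= threshold` the subject is taken to be walking and the window is
rebuilt from the current raw box, expanded by a 15% margin per side
(the margin is a package choice; any fixed fraction works, it only
needs to keep the body inside the held window between rebuilds).
Windows in the classification path are *not* clamped to the frame:
clamping would shift an edge-adjacent subject off-center in the crop
and change the apparent appendage geometry, so overruns are instead
edge-padded at crop time. The coverage statistics below use clamped
windows, which is the realistic measure for a crop that must stay
inside the recorded image.

Two statistics summarize a threshold choice over a labeled clip set:

* stability rate of grooming clips: `(count_all − count_change) /
  count_all`, where frame 0 never counts as a change;
* body coverage rate of walking clips: `(count_all − count_out) /
  count_all`, a frame being "out" when the true box is not fully inside
  the held window.

Raising the threshold can only hold windows longer, so stability is
non-decreasing and coverage non-increasing in the threshold; the sweep
table reports both, pooled over frames by default (an unweighted
per-video mean is available, since the original averaging convention is
not recoverable from the published table).

## Classifier

The baseline classifier is the canonical C3D topology: 8 convolutional
layers (all kernels 3×3×3, stride 1×1×1), 5 max-pooling layers (2×2×2
except the first, 1×2×2, which preserves early temporal resolution),
two 4096-unit fully connected layers with dropout 0.5, and a softmax
over the 7 behavior categories, on 16×112×112×3 inputs.

The fusion variant deepens the backbone to 12 convolutional layers —
the two deepest blocks gain two layers each, keeping C3D's channel
plan (64, 128, 256×2, 512×4, 512×4) — and adds a shallow branch: one
3×3×3 convolution with exactly 16 kernels tapped at the output of the
first pooling stage, 3D **average**-pooled (average, not max, to keep
texture-rich shallow information) to a fixed 4×7×7 extent, flattened
and concatenated with the backbone flatten before the first fully
connected layer. The 16-kernel width keeps the fused fan-in small. The
exact tap point and the branch pool extent are not uniquely determined
by the published description; tapping after pool 1 and pooling to
4×7×7 satisfies every stated constraint and both are single-field
configuration changes (`NetworkSpec.branch_pool`).

Layers are implemented directly on numpy (BLAS matmuls over the 27
kernel offsets); analytic gradients of every layer are validated
against central finite differences in the test suite. Inputs are
mean-subtracted pixel stacks; the network scales them by a fixed 1/255
so that activations arrive at unit order, which the He initialization
assumes.

## Preprocessing and datasets

Clips are stored one directory per class, clip names "behavior name +
number", with a plain-text label index (`<clip> <class index>`; 0 is
the pooled resting-and-walking category, 1–6 the grooming classes).
Frames are standardized to 171×128 (width×height, aspect ratio
deliberately not preserved), and 16-consecutive-frame stacks are cut
with one shared 112×112 crop — random in training, centered in
evaluation — one shared horizontal-flip decision (p = 0.5, training
only), and per-stack RGB mean subtraction. Crop and flip decisions are
per-stack rather than per-frame to preserve temporal coherence. The
sliding-window stride defaults to 16 (non-overlapping, the detection-
unit granularity); train/test splits are clip-level, per-class
stratified at 4:1, with the per-class test count rounded to the nearest
integer (ties toward train). Walking clips are ROI-cropped like
everything else by default; the alternative scheme that feeds
original-size walking frames is available (`walking_crop="original"`).

## Training

SGD with momentum 0.9 (momentum is a package choice; the published
recipe states SGD without it), batch size 8, initial learning rate
0.003 decayed ×0.1 every 4 epochs, 20 epochs, cross-entropy loss,
dropout 0.5 after both fully connected layers (the published wording
"the dropout layer following the fully connected layer" is ambiguous
between one and both; both is the default and configurable). The
training loop records per-epoch train/test accuracy and loss and
retains the best-test-accuracy checkpoint. All randomness (init,
shuffling, augmentation, dropout) flows from explicit seeds.

Networks without normalization layers propagate the scale of their
input statistics multiplicatively through depth; at full C3D width
this is tamed by sheer parameter count and tens of thousands of SGD
updates, but a width-reduced variant on a desk-scale corpus stalls: the
forward signal attenuates until softmax gradients vanish (and a
2-channel first layer can die outright). `calibrate_init` therefore
applies a layer-sequential unit-variance pass on one sample batch —
each conv/FC layer's weights are rescaled until its post-activation
output has unit standard deviation — and zeroes the classifier head so
the initial prediction is exactly uniform and early updates fit the
data rather than unlearning initialization noise. This is an
initialization calibration, not an optimizer change; it is
deterministic given the batch and leaves full-width behavior
essentially unchanged.

## Detection units and ethograms

Continuous video is tiled into back-to-back units of 16 frames (0.64 s
at 25 fps; times are always derived from frame counts and the true
frame rate, never from the rounded 0.6 s). Each unit is classified
from the center 112×112 crop of its stabilized, standardized ROI
frames; stabilizer state persists across unit boundaries. Runs of
identical unit labels merge into behavior intervals with
`start_time = start_frame / fps` and `end_time = (end_frame + 1) /
fps`. A unit in which the detector returned no box at all is labeled
as the non-grooming category with a warning; isolated misses are
forward-filled from the last accepted box.

## Evaluation

Unit-level results aggregate into a confusion matrix (rows true,
columns predicted) with accuracy = trace/total and one-vs-rest
precision, recall and F1 per class; a never-predicted class reports
precision 0 with an explicit flag.

Ethogram comparison counts how many manually recorded behaviors the
automatic table reproduced: greedy in temporal order, one-to-one, a
manual interval matching the first unmatched predicted interval with
the same label, temporal overlap, and both boundary deviations within
25 frames. One-to-one consumption is a package choice; the published
procedure does not say whether a manual interval may match several
predicted fragments. The per-video difference degree is
`100·(n_manual − n_matched)/n_manual` **truncated** to two decimals —
truncation, not rounding, is the only convention consistent with every
published per-video value (e.g. 5/36 → 13.88, 8/56 → 14.28) — while
the summary row averages the untruncated ratios and rounds to two
decimals.

## Synthetic scenes

The generator emulates the recording geometry: a 480×360 field at
25 fps (the original 1920×1080 scaled down) with a single subject
whose tight box (90 px, ~5% of the frame area) matches the "small
subject, wide field" regime. The subject is a dark ellipse with six
appendage blobs placed in mirror-symmetric left/right pairs about the
body axis — grooming is bilaterally symmetric in the real animal, and
symmetric anchors also make the rendered classes invariant under the
training-time horizontal flips. Each grooming class oscillates one
anchor pair radially with a class-specific period (6–17 frames);
resting shows no local motion; walking translates the subject at
`walk_speed` pixels/frame (default 20, ~36 mm/s with the dish spanning
the frame — a realistic pace for an actively walking fly, and large
against detector jitter so walking is separable from box noise by
inter-frame center distance) along a straight, wall-reflected track. The
background is a static low-frequency texture (the original dish
appearance is not described quantitatively, so any static background
is admissible). Ground truth is a tight box per frame plus the
behavior-interval table; the oracle detector adds independent Gaussian
jitter per box edge and Bernoulli misses.

What the generator does *not* emulate: appearance variation between
individuals, limb articulation and occlusion, lighting change, shadows
and reflections, detector failure modes that correlate with pose. A
pipeline that is perfect on these scenes is therefore not validated on
real footage; the synthetic results validate the machinery (geometry,
bookkeeping, optimization, interval logic), not biological recognition
accuracy.

## Desk-scale study conditions

The published experiment trains on ~29k behavior intervals for 20
epochs (~40 GPU-hours); its headline numbers depend on footage that is
not distributable. The repository's end-to-end experiment instead uses
a deliberately small, CPU-sized configuration, chosen once:

* 4 classes ("0", head, foreleg, wing), 40 clips per class, 16 frames
  per clip, detector jitter sigma 2 px;
* stabilizer threshold 10 px: the 80 px default belongs to
  1920-px-wide footage and scales to ~20 px at the generator's 480-px
  frames; 10 px sits between grooming box noise (~2–3 px center steps)
  and walking (~20 px steps) with margin on both sides;
* fusion network at width multiplier 1/32 (branch fixed at 16 kernels);
* variance-calibrated init with a zeroed classifier head, 10 epochs,
  batch 1 (the corpus yields only 128 training stacks, so single-sample
  updates maximize the SGD steps available inside the epoch budget),
  learning rate 0.01 decayed ×0.1 at epoch 8, dropout 0.25
  (regularization scaled down with capacity and data; the full-width
  default stays 0.5), global gradient-norm clipping at 5 and a leaky
  rectifier slope of 0.1 — both guards against single-sample momentum
  updates that can otherwise kill the very narrow first layer;
* seeded random-restart initialization: candidate inits are probed
  for 3 epochs and discarded while held-out accuracy stays at the
  4-class chance level (narrow normalization-free networks have an
  init-dependent flat region where feature-layer gradients vanish; the
  escape is an initialization lottery, so restarts are the standard
  remedy, as with `n_init` in k-means). The first escaping init is
  retrained from scratch for the full 10-epoch budget; everything is
  deterministic given the seed;
* 8 held-out continuous sessions of 4–6 behavior segments (2–3 units
  each) for the ethogram comparison.

These values are problem-size choices for a single-CPU run of the
acceptance script and test suite; they are not tuned to any published
number.

## Known limitations

* The numpy network is CPU-bound; full-width training at the published
  scale is out of reach (and out of scope).
* The stabilizer assumes exactly one subject; multi-animal scenes and
  motion-model smoothing are non-goals.
* The interval matcher is greedy; pathological overlap patterns could
  in principle match fewer intervals than an optimal assignment.
* Synthetic scenes validate machinery, not field performance (above).
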