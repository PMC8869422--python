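# Methods

## Problem and model

The task is binary segmentation of a day of 6-axis wrist motion into eating
episodes. The pipeline separates three concerns:

1. a **window classifier** estimating P(eating) for a fixed-length window,
2. **dense inference** turning the classifier into a per-datum probability
   trace p(e) over the day, and
3. a **hysteresis detector** turning the trace into discrete episodes.

The classifier is deliberately small: three 1D convolution layers
(f = 10 filters each; kernel lengths L = 44, 20, 4; stride 2; valid padding;
relu), global average pooling, a 200-unit relu dense layer, and a sigmoid
output. The first kernel spans ≈ 3 s at 15 Hz — the scale of one
hand-to-mouth gesture — and the stacked strides give the last conv layer a
receptive field of 94 samples (≈ 6 s) sampled every 8 data, so pooled
features summarize gesture-scale patterns across the whole window. Global
average pooling makes the weight count (7471) independent of the window
length W, which is what allows W itself to be treated as a hyperparameter.

Training: binary cross-entropy, Adam with learning rate 10⁻⁴, batch size 32,
fixed epoch budget (no early stopping; the weights after the last epoch are
used). Windows are cut at a 15 s slide and labeled eating when strictly more
than half of the window overlaps the union of annotated meals; the non-eating
class is undersampled to a 1:1 ratio.

## Numerical and implementation choices

* The CNN is implemented directly in numpy (im2col convolutions, explicit
  backprop, Adam). At ~7.5 k weights this trains in minutes on one CPU core;
  backprop is verified against central-difference gradients in the test
  suite. Training runs in float32; prediction runs in float64 so batched and
  one-by-one evaluation agree to ~1e-13.
* **Dense whole-day inference.** Sliding a stride-2 conv stack one datum at a
  time re-computes each convolution ~W·60·15 times. Instead, the stack is
  evaluated once over the full day as *dilated* convolutions (dilation 1, 2,
  4), after which the global average pool for every window start is a
  difference of per-phase cumulative sums, and the dense head is applied to
  all starts at once. This is arithmetically the same computation reordered,
  and unit tests compare it to literal per-window evaluation (agreement to
  float tolerance). It makes the default slide of 1 datum affordable for
  full-day recordings.
* Convolution weight initialization is He-normal (appropriate for relu);
  the L1 penalty on conv weights defaults to 1e-4, small enough not to
  dominate the cross-entropy on balanced batches. Neither value is claimed
  to match the original training setup; both are configurable.
* Gaussian smoothing uses a kernel truncated at 4σ with reflect padding
  (stated constants; the smoothing step itself only fixes σ = 10 samples).
  z-normalization uses population (1/n) standard deviation, per axis, per
  recording by default; pooled dataset-level statistics are available via
  `preprocess.stats_scope = "dataset"`.
* Hysteresis uses strict inequalities: a segment opens at the first datum
  with p > T_S and closes at the first datum with p < T_E (exclusive end).
  A segment still open at end of day is closed at the last datum + 1. The
  merge rule is inclusive (gap ≤ 60 s merges), the minimum-length rule is
  strict (a segment of exactly 60 s survives), and merging precedes
  dropping — so two 40 s detections 30 s apart survive as one episode. All
  four conventions are pinned by oracle tests against a literal per-datum
  reference implementation.
* Within W/2 of the day's edges no full window fits; the trace is defined
  as p = 0 there (the conservative class) so every day has a total trace.
  With an inference slide k > 1, probabilities between evaluated window
  centers are linearly interpolated.
* Boundary errors are signed (detected − self-reported, minutes); for a meal
  overlapped by several detections the start of the first and the end of the
  last are used. Reported spread is the population standard deviation.
* Weighted (class-balanced) datum accuracy is defined as
  (recall + TNR) / 2. With the per-datum rates this package computes
  (e.g. recall 0.69, TNR 0.93) it reproduces the conventional reported
  values within rounding; the exact historical formula behind that metric
  name is not documented anywhere we know of, so balanced accuracy — the
  standard choice — is adopted and stated.
* FP/TP with zero TPs is reported as NaN with a `fp_per_tp_defined` flag
  rather than raising, so threshold sweeps run to completion.

## Cross-validation and sweeps

Folds are assigned to *subjects* (shuffled round-robin; sizes differ by at
most one), never to days, and every fold run asserts train/test subject
disjointness. Sweeps tune one hyperparameter at a time: sweeping W retrains
per value; sweeping T_S or T_E reuses the per-fold trained model and cached
probability traces, since thresholding is cheap. Sweep results are therefore
bitwise independent of the order of swept values, which is also tested.

## Synthetic data generator

The generator produces annotated days with the statistical structure the
method relies on, not biomechanically faithful arm motion:

* **Day**: 13 h at 15 Hz (the scale of a waking day of recording).
* **Meals per day**: truncated Poisson (mean 3, clipped to 1–6).
* **Meal durations**: log-normal, median 11 min and mean 14 min, truncated
  at 1 min. Fixing median and mean gives σ = √(2 ln(14/11)) ≈ 0.694, which
  implies a standard deviation of ≈ 11 min — matching all three summary
  statistics of the target distribution with a two-parameter family. With
  ~3 meals/day this yields ≈ 5% of samples inside meals, the imbalance that
  motivates undersampling.
* **Meal interior**: bite gestures (3–5 s; a raise-then-lower angular
  velocity profile of 60–120 deg/s, so rotational RMS always dominates the
  linear channels) separated by exponential gaps (mean ≈ bite interval of
  20 s, clipped 2–60 s) filled with rest or food-preparation gestures; the
  prep share defaults to ≈ 18% of meal time, reflecting that a substantial
  fraction of a real "meal" is not ingestion.
* **Background**: rest (low-amplitude drift) and walking (1.5–2 Hz
  oscillation on the accelerometer axes, the signature that makes walking
  easy to classify) in a 3:1 time ratio, plus isolated bite-like
  *confounder* gestures at 2/h so the detector's false-positive behavior is
  exercised.
* Accelerometer channels carry a gravity baseline of (0, 0, 1) g plus white
  noise (σ = 0.05 g); gyro noise is scaled ×20 (deg/s vs g units).
* All randomness flows through one `numpy` generator per day; per-day seeds
  are spawned deterministically from a master seed, and each day gets a
  distinct synthetic subject id (mirroring a corpus where >99% of days come
  from unique individuals).

**What passing on synthetic data shows — and does not.** The generator
guarantees (and tests assert) that a plain gyro-variance threshold already
separates eating from background windows, so an end-to-end run demonstrates
that the pipeline trains, infers, segments, and scores *correctly*, with
headroom for the CNN to beat a trivial feature. It does not demonstrate
free-living performance: real recordings contain eating-like confounders at
far higher rates (typing, grooming, conversation gestures), sensor drift,
secondary activities during meals, and annotation noise, none of which are
simulated. Absolute synthetic scores are therefore expected to be much
higher than anything achievable on real data.

## Study sizes used in the tests

The shipped end-to-end benchmark simulates 30 days, trains the 1-minute
window model for 30 epochs on 20 days (~7.5 k balanced windows), and
evaluates on 10 held-out days with an inference slide of 15 data — sizes
chosen so the full suite runs comfortably on a single CPU core while leaving
every stage of the pipeline exercised at realistic day lengths. The
window-size comparison trains a second model at W = 7.5 s on identical data.
The chance-level (leakage) control retrains with permuted labels. One
subtlety: after noise-only training the classifier's output is nearly
constant across windows, so the thresholded balanced accuracy of a *single*
permutation run is a knife-edge draw that can land well away from 0.5 in
either direction even with thousands of held-out windows (the effective
sample size is ~1, not ~n). Chance level is therefore asserted on the mean
over three independent label permutations, with all seeds fixed so the check
is deterministic.

## Known limitations

* Not a bite counter: episodes are found top-down; individual ingestion
  events inside an episode are out of scope.
* Short episodes (snacks of a few minutes) are intrinsically hard for
  multi-minute windows; the default configuration trades snack sensitivity
  for a low false-positive rate.
* The flat-binary reader assumes little-endian IEEE floats (4- or 8-byte,
  configurable) at a fixed 15 Hz; no resampling or clock-drift correction.
* Whole-day batch inference only; no streaming mode.
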