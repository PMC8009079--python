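# Methods

## Signal model and windowing

The package operates on labeled tri-axial accelerometer streams sampled at a
fixed rate (default f = 20 Hz, i.e. one reading every 50 ms) with values in a
nominal sensor range of [−20, 20] m/s². A stream is first split into
*segments* — maximal runs of consecutive samples with the same (user,
activity) — and windows are extracted only inside a segment, so every window
has a single ground-truth label. Timestamps are carried as metadata but play
no role in windowing; windows are defined purely by sample count
(ν = Δt · f, default Δt = 10 s → ν = 200) and stride (default 10 samples).

The ceiling-form count ⌈(D − ν)/stride + 1⌉ for a segment of length D admits
one final partial window whenever the stride does not divide D − ν. How such
a partial window should be filled is unspecified, and any padding policy
would inject invented samples, so the extractor emits complete windows only
(floor-based); the ceiling formula is kept as a separate function
(`sliding_window_count`) for cross-checks, and the two agree exactly whenever
the stride divides D − ν. This is the one place where the pipeline's window
counts can differ by one per segment from counts computed with the ceiling
formula.

## Co-occurrence images

Each window becomes one image with nC = q(q−1)/2 channels, one per unordered
axis pair, in the fixed order (X,Y), (X,Z), (Y,Z) for q = 3. Both coordinates
of a pair are quantized into μ bins and cell (i, j) counts the samples
falling into that bin pair, capped at 255 (an 8-bit grey level) and divided
by 255.

Design choices worth stating explicitly:

* **Global quantization range.** The bin grid spans the global sensor range,
  not the per-window min/max: a convolutional network needs fixed input
  geometry, and a shared grid keeps intensities comparable across images.
  The defaults are [−20, 20] with μ = 40, i.e. 1 m/s² per bin. A quantization
  *step* can be given instead of a bin count: in sensor units μ = η/Q
  (`from_step`), or as a fraction of the normalized 0–1 range μ = 1/Q
  (`from_normalized_step`, Q = 0.025 → 40). Both are exposed; neither is
  silently blended with the other.
* **Normalization divides by 255**, not by the per-image maximum, so the
  same raw count has the same intensity in every image.
* **Binning convention.** Half-open bins [edge, edge + w) with a closed top
  bin (v = value_max maps to bin μ−1); out-of-range values are clipped into
  the border bins by default, or rejected when clipping is disabled. The
  first axis of a pair indexes rows, the second columns; swapping the axes
  of a pair transposes the channel (tested).

The batched builder computes all windows' histograms in one vectorized
`bincount` pass and is tested to be bit-identical to the per-window path,
which in turn is tested against a brute-force per-sample double loop.

## The classifier

Architecture (defaults): conv 2 filters 2×2 (same padding, ReLU) → maxpool
2×2 → conv 4 filters 2×2 → maxpool 2×2 → flatten (40→40→20→20→10 spatially,
so 10·10·4 = 400 features) → dense 48 (ReLU) → dropout 0.5 → dense 24 (ReLU)
→ dropout 0.5 → dense 6 + softmax. Loss is sparse categorical cross-entropy;
the optimizer is Adam (step 10⁻³, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷). The
full-scale training recipe is 100 epochs at batch size 5.

The network is implemented directly in numpy:

* Convolution is **cross-correlation** (no kernel flip), per-channel kernels
  summed over input channels; "same" padding at stride 1 pads
  (a−1)//2 before and the remainder after, so odd total padding puts the
  extra zero at bottom/right. The fast path computes each 2×2 kernel tap as
  a shifted channel-matmul; its output is tested to 10⁻⁶ against a naive
  six-nested-loop transcription of the defining sums, and the analytic
  gradients are tested against central finite differences on a small network
  in float64.
* Max-pooling is non-overlapping k×k with trailing remainder rows/columns
  dropped; pooling gradients route through the argmax (first occurrence on
  exact ties).
* Dropout is inverted (mask scaled by 1/(1−rate)) and active only during
  training.
* Weights are Glorot-uniform; biases zero. All randomness — initialization,
  shuffling, dropout masks — flows from the single training seed, so
  training is bit-reproducible on a single-threaded numpy backend.
* Prediction is the argmax of the softmax vector; exact ties resolve to the
  lowest class index (numpy argmax semantics, documented and tested).

Data are held in float32 for memory and speed; the forward pass preserves
float64 inputs so that numerical verification is not precision-limited.

## Metrics and cross-validation

Per-class metrics come from one-vs-rest reduction of the multi-class
confusion matrix (rows = actual, columns = predicted): TP is the diagonal
cell, FN the rest of the row, FP the rest of the column, TN everything else
— note TN enters the per-class accuracy, which is why per-class accuracies
exceed the overall (trace) accuracy on imbalanced data. AUC here is the
sensitivity–specificity average (balanced accuracy), *not* a ROC area, and
F-measure is the harmonic mean of sensitivity and precision. Undefined
ratios (zero denominators) are reported as NaN and flagged by name, never
coerced to 0. Rounding for table display is round-half-even to 3 decimals,
applied only at the final step.

Cross-validation is stratified per class with a seeded shuffle; each fold's
held-out predictions are pooled into one confusion matrix in which every
sample appears exactly once, and all metrics are computed from the pooled
matrix. Cross-class summaries report the mean, the sample standard
deviation, and two interval conventions — mean ± 1.96·sd/√n (normal theory)
and mean ± sd — because published tables are ambiguous about which is meant;
neither is treated as authoritative.

**Caveat: window overlap.** With stride 10 and ν = 200, consecutive windows
share 95% of their samples. The default split is per image (matching the
standard protocol for this method), which means near-duplicate windows can
land on both sides of a fold boundary and optimistically bias the estimate.
A grouped assignment (`groups=` in `cross_validate`, keeping e.g. each user's
images in one fold) is provided for a stricter protocol; it is not the
default.

## Published reference results

`harimages.reference` bundles the pooled 10-fold confusion matrix reported
for the method's original evaluation on the public WISDM v1.1 dataset
(105,205 images over six activities). The published table of that evaluation
is reproduced exactly, at 3-decimal rounding, by running this package's
metric pipeline on that matrix — per-class rows, the mean row and the
standard-deviation row — which pins down every reduction and rounding
convention used here. The printed matrix's row order was disambiguated using
the published per-class image totals as row-sum constraints (the resulting
parse is unique and its row sums match those totals exactly).

## Synthetic data: what it does and does not show

Each activity is modeled as a static gravity orientation plus one or two
sinusoids and i.i.d. Gaussian noise per axis, clipped to the sensor range:
jogging as a high-amplitude ~2.5 Hz vertical oscillation, walking ~1.7 Hz at
lower amplitude, stair climbing walking-like with an opposite-sign
forward-axis gravity bias per direction and distinct vertical amplitude, and
sitting/standing as static postures distinguished by gravity orientation
(on Z when sitting, on Y when standing). Amplitudes and noise levels (0.3
m/s² static, 0.8 walking, 1.5 jogging) were chosen once as plausible
magnitudes for pocket-worn phones; profile validation enforces the Nyquist
limit and forbids systematic clipping. Timestamps are exact 50 ms spacings
(optional jitter flag). Generation is a pure function of the dataset spec;
per-(user, activity) sub-seeds derive deterministically from the top seed.

The generator reproduces the *structure* of real recordings — contiguous
per-activity segments, per-class orientation/frequency/amplitude signatures,
bounded values — but none of the hard parts of real accelerometry:
within-class variability across subjects, autocorrelated and non-stationary
noise, transitions, device orientation drift. The default classes are
separable by a nearest-centroid classifier on window mean/variance features
(tested, >90%), which is intentional: it makes the end-to-end classifier
tests well-posed. Consequently, perfect synthetic cross-validation accuracy
demonstrates that the pipeline and classifier are implemented correctly and
can learn the encoding, not that the method achieves any particular accuracy
on real data.

## Benchmark problem sizes

The package's desk-scale benchmark (in `harimages.experiments`, also run by
`scripts/acceptance.py`) is 36 synthetic users × 6 activities × 60 s at
20 Hz → 216 segments × 101 windows = 21,816 images, evaluated with 3-fold
cross-validation at 10 epochs and batch size 32. These sizes were chosen as
the package's standard quick-run configuration: large enough that every
class has thousands of images and the stratified pooling machinery is
exercised, small enough to run in minutes on one CPU core. The full-scale
recipe (10 folds, 100 epochs, batch 5) remains the configurable default of
the training/evaluation APIs.

## Known limitations

* No biomechanically realistic gait model; synthetic profiles are stand-ins.
* Single-sensor images only (q ≥ 2 axes supported; fusing several sensors'
  images into one sample is out of scope).
* No GPU path; training is practical up to ~10⁵ images on one CPU core.
* The EDA-style cleaning implements exactly one rule — removing samples
  whose three axes all read exactly 0 (gravity makes a true all-zero reading
  physically implausible) — and nothing else.
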