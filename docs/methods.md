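# Methods

## Problem setting

`frlf` implements decision-level fusion for an ensemble of classifiers
that each emit a softmax-style confidence vector per input — the setting
of CNN-based Parkinson's disease detection from DaTscan SPECT images,
where four base networks (VGG16, ResNet50, Inception-V3, Xception)
produce per-class confidences on a binary PD / non-PD task.  The
package covers everything downstream and upstream of network training:
slice preprocessing, the fusion rules themselves, binary diagnostic
metrics, and a simulator standing in for the trained networks.  Network
training itself is out of scope; the reference training configuration
(500 epochs, batch 16, step 32, learning rate 0.001, Adam) is recorded
here only as documentation of the setting the fusion stage was designed
for.

## Fuzzy rank level fusion

Given `N` models and `C` classes, with normalized confidences
`CS_c^i` (each model row sums to 1), each score maps to a fuzzy rank

    R_c^i = 1 - exp( -(CS_c^i - 1)^2 / (2 * v) ),    v = 1 by default.

This is the complement of an unnormalized Gaussian centred at the ideal
confidence 1: rank 0 means perfect confidence, and the rank saturates at
`1 - exp(-1/(2v))` (≈ 0.3935 for `v = 1`) as confidence falls to 0.
Unlike ordinal ranking, proximity matters: two near-tied confidences get
near-tied ranks.

Each model contributes a top-K set (the `k` classes with smallest rank;
`k = 1` by default).  Per class:

    RS_c  = Σ_i ( R_c^i    if c in topK_i else P_R )      rank sum
    CSS_c = 1 - (1/N) Σ_i ( CS_c^i if c in topK_i else P_CS )
    FS_c  = RS_c × CSS_c

and the decision is `argmin_c FS_c`.  The penalties `P_R = 0.33` and
`P_CS = 0.05` substitute for the rank and the confidence of any class
outside a model's top-K set, pushing weakly supported classes away from
the minimum.  The defaults are the values reported as optimal for the
DaTscan task; both are plain scalars (not per-class), which is how the
single printed values are read here.

Reading notes on the defining formulas, where the published notation is
ambiguous:

- The penalty substitution in `CSS_c` happens *inside* the mean, before
  complementing.  This is the reading under which the penalties act as
  intended (a class missing from all top-K sets gets
  `CSS = 1 - P_CS = 0.95`, close to the worst possible complement).
- The final score multiplies `RS_c` by `CSS_c` (the source text's
  "CFS" is taken as the confidence-sum complement).
- Normalization divides each row by its sum; softmax outputs already
  satisfy it, so this is a no-op in the intended pipeline.  An all-zero
  row carries no information and maps to the uniform row `1/C` rather
  than erroring, preserving proportions everywhere else and injecting
  no temperature.

Tie-breaks (top-K membership and the final argmin) go to the lowest
class index, making every decision deterministic.  Aggregation is done
in double precision; the argmin compares computed values exactly.

### Why both factors

`RS` and `CSS` fall with confidence in different ways: the Gaussian
complement is insensitive near `CS = 1` (flat top) and steep in the
mid-range, while the confidence complement is linear.  Their product
rewards classes that are simultaneously top-ranked by every model and
backed by high raw confidence; a class that sneaks into a top-K set
with mediocre confidence still carries a large `CSS` factor.

## Baseline rules

Sum rule (`argmax Σ_i CS_c^i`), product rule (`argmax Π_i CS_c^i`), and
majority voting (each model votes its argmax).  Product-rule zeros
annihilate a class; no epsilon flooring is applied by default (an
optional `floor` clips from below for users who want it).  Majority-vote
ties are resolved by the sum rule restricted to the tied classes, then
by lowest index — the published description leaves ties open, and this
cascade keeps the decision deterministic while using the available
score information.

## Diagnostic metrics

From TP/TN/FP/FN with the disease class positive:
accuracy `(TP+TN)/total`, precision `TP/(TP+FP)`, sensitivity
`TP/(TP+FN)`, specificity `TN/(FP+TN)`, F1 the harmonic mean of
precision and sensitivity.  A metric whose denominator is zero is
*undefined* (`None`, rendered `NA`), never silently 0 — silent zeros
corrupt result tables.  Percentages render with two decimals, rounding
half up; published tables in this domain mix rounded and truncated
values, so comparisons elsewhere use a ±0.01 percentage-point band.
`counts_from_rates` inverts printed sensitivity/specificity plus class
sizes back to integer counts (nearest integer), which is how a printed
results table can be checked for internal consistency.

## DaTscan preprocessing

DaTscan volumes arrive as 91 slices of 109 × 91 voxels.  The pipeline
takes the 41st axial slice (1-based count — the convention adopted
here, exposed as a parameter since slice numbering conventions vary),
crops the tight bounding box of pixels brighter than a threshold
(default 0, i.e. strictly black borders; the border removal rule is an
interpretation since no crop rule is published), bilinearly resizes to
224 × 224 (the standard CNN input size; interpolation order was an open
choice), and min-max scales to [0, 1].  Degenerate cases have fixed
conventions: an all-black image crops to its 1 × 1 centre pixel, and a
constant image scales to all zeros.  A multiplicative brightness factor
in [0.1, 1.5] is provided as a *training-time* augmentation only — the
bracket matches common augmentation configs — and is never applied at
evaluation.  The 80:20 train/test splitter assigns
`round(0.2 · n)` samples to test with a seeded shuffle, unstratified
by default (matching the observed 86/43 test composition arising from
an unstratified draw of the 432/213 cohort), with an optional
stratified mode.

PNG export uses 16-bit grayscale so the [0, 1] scaling survives
round-trips to within 1/65535; DICOM reading is isolated behind
`read_dicom_volume` so everything else operates on plain arrays.

## Synthetic score generator

No public simulation accompanies the method, so the generator's
distributional choices are this package's own.  For each sample a true
label is drawn (binary prevalence defaults to 86/129, the positive
fraction of the DaTscan test split, so simulated confusion tables live
at the study's scale).  Each model independently favors the true class
with its configured accuracy (default 0.93, the ballpark of the four
base CNNs), otherwise a uniformly drawn wrong class.  Its score row is
drawn from a Dirichlet with mass `concentration` (default 20, giving
mean winner confidence ≈ 0.95 on the binary task — sharp but not
saturated, resembling softmax outputs of a well-trained network) on the
favored class and 1 elsewhere; the favored entry is then swapped into
the argmax position, so the configured accuracy is exact by
construction rather than approximate.  Sharpness and accuracy are
thereby independently tunable.  All draws flow from one seed;
identical configs reproduce bitwise.

What the simulator does *not* emulate: correlated errors between models
(real CNNs trained on the same images err on overlapping subsets),
miscalibration drift, and any image structure.  Passing fusion tests on
simulated scores therefore demonstrates the algebra and the
independent-ensemble gain, not performance on real DaTscan images —
reproducing the published image-level accuracies would require the
cohort data and GPU training, which this package deliberately does not
depend on.

## Problem sizes and numerics

The oracle-equivalence check compares the vectorized fusion against a
pure-Python scalar transliteration on 1000 random matrices
(`N ∈ 1..5`, `C ∈ 2..6`, random `k`) at 1e-12 absolute tolerance.  The
ensemble-gain study uses 4 models at accuracy 0.93 on 5000 samples per
seed across 10 seeds — large enough that the binomial noise on a
per-seed accuracy is ≈ 0.2 percentage points, far below the observed
≈ 5.7-point gain.  Score-matrix CSVs are written with `%.17g` and read
with round-trip float parsing so file round-trips are bit-exact.

## Known limitations

- Metrics are binary only; multiclass macro-averaging, ROC/AUC and
  confidence intervals are out of scope.
- The fusion rules assume models are worth equal weight; no learned or
  weighted combination is provided.
- `counts_from_rates` assumes the printed rates round to the nearest
  representable count; it cannot detect a table that is wrong by a
  whole count in both numerator and denominator simultaneously.
- The brightness augmentation and split utilities support a training
  pipeline that this package does not itself run.
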