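# Methods

## Problem and scope

A radial-artery pulse recording is a quasi-periodic pressure signal, one
period per cardiac cycle. Downstream analyses consume *single-period
segments*, so two things must work reliably: cutting the series at pulse
onsets, and rejecting segments that are not clean single cycles (the two
failure sources being segmentation error and interference). `pulseqc`
implements both, plus the machinery to re-derive and stress-test the quality
classifier on synthetic data with exact ground truth.

## Segmentation by derivative thresholding

Amplitude thresholds on the raw signal are defeated by baseline wander
(respiration, motion), but the first derivative is nearly wander-free. The
procedure, per threshold coefficient α:

1. `threshold = M·α`, where `M` is the record's maximum forward-difference
   derivative (scaled by the sampling rate). Flat or monotonically
   decreasing records have `M ≤ 0` and raise a no-pulse error.
2. Upward crossings are indices `i` with `deriv[i−1] < threshold ≤ deriv[i]`.
   If the record opens mid-upstroke (`deriv[0] ≥ threshold`), index 0 counts
   as a crossing clipped at the boundary; otherwise the first cycle would be
   silently lost for short periods at low α.
3. Each crossing is traced backward to the last derivative sample ≤ 0; the
   original-signal sample after it is the segmentation point (the pulse
   foot, a local minimum). Exact derivative zeros are measure-zero in
   sampled data, hence "first non-positive". A crossing with no non-positive
   history maps to index 0.
4. Segments are spans between adjacent distinct onsets, inclusive of both
   boundary samples, so `x₁` and the final feature point both sit on onset
   minima. Multiple crossings within one upstroke deduplicate to one onset.

Defaults follow the published protocol: α ∈ {0.1, 0.3, 0.5, 0.7, 0.9}, at
most 5 uniformly sampled segments per threshold (seeded, without
replacement, temporal order preserved), at most 25 per record. Exact
duplicates (same start and end) produced by different thresholds are removed
before the record cap — the protocol's stated motivation is avoiding
repetitive near-identical waveforms — and `--keep-duplicates` restores the
literal behaviour. The derivative scheme is the forward first difference;
central differences would shift index bookkeeping by half a sample without
changing any conclusion at the lengths involved.

## Standardization

Each segment is min-max rescaled (`y = (x − min)/(max − min)`; constant
segments are flatlines and raise a degenerate-segment error) and then
resampled with an interpolating cubic spline (not-a-knot boundary, the
standard default; configurable) evaluated at L equally spaced points on the
closed interval, so both endpoints are preserved exactly. The operation
order is rescale-then-resample. Spline overshoot can push interior values
slightly outside [0, 1]; these are **not** clipped, since clipping would
distort the peak-shape features. The two operation orders agree to within
that overshoot (property-tested bound < 0.05 on pulse-like cycles).

L = 15 is the operating length of the shipped classifier; L = 100 retains
the full clinically useful bandwidth (≤ 25 Hz over a ≤ 2 s cycle) and is the
ceiling of the standard-length sweep (trial lengths 3–100).

## The quality classifier

The shipped model is fixed (never refit):
`P = sigmoid(−9.6919·x₁ + 8.2570·x₃ + 8.9216·x₄ − 7.9818·x₁₄ − 10.8732)`,
threshold 0.5, ties classified normal. "Normal" is the positive class
throughout the package: sensitivity is the true-normal rate, specificity the
true-abnormal rate. Of the expert labeling criteria only the
horizontal-baseline rule — |start − end| ≤ half the amplitude, boundary
inclusive — is checkable on an isolated raw segment and is exposed as
`check_baseline_rule`; the others (single complete cycle, no serious
interference, cohort similarity) exist as ground-truth constructions in the
synthetic generator.

Known blind spot: anomalies confined to feature points the model does not
read (e.g. a negative baseline step late in the cycle, which mimics a deep
diastolic dip) can score as normal. The synthetic `baseline_jump` anomaly
exercises exactly this and is detected only ~half the time — deliberately
left in the default anomaly mix so corpus metrics reflect the model's real
limits rather than a rigged ceiling.

## Training harness

* `fit_logistic_l2` — L2-penalized logistic regression (lbfgs, tol 1e-8);
  `l2_strength` is the penalty weight in the standard regularized-loss
  parameterization (scikit-learn `C = 1/l2_strength`), default 1.0. The
  original model's exact coefficients are not reproducible without the
  clinical corpus and its (unstated) penalty; this is a documented
  irreproducibility.
* `cross_validate` — stratified seeded k-fold (default 10); stratification
  prevents single-class folds at small n. Grids follow the published search
  (KNN neighbors 1–50; SVM cost {0.01…100} × gamma {0.001…10}; linear kernel
  over cost only). The selection criterion is mean CV accuracy; the best
  setting's accuracy/sensitivity/specificity mean ± sd over folds is
  reported.
* `rfe_rank` — recursive feature elimination, one feature per iteration,
  importance = absolute weight (comparable because all features share the
  [0, 1] scale after standardization); ranking is reverse elimination order.
* `sweep_standard_length` / `sweep_feature_count` — the length-sweep and
  feature-count-sweep tables, re-standardizing raw segments at each trial L
  and cross-validating on the top-k ranked features respectively.
* `split_corpus_by_record` — train/test splitting at the record (patient)
  level so segments from one recording never straddle the split.

Whether the original cross-validation was stratified, and which class its
sensitivity treats as positive, are not stated in the source protocol; this
package stratifies and treats normal as positive (consistent with the
model's "P is the probability of normal" orientation).

## Synthetic data generator

The generator is the package's stand-in for clinical data (which is not
publicly deposited) and the oracle for every accuracy claim. A normal cycle
of unit amplitude on t ∈ [0, 1):

* raised-cosine systolic rise from 0 to the peak at t = 0.19 (radial pulses
  peak early in the cycle);
* raised-cosine systolic fall to a diastolic shoulder of 0.35 at t = 0.45;
* linear diastolic runoff from the shoulder to 0.02 at the cycle end;
* a Gaussian dicrotic bump (amplitude 0.12, σ = 0.08) at t = 0.62.

Two of these choices are load-bearing for the segmentation guarantees. The
*linear* diastole keeps the derivative ≈ −0.6/T throughout late diastole,
strictly steeper than the worst admissible wander slope (amplitude ≤ 50%,
period ≥ 10 cycles ⇒ ≤ 2π·0.5/10T ≈ 0.31/T), so wander can never turn the
diastolic derivative positive — this is what bounds segmentation-point
shifts under wander at ≲ 1 sample. The dicrotic bump sits entirely on that
linear segment with net upstroke slope ≤ ~0.65/T, below the lowest
threshold (0.1·M ≈ 0.83/T), so low-α thresholding never fires mid-cycle on
a clean record. An exponential diastole (the common first choice) flattens
near the cycle end and breaks the wander bound; a dicrotic bump near the
zero-slope fall/diastole junction breaks the low-α guarantee.

Records concatenate per-cycle-jittered periods (default 100 samples ± 5%),
add sinusoidal wander (default 20% amplitude, 10-cycle period, random
phase) and band-limited measurement noise: Gaussian white noise smoothed
with a σ = 3-sample Gaussian kernel and rescaled to the target sd (default
1% of pulse amplitude). Sample-level white noise would make any
forward-difference threshold fire spuriously at realistic rates; acquisition
chains low-pass filter before sampling, so correlated noise is the faithful
model. Ground-truth onsets are the exact concatenation boundaries.

Abnormal kinds map onto the labeling criteria they violate:

| kind | construction | violated criterion |
|---|---|---|
| `truncated_cycle` | 30–75% sub-span starting at/after 20% of the cycle | incomplete cycle |
| `merged_cycles` | 2–5 whole cycles as one segment | more than one cycle |
| `elevated_endpoint` | last 20% raised by 0.6–0.95 amplitude (cosine ramp over [0.8, 0.9], then plateau) | baseline rule, by construction |
| `interference_burst` | Gaussian transient, 1–2× amplitude, at 30–90% of cycle | serious interference |
| `baseline_jump` | ±0.6–1.2 step at 20–80% of cycle | interference / baseline |

Truncations start at/after 20% of the cycle because a truncation boundary is
a spurious derivative zero point, and on this waveform those exist only at
or after the systolic peak — never partway up the upstroke. Labeled corpora
default to 58.2% normal, matching the clinical training prevalence, with
anomaly mix {truncated 0.25, merged 0.25, elevated 0.2, burst 0.2,
jump 0.1} among abnormals; class counts are exact
(`round(n · normal_fraction)`), order is a seeded permutation, and the whole
corpus is a pure function of config + seed.

**What passing tests do and do not show.** The generator reproduces the
coarse single-period morphology the classifier reads (onset level, early
peak, slow systolic decay, quiet end-diastole) and the two anomaly sources,
but not inter-patient morphological diversity, disease-specific waveforms,
sensor transfer functions, or annotator disagreement. Calibration results on
synthetic corpora (accuracy ≈ 0.96–0.98) therefore validate the pipeline's
internal consistency, not clinical performance; the original clinical
metrics are not reproduction targets here.

## Problem sizes and numerical choices

Test and acceptance simulations use: 100 seeded records (6 cycles, periods
40–400 samples) for the segmentation oracle; 20 000 samples for logistic
coefficient recovery (weak penalty 1e-4; recovery within ~2–13% relative
error across seeds, all signs correct); 100 replicates of n = 2000 for RFE
recovery; corpora of n = 1000 for calibration. For the recovery simulations
the four informative features are drawn from pulse-like ranges
(x₁, x₁₄ ∈ U(0, 0.4); x₃, x₄ ∈ U(0.5, 1) in the RFE setting) so both label
classes are well represented. Seeded `numpy` Generators drive all
randomness; every pipeline is bit-reproducible under a fixed seed. Cubic
resampling requires ≥ 4 samples; segments shorter than that raise a
too-short-segment error rather than silently degrading.
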