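# Methods

This note documents the models, conventions and design choices behind
emgkit, in the spirit of a package reference manual. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic EMG model

A recording is the superposition of independent motor-unit action
potential (MUAP) trains plus additive white Gaussian noise, band-limited
by a zero-phase 4th-order Butterworth filter.

**MUAP template.** A MUAP with `n_phases` phases spanning `duration_ms`
is a sum of `n_phases` alternating-sign Gaussian lobes with centres at
(k+1)/(P+1) of the duration and common width D/(4(P+1)). For odd phase
counts the two end lobes carry half magnitude so the signed lobe areas
cancel; the waveform is then rescaled so its peak equals `amplitude_mv`
exactly. Consequences that the tests check: exactly `n_phases − 1` sign
changes, peak equal to the amplitude, and near-zero mean (baseline
return) for two or more phases. A monophasic template (one lobe) cannot
have zero mean; it is the documented exception.

**Firing.** Each unit fires as a renewal process: inter-pulse intervals
are Normal(1/rate, jitter/rate), truncated below at 5 % of the mean
interval so intervals stay positive. The first discharge is uniform on
one mean interval. `firing_jitter` is therefore the coefficient of
variation of the inter-pulse interval.

**Class profiles** (simulator defaults; configurable, and *not* claims
about any clinical dataset — they encode the textbook contrast between
the conditions):

| class      | amplitude (mV) | duration (ms) | phases | units | rate (Hz) |
|------------|----------------|---------------|--------|-------|-----------|
| Normal     | 1.0 ± 0.3      | 9 ± 2         | 2–4    | 12    | 15        |
| Myopathy   | 0.4 ± 0.15     | 5 ± 1.5       | 4–6    | 12    | 20        |
| Neuropathy | 1.6 ± 0.5      | 14 ± 3        | 2–4    | 5     | 12        |

Amplitude/duration draws are truncated normals (> 0). Measurement noise
defaults to 0.05 mV for every class: small enough that the class contrast
dominates, large enough that subband statistics are never degenerate.

**Acquisition.** Defaults: 20 kHz sampling, 5 s duration, 5 Hz–10 kHz
band. The upper band edge sits exactly at Nyquist, where a band-pass is
vacuous; the filter therefore degrades to a high-pass at 5 Hz in that
case. 12-bit quantization is available (`quantize_bits=12`) but off by
default — it is irrelevant to the feature/classifier chain under test.

**What the simulator does not emulate:** volume conduction, needle
position and insertion artefacts, motor-unit recruitment hierarchies,
firing-rate modulation, non-stationarity across a contraction, and
between-subject variability beyond what the per-unit parameter draws
produce. Passing the end-to-end benchmark therefore demonstrates that the
pipeline machinery separates class-structured signals under the stated
generative model — it does not certify clinical performance.

## Framing and storage

Frames are rectangular windows of 2048 samples starting at sample 0 with
no overlap (both configurable); the trailing remainder is discarded.
A 5 s recording at 20 kHz yields ⌊100000/2048⌋ = 48 frames. Frames
inherit their recording's label; nothing downstream relabels. Recordings
are stored as one-sample-per-line text (17 significant digits, exact
float64 round-trip) plus a CSV manifest `recording_id,path,
sampling_rate_hz,label`; unlabelled recordings use the token
`unlabelled`. Feature tables serialize to CSV (label column last; read
back with round-trip float parsing) and ARFF (nominal `label` attribute
listing the three classes).

## Wavelet-packet features

The full dyadic analysis tree is built by recursive single-level DWT
(PyWavelets filter pairs), batched across frames. Terminal nodes are
reported in increasing frequency order: the natural filter-bank order
permuted by the Gray-code rule (children of a node at an odd frequency
position appear reversed). "Adjacent subband" in the ratio feature means
frequency-adjacent under this ordering.

Default configuration: Daubechies-4, level 4, periodized extension,
terminal subbands. With a 2048 frame this gives 16 subbands × 128
coefficients, perfect reconstruction, and exact energy conservation
(Parseval), all asserted by tests at 1e−8 / 1e−10. An `all_nodes` option
exposes all 30 nodes of levels 1–4 (179 features); a `statistics` switch
restricts the statistic set. Reconstruction is implemented for the
periodized mode only, where coefficient lengths determine the length tree
uniquely; other extension modes decompose but refuse to reconstruct.

Statistic conventions, chosen once and logged here: the first feature is
the mean *absolute* coefficient; standard deviation is the population
form (divisor M, no Bessel correction); kurtosis is raw (no −3);
zero-variance subbands define skewness/kurtosis as 0, and a zero
denominator defines the adjacent ratio as 0, both with a logged warning —
classifiers require finite features. Feature columns are deterministic:
five statistics per subband in frequency order, then the 15 ratios.

## Base learners

All learners consume instance weights and expose `predict` plus a `score`
vector (nonnegative, sums to 1, argmax consistent with `predict`). Ties
everywhere break toward the smallest class index, with the classes
ordered Normal < Myopathy < Neuropathy.

**Gain-ratio tree.** Binary splits on continuous features at midpoints
between consecutive distinct sorted values. Candidate splits are all
(feature, threshold) pairs at a node; following the C4.5 heuristic, the
split maximizing gain ratio among candidates whose information gain is at
least the mean candidate gain is selected. Entropies are weighted; trees
are unpruned by default (`max_depth`, `min_leaf` available). Categorical
multiway splits and the MDL numeric-split correction of full C4.5 are
deliberately out of scope: the feature table is wholly continuous.
The **random tree** draws a fresh uniform feature subset (default ⌈√d⌉)
at every node; the **random forest** bags such trees over weighted
bootstrap resamples and votes without weights.

**Naive Bayes** uses per-class, per-feature Gaussians with weighted
moments and a variance floor of 1e−9; a Gaussian event model is the
natural choice for wholly continuous features. **k-NN** stores the
(optionally z-scored) training set and takes the weight-weighted majority
of the k Euclidean-nearest instances. Feature standardization is fitted
on training data only; it defaults ON for k-NN and the scikit-learn
adapter, OFF for trees, forests and naive Bayes (scale-invariant or
scale-robust learners).

## Ensembles

**Bagging**: T independent weighted-bootstrap resamples of size n, equal
votes. A failed member fit skips that round with a warning.

**AdaBoost.M1**: weights start at the dataset weights (sum n). Round t
fits on the current weights (directly if the learner supports weights,
else by weighted resampling), computes the weighted error ε_t; ε_t ≥ 1/2
discards the member and stops, ε_t = 0 accepts it with the capped weight
log(1/β_min), β_min = 1e−10, and stops; otherwise correct instances are
multiplied by β_t = ε_t/(1−ε_t), weights renormalised to sum n, and the
member votes with log(1/β_t). If no round is accepted the committee falls
back to one unweighted base model. The optional `samme` flag adds
log(K−1) to member weights and relaxes the acceptance threshold to the
multiclass chance error; it is off by default (three classes are handled
by plain M1 throughout).

**Wagging** draws random instance weights — continuous-Poisson −log U by
default, or max(0, 1 + N(0, scale)) with zeros floored at 1e−10 — and
renormalises them to sum n.

**MultiBoosting** partitions T rounds into ⌈√T⌉ contiguous sub-committees
of near-equal size (T = 10 → [3, 3, 2, 2]; the larger blocks come first).
Each sub-committee starts from fresh wagging weights; inside it the
AdaBoost update runs, with ε_t ≥ 1/2 or ε_t = 0 ending only that
sub-committee. With one sub-committee and wagging noise disabled the
procedure reduces to AdaBoost.M1 member-by-member (a tested identity);
with T singleton sub-committees it is wagging alone.

## Evaluation protocol

Stratified k-fold CV (default 10): per class, a seeded permutation is
dealt round-robin, so per-fold class counts deviate from proportionality
by at most 1. k = n is treated as leave-one-out (singleton folds);
otherwise a class rarer than k raises an error. Headline metrics come
from the pooled out-of-fold confusion matrix; per-fold accuracies are
reported alongside. Multiclass precision/recall/F and AUC are
prevalence-weighted averages of the one-vs-rest values (the convention of
the common Java data-mining toolkits, so a single number summarises three
classes); AUC uses the Mann–Whitney rank-sum with average ranks, giving
half credit to ties. 0/0 precision or recall is defined as 0 with a
warning; kappa with P_e = 1 (constant truth and prediction) is defined
as 0.

Frame-level stratified CV replicates the common protocol for this task
but lets frames of one recording fall on both sides of a split; a
`grouping="recording"` mode assigns whole recordings to folds for a
leakage-free estimate. The default stays frame-level, and the leakage
caveat stands here rather than being silently "fixed".

## Determinism and seeding

Every stochastic routine takes an integer seed and derives child
generators through `SeedSequence` tagged streams (`derive_seed`), so the
simulate → extract → evaluate chain is a pure function of one global
seed; repeated runs produce byte-identical reports and sample files. The
CLI fans one global seed out to the stages with fixed tags.

## Problem sizes

The packaged benchmark simulates 3 × 17 recordings of 5 s at 20 kHz
(2448 frames of 2048 samples, 95 features) and cross-validates
AdaBoost.M1 (T = 10) over a 25-tree random forest, the single forest on
the same folds, and a k-NN label-permutation control. The permutation
control uses k-NN deliberately: it validates that the CV protocol yields
chance-level pooled accuracy under destroyed label structure, a property
of the protocol rather than of any particular learner, and k-NN evaluates
it in seconds where unpruned forests on permuted labels would grow
O(n)-leaf trees. Committee size T = 10 and 25 trees are defaults chosen
as round, commonly used values for these methods.

## Known limitations

* Synthetic data only; no claim transfers to clinical recordings
  (see the simulator caveats above).
* No pruning, no missing-value handling, no categorical features in the
  native trees.
* ANN/SVM are supported only through the external-estimator adapter.
* No significance testing between classifier configurations; reported
  differences are descriptive.
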