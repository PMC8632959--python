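# Methods

This note records the scientific and numerical choices behind the
package: the models implemented, the parameters that matter, what the
synthetic-data generators do and do not emulate, and the decisions made
where the method family leaves the design open.

## Feature selection

### Filter stage

Features are ranked by two model-free criteria computed against the
binary class label.

*ANOVA F.* The per-feature variance decomposition uses the total sum of
squares about the grand mean, TV = ΣᵢΣⱼ(Yᵢⱼ − Ȳₜ)², so that
TV = BGV + WGV holds as an identity; F = [BGV/(k−1)] / [WGV/(N−k)].
Perfectly separated groups (WGV = 0 < BGV) receive F = +∞ and rank
first; a feature with identical group means gets F = 0.

*Mutual information.* Discrete MI is the plug-in estimate from the
empirical joint table, in bits (log base 2 throughout). Continuous
features are reduced to the discrete case by equal-width binning with 10
bins per margin. Binning was preferred over kernel or k-NN density
estimators because it is deterministic, fast, and adequate for ranking;
the absolute MI value is biased upward at small n, but the *ranking*
across features — all binned identically — is what the filter consumes.
A constant margin occupies one bin and yields MI = 0.

*Union.* The top `k_anova` features by F and the top `k_mi` by MI are
unioned; ties are broken toward the lower feature index so runs are
reproducible. Both k default to ⌈p/2⌉ for p features: aggressive enough
to halve the wrapper's search space, conservative enough that a feature
strong under either criterion survives. Fixed-size top-k sets were
chosen over score thresholds because they behave predictably across
datasets with very different score scales.

### Wrapper stage

The wrapper is a genetic algorithm over boolean masks restricted to the
filter union, hybridized with simulated annealing.

*Fitness.* Fit(x) = f(x) − D when f(x) > D, else 0, where f(x) is the
stratified 5-fold cross-validated accuracy of a chosen classifier on
the masked features and D defaults to the majority-class rate — the
accuracy any constant predictor achieves, so fitness measures genuine
signal. A cache keyed by the mask bits avoids re-training on repeated
masks; with 20-bit unions roughly half of all proposals are cache hits.

*Annealing acceptance.* Proposals are judged on the energy e = 1 − Fit.
A candidate whose energy does not exceed the incumbent's is accepted
with probability 1 (ties accepted, which lets the search drift across
accuracy plateaus); a worse candidate is accepted with probability
exp(−E·Δe/T). The temperature follows T_g = T₀·c^g exactly, with
defaults T₀ = 1, c = 0.95, E = 1.

*Operators and loop.* Tournament selection (size 3), single-point
crossover with probability 0.8, per-bit mutation at 0.02, then a local
search of 10 single-bit-flip proposals per individual judged by the
annealing rule. An all-zero mask is undefined under the fitness, so any
empty offspring is repaired by activating one uniformly chosen union
bit. Elitism (1 individual) re-inserts the all-time best, making the
best fitness non-decreasing; the run stops at 50 generations or after
10 generations without improvement. Population size defaults to 30.
All randomness flows through one seeded generator, so a run is
bit-reproducible from its config.

*Driver classifier.* The wrapper's evaluation classifier defaults to
the RBF SVM. Of the five supported families it gave the most stable
subset rankings in development: its regularized smooth decision
boundary degrades gracefully when noise features are present, so the
fitness landscape is less plateau-ridden than with k-NN or trees, and
the search is pushed toward sparse masks. The driver is configurable.

## Evaluation protocol

Stratified 5-fold cross-validation, shuffled with the protocol seed;
the validation folds partition the sample index set (asserted at every
run). Features are standardized on each training fold and the fitted
transform applied to its validation fold, so no statistics leak across
the split. Classifier defaults: logistic regression (L2, C = 1),
unrestricted decision tree, 5-nearest neighbours, RBF SVM (C = 1),
random forest (100 trees). These are conventional settings, not tuned;
the selector comparison is paired (same folds, same seed) so any
systematic bias cancels.

## EEG front end

*Down-sampling.* Integer-ratio decimation (1000 → 250 Hz by default)
with a zero-phase anti-alias FIR low-pass. Arbitrary resampling is
deliberately unsupported: integer decimation is exact, and the
acquisition/analysis rate pair is fixed in this design.

*Band-pass.* 4th-order Butterworth, 0.5–50 Hz by default, applied
forward-backward (zero phase). The band edges are configurable; 0.5–50
Hz is the conventional EEG analysis band below power-line frequencies.

*Electro-oculogram removal.* Blinks on frontal channels are slow
(~300 ms), high-amplitude transients. Per channel: (i) a scalar
local-level Kalman model (levelₜ = levelₜ₋₁ + w, x = level + v) is
RTS-smoothed; the smoothed level tracks the blink lobe plus baseline
drift and is subtracted. The process/observation variance ratio
(default 10⁻³) sets the tracked bandwidth — roughly 1–2 Hz at 250 Hz —
low enough to leave alpha-band activity untouched, high enough to
absorb most blink energy. (ii) The residual is wavelet-decomposed
(Daubechies-4, level 5) and the approximation band soft-thresholded at
the universal threshold σ√(2 ln n), with σ the robust MAD estimate from
the finest detail band; this suppresses the low-frequency transient
energy the smoother missed. Order (i)→(ii) is a design choice: the
smoother removes the bulk of the artifact so the wavelet stage operates
near its small-residual regime. On blink-free input the chain changes
the signal by under 3% RMS; on planted-blink fixtures it raises the
correlation with the clean reference by ≈ 0.18 (median over 10 seeds).

*Epoching.* Fixed windows with configurable overlap; a trailing partial
window is discarded; zero-overlap epochs concatenate back to the
trimmed input exactly.

## Nonlinear features

Twelve features per channel-epoch (names are stable API): power-
spectrum entropy, binarized Shannon entropy, correlation dimension, K2
entropy, C0 complexity, total power, five relative band powers
(δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz), and spectral peak
frequency. The composition pairs the five complexity measures with the
conventional spectral summary a clinician-facing EEG pipeline reports.

*Power-spectrum entropy* is the Shannon entropy (bits) of the
normalized periodogram, with 0·log 0 ≡ 0; bounded by log₂ of the bin
count. *Binarized Shannon entropy* applies H(x) = −x log₂x −
(1−x) log₂(1−x) to the fraction of samples above the epoch median — the
median was chosen as the binarization threshold because it is scale-
free and makes H ≈ 1 for any symmetric signal, so deviations flag
asymmetry.

*Correlation dimension* is the Grassberger–Procaccia estimator: delay-
embed (default m = 5; τ = first autocorrelation zero crossing, fallback
1; Theiler window = τ to exclude temporally correlated pairs), compute
the correlation integral C(r) over 12 log-spaced radii between the 5th
and 50th percentile of pairwise distances, and take the least-squares
slope of ln C(r) vs ln r. The percentile-based scaling region replaces
the formal r → 0 limit, which finite noisy data cannot approach; the
implementation is vectorized but verified against a naive O(n²) pair
count to 10⁻⁹.

*K2 entropy* is the correlation-entropy estimator
K₂ = (1/τ)·⟨ln[C_m(r)/C_{m+1}(r)]⟩ over the scaling radii, in nats per
sample — the standard finite-data realization of the entropy-rate
limit. It is ≈ 0.02 for a pure sinusoid and ≈ 0.3–0.6 for white noise
at n = 2000.

*C0 complexity* keeps DFT coefficients whose squared magnitude exceeds
the mean squared magnitude, inverts to the "regular" part Y, and
reports ‖X − Y‖²/‖X‖² ∈ [0, 1]. For Gaussian white noise the expected
value is 1 − 2/e ≈ 0.264 (the below-mean tail of the exponential power
distribution carries that energy share), which the tests use as the
reference scale; a tone at an exact DFT frequency gives ≈ 0.

Degenerate inputs (constant signals, zero energy, too few embedded
points) raise a dedicated error naming the offending feature rather
than returning NaN.

## Synthetic data

The generators are pure functions of their spec (seed included) and
return ground truth as metadata, never inside the data.

*Tabular.* Standard-normal features; a chosen subset receives a mean
shift of `effect_size` noise SDs in class 1. This is the simplest
structure that satisfies the filter stage's assumptions (between-group
mean shift, class-independent noise). Default shapes emulate public
benchmark dimensions (hundreds of samples, tens of features, 2
classes). It does not emulate feature correlation, heteroscedasticity,
or label noise — so recovery results bound behaviour on clean,
independent features only.

*EEG.* Sum of sinusoids plus white Gaussian noise, contaminated by
raised-cosine blink pulses (300 ms, amplitude 5× the clean-signal SD,
placed uniformly without overlap, shared across channels as real
frontal blinks are). This captures the spectral concentration and the
transient-artifact structure the preprocessing chain targets; it does
not model 1/f background, non-stationarity, or muscle artifacts, so
denoising results demonstrate artifact suppression, not physiological
fidelity.

*Cohort.* Two arms of `n_per_group` patients; pre scores
N(pre_mean, pre_sd²) clipped to the instrument range; post = pre minus
a Gaussian reduction whose mean is `control_reduction` in the control
arm plus `intervention_effect` in the intervention arm (defaults 27 per
arm, HAMD pre ≈ 24 ± 4, reduction 8 ± 3, effect 6 — magnitudes typical
of a moderately depressed cohort responding to treatment). Scores are
rounded to 0.1 points. Independence of pre score and reduction is a
simplification; regression-to-the-mean effects are not modeled.

## Clinical statistics

Severity bands: SAS/SDS <50 none, 50–59 mild, 60–69 moderate, ≥70
severe; HAMD <8 none, 8–20 mild, (20, 35] mild-to-moderate, >35
severe. The published HAMD banding leaves (34, 35] unassigned; it is
folded into mild-to-moderate so the bands partition the scale. The
reduction-rate banding likewise leaves exactly 25% unassigned; it is
placed in "ineffective" (≤25). Percentages are rounded half-up to two
decimals, matching clinical reporting convention. The χ² test is
Pearson's without continuity correction by default (Yates optional);
the t test is Welch's, which is safe under unequal variances and
equivalent to the pooled test when they are equal.

## Problem sizes and tolerances

The test and acceptance workloads use n = 300 samples / 20 features for
selector recovery (population 30, 40 generations), 10-second 250 Hz
recordings for denoising, and 1000–2000-point reference signals for the
nonlinear estimators — sizes at which every stochastic check has
comfortable margins while a full run stays in the minutes range on one
core. Numerical comparisons use 10⁻⁹ relative tolerance against
independent oracles (two-pass ANOVA, brute-force pair counting, closed
forms) and 3-binomial-SD bands for Monte-Carlo rates.

## Known limitations

- EDF files can be read (via MNE) but EDF export requires MNE's
  optional backend; wide CSV is the tested round-trip format.
- Continuous MI is a binned estimator; its absolute value is upward
  biased at small n (ranking, its only use here, is unaffected).
- The wrapper's fitness is CV accuracy on the same data used for
  selection; reported accuracies are selection-biased upward, as in any
  wrapper method. Held-out evaluation is the caller's responsibility.
- The K2 and correlation-dimension estimators assume stationary epochs;
  epoching must be chosen accordingly.
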