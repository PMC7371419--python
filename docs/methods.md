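# Methods

This note documents the models and procedures implemented in `reactime`, the
assumptions behind them, the parameter choices that matter, what the
synthetic-data generator does and does not emulate, and the numerical
decisions a user auditing results should know about.

## Decoding model

Each "perception model" is a two-class linear discriminant trained on the
sensor vector at a single time sample (no temporal averaging window). With
class means μ₀, μ₁ and pooled within-class covariance S over p sensors, the
weights solve

    [(1 − γ) S + γ ν I] w = μ₀ − μ₁,      ν = tr(S)/p,

i.e. shrinkage toward the identity scaled by the average sensor variance,
with γ = 0.05 by default. The bias puts the decision boundary midway between
the projected class means; the peak-timing statistic is invariant to it. The
signed distance to the hyperplane is evaluated at every test sample and the
sign is flipped for class-1 trials, so positive values always mean evidence
for the trial's correct class.

Cross-validation is 5-fold, stratified by class; class counts are balanced
inside each training fold by randomly dropping majority-class trials. When a
paired test epoch set is supplied (e.g. classifiers trained on one epoch type
and tested on another epoch of the *same* trials), the folds partition the
shared trial indices, so no model is ever evaluated on the test epoch paired
with one of its training trials. Demeaning (subtracting the mean over trials
per sensor and time point) is applied to each full epoch set before fold
splitting; it removes global amplitude differences while leaving the class
difference untouched. It marginally mixes folds through the common mean; we
follow the convention of treating it as global preprocessing, and it is a
visible knob (`apply_demean`).

Multi-subject data are decoded within subject — classifiers never mix
subjects — and the per-subject evidence tensors are reassembled in trial
order.

## Reactivation timing and order inference

For long test windows the signed evidence trace is low-passed at 30 Hz
(zero-phase 4th-order Butterworth, applied forward and backward with
reflection padding; the contract is the cutoff and zero phase, not the
topology). Within-stimulus analyses use no filter: the windows are short and
high-frequency structure is of interest. The reactivation time is the argmax
of the (filtered) trace in the search window, ties broken toward the earliest
sample; it is invariant under strictly increasing transforms of the evidence.
The default peak definition is the signed maximum; an absolute-value variant
would differ only when strong negative evidence exists, and the sign-flip
convention makes the signed maximum the quantity of interest.

The pooled order regression `peak_time ~ train_time` is ordinary least
squares over all (trial, training time) points; the slope sign is the
direction verdict. The rows are not independent: the ~13–19 peak times of one
trial share that trial's reactivation onset, and cross-validated trials of a
subject share classifiers. Plain OLS p-values therefore overstate evidence
(and are reported as such, flagged by `random_structure="none"`); headline
inference uses cluster-robust sandwich standard errors at the coarsest
exchangeable unit — subjects when at least five are present, trials otherwise
— with a t reference on (number of clusters − 1) degrees of freedom. This is
the fast analogue of the mixed models below and behaves correctly under the
shuffled-label null, where we found plain-OLS p-values anti-conservative
(permutation inside cross-validation couples the training-fold and test-fold
label overlaps negatively, deflecting null peaks away from
representation-matched times and biasing the null slope opposite to the
data's true order).

Mixed models: five random-effect structures (none; subject intercept; trial
intercept; subject+trial intercepts; subject intercept+slope) are fitted by
maximum likelihood — not REML, so likelihoods are comparable across fixed
structures — and compared by BIC, computed as −2·llf + k·log(n). The selected
model is the BIC *minimiser*; every candidate's BIC is reported so the
selection is auditable. A candidate that fails to converge is flagged and
excluded, not fatal. A between-subject variant (`subject_level_fit`) averages
peak times over trials within subject × training time first, removing the
within-subject dependence entirely.

The shuffled-label control permutes the class labels (applied to both members
of a paired train/test set), re-runs the entire decode → peak → regression
pipeline, and reports the null fit. Permutation removes stimulus information
while preserving the temporal structure of the data.

Realignment extracts, for every trial and training time, the sensor vector at
that trial's peak time; the time axis of the realigned data is
β₀ + β₁·train_times from the order fit.

## Spectral analysis

The single-frequency time–frequency transform is a complex Morlet wavelet
`exp(−t²/(2s²) + iwt)` on a time vector from −0.5 to 0.5 s in steps of 1/fs,
with w = 2πf₀ and width s = c/f₀ (0.1 s at 10 Hz for c = 1 cycle; an
alternative c/(2πf₀) convention is available). Only 200 central samples are
kept; convolution is centre-aligned and power is the squared magnitude.
Samples within half the support of an edge are boundary-contaminated.

Amplitude spectra use a Hanning taper over the analysis window, an FFT, and
magnitude normalised by the segment length. Coherence at a target frequency
is estimated from one DFT window per trial at the bin nearest f₀, with
cross-spectra averaged over trials (trials are the natural averaging unit
here; no Welch segmentation). The permutation test for "does the reactivation
trace share rhythm with the raw signal beyond what a shuffled classifier
shows" exchanges the true and shuffled traces independently per trial
(default 10 000 permutations) and applies Benjamini–Hochberg FDR across
sensors. Cross-correlation lags are Pearson-normalised (mean-removed,
unit-variance, per-shift overlap scaling); a positive lag means the first
signal leads. Trial-resolved inputs get a percentile bootstrap CI over
trials.

## Phase segmentation and the Recurrence Index

Empirical mode decomposition is implemented in-package: sifting with upper
and lower cubic-spline envelopes through the maxima/minima, extrema mirrored
about the signal boundaries, iterated until the normalised squared change
between sifts falls below 0.2 *and* the interior extrema and zero crossings
differ by at most one (max 50 sifts), modes extracted until the residual has
fewer than two interior extrema. The residual is defined as input minus the
sum of modes, so reconstruction is exact by construction. The mode used for
phase parsing is the one whose interior extrema count is closest to the
expected count (eight for 10 Hz over 400 ms — four cycles), ties toward the
faster mode. Phases are the intervals between consecutive extrema, their
direction the sign of the mode's change across the interval; a
fixed-frequency alternative tiles the window with half-period phases.

The phase-pair slope matrix re-runs the peak search restricted to each test
phase (a peak found in the full window cannot be reused) and regresses peak
time on training time restricted to each train phase, pooling trials across
subjects (a per-subject variant is available). Cells with fewer than two
distinct training times are missing. Because the within-cell training times
are identical across trials, the pooled OLS slope decomposes exactly into a
mean of per-trial contributions; the bootstrap over trials resamples those
contributions, making 10 000 resamples cheap.

The hypothesis matrix is +1 where test and train phase share direction and
−1 otherwise; the Recurrence Index is the elementwise product summed over
non-missing cells. Its raw scale depends on slope units and matrix size, so
only its sign, CI and nulls are interpretable across analyses. The
"neighbour" contrast averages the hypothesis-weighted slopes over the
diagonal band (|i−j| ≤ 1) versus all other cells, each normalised by its
cell count, with a two-sided bootstrap p from the trial-resampled slope
matrices. The negative controls are (a) the shuffled-label pipeline re-run
and (b) order-free data (see below).

## Synthetic data generator

The generator emulates a two-class sensor-level experiment with a known
activation order. Five patterns (pseudo-random i.i.d. normal activations of
20 abstract sensors per class, each pattern–class vector scaled to unit norm)
are activated in a partially overlapping sequence over 60 ms at 300 Hz:
equal-length windows whose supports overlap 50 % with their neighbours
(length 2D/(n+1), step half that) with raised-cosine ramps. Training epochs
add a 20 ms noise-only margin on each side. Test trials are 2 s long and
contain the same sequence slowed 10×, in the same or reversed order, at a
per-trial onset drawn from N(0.8 s, 0.1 or 0.5 s). Onsets keep their exact
Gaussian distribution; sequence activity extending beyond the recorded trial
is truncated. (Clipping the onsets instead piles ~17 % of them onto the
interval edges at SD 0.5, creating an artificial time-locked component that
restores the temporal-generalization ridge the large-jitter regime is
supposed to destroy.) Ten subjects are simulated independently — fresh
patterns and noise per subject.

Ongoing activity is sampled trial-by-trial from a multivariate AR(1) model.
The packaged model (`data/ar1_synthetic_background.json`) is a synthetic
stand-in, not a fit to any recording: lag-1 coefficients with 0.95 diagonal
and weak random coupling rescaled to spectral radius 0.96, innovations with a
low-rank correlation structure, stationary per-sensor SD ≈ 0.25. This gives
the 1/f-like spectral decay characteristic of ongoing electrophysiological
activity; `fit_ar1` (pooled least-squares lag-1 regression) refits the model
on any epochs.

`noise_scale` multiplies the noise relative to the unit-norm patterns. The
default 2.0 is calibrated — once — to reproduce the qualitative dissociation
that motivates the method: at onset SD 0.5 the per-subject accuracy matrices
show no monotone ridge (group-mean Spearman correlation between training time
and the accuracy argmax ≈ ±0.2) while the per-trial peak-timing slope keeps
the true sign at p < 0.01; at onset SD 0.1 the ridge is strong (≈ ±0.9).
At lower noise the ridge survives arbitrary jitter because with 2000 pooled
trials the argmax statistic detects arbitrarily faint accuracy bumps.

Order regressions on simulated data use the *informative training window*
between the first and last pattern-window centres (10–50 ms of the 60 ms
sequence, 13 grid points): samples at the sequence edges fall where every
activation envelope is near zero, so their classifiers see only noise and
their peak times dilute the slope toward zero. Within that window the
envelope geometry maps training time to test time with slope exactly ±10, so
the low-noise slope magnitude recovers the slowdown factor.

A second generator produces the recurrence regime: the pattern *position*
sweeps across the five representations once per half-period of a 10 Hz
alternation, reversing direction each half-period (triangle wave); activation
at fractional positions is a linear blend of the two neighbouring patterns.
Epochs are time-locked. Two controls: `forward` repeats the same-direction
sweep (order information, no reversals — note that grid discretisation
leaves small systematic slope structure, so it is not a perfect RI null),
and `static` holds the position fixed at the middle pattern (decodable
stimulus information, no sequential order) — the clean negative control,
with RI ≈ 0 and a bootstrap CI covering zero. An optional "imagery" set adds
slow reversed single-sweep test trials whose reactivation trace against the
alternating training epochs oscillates at the alternation frequency.

What the generator does **not** emulate: realistic lead fields or sensor
geometry (channels are abstract), trial-to-trial amplitude variability,
non-stationary or oscillatory background noise beyond AR(1), behavioural
structure, or multi-class designs. Passing tests therefore demonstrate that
the *estimators* recover injected structure under realistic noise and jitter,
not that any particular real dataset contains such structure.

## Numerical choices and problem sizes

- Windows are closed intervals snapped inclusively onto the sample grid
  (tolerance 1e-9), so 70–130 ms at 300 Hz contains exactly 19 samples.
- Argmax ties break to the earliest sample; non-finite input data are
  rejected at container construction, not imputed.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; every pipeline report carries a
  manifest (config, stage seeds, versions) sufficient to replay it
  bit-identically.
- Bootstrap CIs are percentile-based with 10 000 resamples by default;
  permutation tests use 10 000 permutations by default and add-one p-value
  smoothing; FDR is Benjamini–Hochberg.
- The test suite and the acceptance script run the full-scale conditions
  (10 subjects × 200 trials × 2 s × 300 Hz) for the order-recovery analyses
  — decoding is linear algebra and takes seconds — and single-subject
  200-trial data for the recurrence analyses; mixed-model recovery runs use
  8 subjects × 20 trials × 5 time points per fit, sizes at which the five
  candidate structures fit in well under a second each.

## Known limitations

- Binary classification only; no multi-class or continuous decoding.
- One reactivation time per (trial, training time): no multi-peak or
  prominence analysis, so a process that reactivates twice within the search
  window is summarised by its stronger peak.
- The EMD is the standard single-realisation sifting algorithm; no ensemble
  averaging (EEMD) or instantaneous-frequency (Hilbert) analysis.
- Cluster-robust inference with few subjects (<5 falls back to trial
  clustering) relies on the trial level being the dominant dependence; with
  very few trials per subject, prefer `subject_level_fit`.
- The recurrence bootstrap resamples trials within the given phase set; it
  does not propagate uncertainty in the EMD phase boundaries themselves
  (the fixed-frequency segmentation sidesteps this).
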