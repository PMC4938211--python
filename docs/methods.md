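# Methods

## Scope and intent

`prepsacc` is an analysis test bed, not a preprocessing suite: it starts
from (simulated or already-preprocessed) voxel time series and event tables
and carries them through GLM estimation, ROI univariate statistics, and
pattern decoding. Motion correction, slice timing, coregistration, spatial
normalization, eye-tracking analysis, and anatomical delineation on real
scans are out of scope.

## Trial timing model

A run is lead-in (15 s), `n_trials` trials, lead-out (15 s). Each trial
contributes exactly three impulse events (0.5 s): a preparation cue
(pro/anti), an execution target (type × direction), and a return-saccade
cue. Preparation intervals are drawn uniformly from {6, 10, 14} s; the
post-saccade hold and the inter-trial interval are integer seconds from a
truncated Poisson on [2, 12] s.

**Delay calibration.** The nominal mean of the delay distribution is 4 s,
but truncating a Poisson(4) to [2, 12] raises its mean to ≈ 4.33 s. The
sampler therefore finds, by Brent root finding on the strictly increasing
map λ ↦ E[X | 2 ≤ X ≤ 12], the rate (λ* ≈ 3.595) whose truncated mean is
exactly 4.0 s. Design efficiency is governed by the realized delays, so the
stated mean is honoured rather than the stated nominal rate.

Run duration is emergent (lead + Σ(preparation + hold + ITI) + trail);
nothing pins it to a particular volume count. Trials are shuffled uniformly
per run; direction is balanced within each saccade type, which requires even
per-type trial counts (odd counts are rejected).

## Hemodynamic model

The impulse response is a difference of gamma densities: a positive lobe
whose mode is `time_to_peak` (shape = peak/dispersion + 1, unit dispersion)
minus an undershoot (gamma shape 16) scaled by 1/6. The cortical default
peaks at 5.0 s; the subcortical variant re-parameterizes only the positive
lobe to peak at 4.5 s, leaving the undershoot unchanged. Both satisfy
h(0) = 0 and are evaluated deterministically; peak times are verified by
dense (1 ms) grid search. The undershoot pulls the realized argmax earlier
by well under 1 ms, which is inside every stated tolerance.

Regressor construction uses a 0.1 s convolution grid — finer than the 0.5 s
impulse, the integer-second delays, and the 1.5 s TR, so no event onset is
quantized away — and each task column is scaled to unit maximum ("scaling to
unity" interpreted as column-max scaling; the unconvolved-peak alternative
differs only by a constant per column). Volume k samples the grid at k·TR.

## Drift and noise

High-pass filtering is projection onto the complement of a DCT-II basis:
the mean plus components k = 1 … 2·cutoff − 1 (frequency k/(2·duration) <
cutoff/duration), cutoff 3 cycles/run by default. Projection is idempotent
and exactly testable against a dense projector, which is why it is preferred
over recursive filtering. In session fits the same basis enters the design
block-diagonally per run, so each run keeps its own baseline and drift.

Simulated noise is i.i.d. Gaussian per volume (optional AR(1), default 0);
drift is a random combination of the sub-cutoff cosine basis with
configurable amplitude, default 0 so that exactness oracles (noiseless
recovery to < 1e-8) are meaningful. A constant baseline (default 100
arbitrary units) makes percent signal change well defined.

## Ground-truth scenarios and calibration

Amplitudes are expressed in units of peak regressor response. Defaults:

| parameter | value | role |
|---|---|---|
| g_prep_pro / g_prep_anti | 0.8 / 1.2 | anti-dominant preparatory gain |
| g_exec_pro / g_exec_anti | 2.0 / 2.4 | execution ≈ twice preparation |
| g_return | 1.0 | return-saccade response |
| pattern_scale | 0.15 | sd of per-voxel pattern modulation |
| noise_sd | 1.0 | volume-wise Gaussian noise |
| lateralization L | 0.0 | no ipsi/contra asymmetry |
| baseline | 100 | percent-signal-change denominator |
| voxels | 30 per hemisphere, 6 participants | 360 pooled features |

`cortex_like` draws independent Gaussian pattern vectors per class and
phase, modulating each gain as g·(1 + s·z(v)); `sc_like` shares one pattern
per phase across classes with averaged gains; `null` zeroes everything.
`pattern_scale` was calibrated once, by forward simulation at the default
design, so that cortex-like decoding sits clearly above the run-stratified
permutation criterion while small voxel samples remain below ceiling (a
rising accuracy curve), and was then frozen. The scale of the synthetic
study (360 pooled voxels vs the 500/200 caps used with real scans) is the
package's own choice to keep replicate-based tests fast; the caps are
configuration fields.

What the generator does *not* emulate: spatial autocorrelation, motion and
spin-history artifacts, physiological noise spectra, behavioral errors, and
between-session variability. Passing tests therefore demonstrate the
correctness and calibration of the analysis chain, not the effect sizes to
be expected from real scanners.

## Univariate analysis

The analysis unit is a hemisphere-ROI instance (6 participants × 2
hemispheres = 12 units; within-unit dof 11 for t and F tests). ROIs come
either from a thresholded execution-vs-baseline t-map intersected with a
template label (the stand-in for manual identification of activation
patches at known anatomical locations) or directly from an anatomical
label, the default for synthetic data since a null scenario has no
activation to threshold. The execution-vs-baseline contrast averages the
four direction-resolved execution regressors against the implicit baseline
(constant + drift).

Normalization: percent signal change = 100·β / baseline, where baseline is
the ROI mean of the per-run constant estimates; each unit is then divided by
its grand mean across conditions and multiplied by the group grand mean.
This mean-preserving rescaling removes between-unit gain (scanner and
vascular differences) without altering condition ratios; operating on
percent signal change rather than raw betas is the implemented choice
(the two differ only by the per-unit baseline factor, which the rescaling
removes anyway).

The 2×2 repeated-measures ANOVA (saccade type × phase) tests each effect
against its effect-by-unit interaction mean square; two-level factors need
no sphericity correction. A factor whose effect sum of squares is
numerically zero is reported as F = 0, p = 1 rather than as the unstable
ratio of two near-zero mean squares. Benjamini–Hochberg is used for FDR
thresholding; paired t-tests are two-sided.

## Decoding analysis

Exemplars are per-run beta vectors from the 5-regressor direction-collapsed
GLM — one GLM per run, so that leave-one-run-out folds are estimated on
disjoint data. Two-stage normalization (participant block to unit RMS, then
each class block to unit RMS) removes participant and class magnitude;
"normalised to 1.0" is implemented as RMS = 1, with max-abs scaling
available in configuration. Cross-participant concatenation joins feature
axes aligned by (run, class), keeping 12 exemplars; stacking exemplars
instead would break fold independence across participants.

The classifier is a linear-kernel SVM with C = 1 (the library default of
the classifier family used in this literature). A test exemplar exactly on
the decision boundary counts as misclassified.

**Permutation scheme.** The default null swaps each run's pro/anti label
pair independently (run-stratified). Free shuffling across all 12 exemplars
is also available, but it unbalances training folds, and the classifier's
majority-class bias then anticorrelates with the held-out fold — the
familiar small-sample artifact that drags the null mean to ≈ 0.46–0.48
rather than chance. Stratified swaps keep every fold balanced, so the null
centres on 0.5 and its 95th percentile is a calibrated criterion. The
stratified assignment space (2^runs, including the identity and the full
reversal, which are decoding-equivalent to the true labeling) makes the
percentile estimate sensitive to permutation count; 500–1000 draws
stabilize it at the one-swap level. On very small exemplar sets a free
shuffle can make a training fold single-class; such assignments are
undefined for leave-one-run-out and are redrawn.

Decoding curves draw `n_repeats` (default 20) random voxel subsets per
sample size and average; the per-size criterion uses fresh subsets with
permuted labels. The p-value-histogram analysis draws a fresh subset and a
fresh permutation per iteration and applies a two-sample t-test between the
6 true-label and 6 permuted-label fold accuracies (p defined as 1 when both
samples are degenerate); clustering below 0.05 indicates pattern
information.

## Reproducibility

Every stochastic operation takes an explicit generator. The pipeline derives
named child streams from one master seed (SeedSequence keyed by a CRC of
the stage name), so streams are order-independent and adding a stage never
perturbs earlier ones; fixed config + seed reproduces every table
byte-identically. Problem sizes in the test suite (shortened 8-trial runs in
unit tests; 6 participants × 6 runs × 60 voxels with 200–500 permutations
in replicate-based checks) are the package's own balance of statistical
resolution against suite turnaround.

## Known limitations

- Gaussian white noise flatters OLS efficiency relative to real fMRI noise;
  AR(1) is available but default-off.
- The functional-ROI route needs visible activation; on null data it
  correctly raises rather than returning an empty region.
- Percent-signal-change normalization assumes a positive baseline; data
  written without ground truth (the NIfTI round trip) reload as measurement
  bundles only.
- The permutation criterion's stratified assignment space is small (2^runs);
  with 6 runs the achievable null p-value is bounded below by 1/64, which is
  adequate for a 5% criterion but not for finer thresholds.
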