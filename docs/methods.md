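# Methods

## Overview

`eegscreen` implements a complete screening pipeline for three-class
discrimination of dementia, mild cognitive impairment (MCI) and healthy
ageing from a single frontal EEG channel (Fp1, 10–20 system), together with
a synthetic cohort generator that provides ground truth for every stage.
Group membership follows the Mini-Mental State Examination (MMSE) rule:
score ≤ 24 → dementia, 25–27 → MCI, ≥ 28 → healthy.

The processing chain per recording is

1. band-pass 1–30 Hz, z-normalize (mean 0, population variance 1);
2. artifact detection by SDW (summation of derivatives within windows) on
   consecutive 2 s windows, with a per-recording robust threshold;
3. cleaning of flagged intervals by ensemble empirical mode decomposition
   (EEMD), rejection of artifact-dominated intrinsic mode functions (IMFs),
   and reconstruction with raised-cosine crossfades;
4. short-time Fourier features: per-second Hann-tapered power spectra,
   averaged and reduced to 45 one-Hz bins (1–45 Hz) normalized to sum to
   one, plus 10 band powers (delta 1–4, theta 4–8, alpha 8–13, alpha1 8–9,
   alpha2 9–11, alpha3 11–13, beta 13–30, beta1 13–20, beta2 20–30, gamma
   30–45 Hz);
5. control-referenced relative power: every feature divided by the healthy
   group mean, so the healthy mean is exactly 1;
6. feature screening with the Kruskal–Wallis rank test over all 55
   candidates, Bonferroni-corrected (Benjamini–Hochberg FDR available), at
   the 5 % level;
7. class balancing with SMOTE (k = 5 neighbours) and classification with an
   RBF-kernel SVM under stratified tenfold cross-validation.

## The synthetic cohort generator

A recording is a weighted mixture of band-limited Gaussian noise sources
(4th-order Butterworth-filtered white noise per canonical band, zero-phase)
plus a 1/f background produced by spectral shaping, scaled to a target RMS.
Amplitude units are arbitrary because the pipeline z-normalizes.  Per-group
spectral profiles set the band weights; each subject additionally draws
lognormal multipliers (SD 0.2 on the log scale) on its band weights, so
groups form overlapping distributions rather than point clusters — without
this, any classifier separates the groups perfectly and permutation nulls
behave pathologically.  The 0.2 figure is a typical inter-subject
coefficient of variation of relative band power and was fixed once.

Two directions of group contrast ship as presets, because the literature on
low-frequency changes in dementia is not unanimous: `slowing` (patients show
elevated delta/theta and suppressed alpha — the classical EEG-slowing
picture; the default) and `reversed` (controls show the elevated delta).
A third preset, `separated_profiles`, applies deliberately large (~2×)
band-share shifts and exists for pipeline validation, where a cohort that a
competent classifier *should* separate is needed.

Artifacts are injected with an exact ground-truth mask: blinks are smooth
unipolar raised-cosine bumps (0.3 s, default peak 10× the clean RMS), EMG
events are band-limited bursts (15–45 Hz) under the same envelope, and line
noise is a continuous sinusoid (not maskable by intervals, hence excluded
from the mask).  The standard contamination benchmark uses 60 s recordings
with Poisson blinks at 3 events/min — sparse contamination of closed-eye
rest, leaving most windows clean so the robust threshold has a sound
baseline.

What the generator does **not** emulate: non-stationarity (drowsiness,
alpha blocking), non-Gaussian waveform shape, device-specific transfer
functions, electrode drift, and real blink morphology (which has a faster
rise than a raised cosine).  Passing tests therefore demonstrate internal
correctness and statistical behaviour of the pipeline, not clinical
performance on real recordings.

## Artifact detection: the SDW operating point

The SDW score of a window is its total variation, Σ|x[i+1] − x[i]|.  (The
literal signed sum telescopes to last-minus-first and cannot detect bursts,
so the absolute-valued reading is the only usable one.)  The threshold is
median + k·MAD of the recording's own window scores; the default k = 2 was
calibrated to the false-positive budget alone: it is the largest
sensitivity whose clean-window false-flag rate stays below 0.1 on the
benchmark (measured ≈ 0.06–0.08).

A hard ceiling is worth stating plainly.  A smooth bump of peak amplitude A
adds at most ~2A to a window's total variation, and derivative masking by
the background reduces this to ~A for the raised-cosine shape.  The
within-recording spread of clean-window scores is ~6–9 (z-units) for any
realistic background at 512 Hz, so a 10×-RMS blink shifts its window's
score by only ~1–2 standard deviations.  Event recall at a ≤ 0.1
false-flag rate is therefore bounded around 0.3–0.8 depending on blink
sharpness, and the benchmark reports ~0.33 for raised-cosine blinks.  This
is a property of the total-variation statistic with 2 s windows, not of the
implementation; detectors sensitive to amplitude (not slope) would not
share it.

## EEMD and mode rejection

EMD sifts with cubic-spline envelopes through strict local extrema,
mirroring two extrema beyond each end.  A sift stops when the Cauchy
criterion Σ(h_prev − h)²/Σh_prev² < 0.2 is met *and* the candidate
satisfies the IMF count property (extrema and zero crossings differ by at
most one), or after 12 sifts; extraction stops when the residual has fewer
than three interior extrema or after 10 IMFs.  The residual is input minus
extracted modes, so completeness is exact by construction.

EEMD averages the modes of noise-perturbed copies (noise SD 0.2× segment
SD, default ensemble 100; validation runs use 50).  Noise realizations are
used in ± pairs, so the ensemble-mean perturbation is exactly zero and the
averaged decomposition reproduces the input to machine precision — the
completeness invariant then needs no ensemble-size-dependent tolerance.
Members with fewer modes are zero-padded to the deepest member before
averaging.

Rejection scores each IMF by its maximum-over-lags biased normalized
cross-correlation, either against the other IMFs of the decomposition
(mean over them; mode `between`) or against the original segment
(mode `vs_original`); scores above 0.5 mark noise, and the residual is
never rejected.  The pipeline default is `vs_original`: in a flagged window
the artifact dominates the segment, so the artifact-carrying modes are
precisely the ones that correlate strongly with it (measured 0.7–0.9,
versus ≤ 0.35 for all between-IMF means, which reject nothing at 0.5).
Cleaning a *correctly* flagged window reduces in-interval RMS error against
ground truth by roughly 3×; cleaning a falsely flagged window strips the
dominant rhythm and adds error, which is why the detector's false-flag
budget matters.

## Spectral features

Windows are 1 s, non-overlapping, Hann-tapered (boxcar available for tonal
tests); the one-sided periodogram is scaled so bins sum to the tapered
window's mean square (Parseval).  With 1 s windows, bin index equals
frequency in Hz.  Band edges are half-open [low, high) — a shared printed
edge belongs to the upper band — except gamma, closed at 45 Hz; with 1 Hz
bins, delta = {1,2,3}, alpha1 = {8}, alpha2 = {9,10}, alpha3 = {11,12},
gamma = {30..45}.  Band power is the mean of constituent bins.  Bin
features are normalized to sum to one per recording.  Note the deliberate
asymmetry inherited from the analysis being reproduced: the preprocessing
band-limit is 1–30 Hz while features extend to 45 Hz, so gamma bins sit in
the filter's stopband; `RunConfig.bandpass_high_hz = 45` gives an
internally consistent variant.

Relative power divides all subjects' features by the healthy-group mean;
the healthy post-scaling mean is exactly 1 by construction, and an injected
1.5× delta-share elevation is recovered as 1.50 ± 0.01 at n = 30/group
(the recovery experiment disables the 1/f background, whose leakage into
the delta bins would otherwise dilute the injected ratio).

## Statistics and classification

Kruskal–Wallis uses joint ranks with tie correction and the χ² reference
distribution (k − 1 df); the fully tied case is defined as H = 0.  The
Bonferroni family is all 55 candidates.  Pairwise Mann–Whitney post-hocs
(Bonferroni over the 3 pairs) are reported for interpretation only.

SMOTE grows every minority class to the majority count; each synthetic
sample is a uniform interpolation between a minority sample and one of its
5 nearest same-class neighbours.  The SVM uses an RBF kernel with C = 1 and
`gamma = "scale"` (1/(d·Var X)) — hyperparameters are deliberately not
tuned — with features standardized by training-fold statistics, since RBF
kernels are scale-sensitive.  Sensitivity and specificity are macro
one-vs-rest means over classes present in the truth.

Two cross-validation protocols are exposed because their contrast is
informative: `safe` re-fits selection and SMOTE inside each training fold;
`global` applies both to the full dataset before splitting, which leaks
held-out information and reproduces the familiar pattern of near-perfect
training metrics with optimistic test metrics.  `safe` is the default and
the only protocol whose test metrics estimate generalization.

For permutation-null validation the cohort is balanced (40/40/40): under
label permutation expected accuracy is Σ_c p_c q_c, which equals 1/3
independently of the classifier's prediction distribution q only when the
class priors p are uniform.  With imbalanced truth, a classifier that
predicts the locally dominant class scores ~0.6 on permuted labels — a
property of the null, not evidence of leakage.

## Determinism and numerics

All randomness flows from explicit seeds through `numpy.random.SeedSequence`
(per-subject, per-stage and per-interval children; all below 2³¹).  Fixed
iteration order over bands makes generation independent of dict ordering.
Degenerate inputs fail loudly: constant signals cannot be z-normalized,
all-zero spectra cannot be sum-normalized, zero reference means abort
relative power with the offending feature named.  Validation problem sizes
(e.g. 256 Hz / 40–60 s cohorts, ensemble 50) are chosen so the full
validation battery completes in a few minutes on one core while leaving
every statistical conclusion unchanged at the study's native 512 Hz / 100 s
geometry, which the geometry checks exercise directly.

## Known limitations

- The SDW recall ceiling for smooth low-slope artifacts (analysis above).
- EEMD cleaning assumes flagged windows are truly contaminated; false
  flags trade signal fidelity for robustness.
- The generator's stationary Gaussian model understates the richness of
  real EEG; classification results on synthetic cohorts are upper bounds
  contingent on the chosen profile separation.
- Single channel only; no topographic or connectivity information.
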