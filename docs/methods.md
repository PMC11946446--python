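# Methods

This note documents the models, numerical choices and limitations of the
`ledgaze` pipeline: what is simulated, how the two classification stages are
computed, and what the packaged tests do and do not demonstrate.

## Synthetic cohort model

No public recordings exist for this paradigm, so the package generates its
own cohort with the statistical structure the analysis assumes. Each
recording is 16 s at 256 Hz on the 14-channel 10/20 montage
(AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4) and is a sum of
three components.

**Background EEG.** Gaussian noise shaped to a `1/f^1.5` power spectrum plus
a white floor (10 % of the low-frequency spectral weight), scaled to a
per-channel standard deviation of `noise_amp_uv = 15 µV`. This produces
realistic monotonically decaying spectra with controllable SNR. It does
*not* contain an alpha peak, sleep spindles, line noise or non-stationary
drifts; in particular the alpha-band prominence of resting EEG is absent,
so band-amplitude profiles are only order-of-magnitude realistic.

**EOG artifact.** The eyes track the ball sinusoidally, completing one
cycle per second; both gaze axes move in phase so the extrema reach the
trajectory's peak angles (horizontal ±14.2°, vertical ±8.1°, from a
61 × 34 cm screen viewed at 120 cm: full gaze angles
2·arctan(extent/2/distance) = 28.5° and 16.1°). The corneoretinal dipole
(cornea positive) projects the angle series onto the montage: horizontal
gaze drives right-frontal electrodes (F8, AF4) with sign opposite to
left-frontal ones (AF3, F7); vertical gaze drives all four frontal
electrodes with a common sign; every other channel receives the same
pattern attenuated to 10 % (leakage). The projected series is scaled by
`eog_gain_uv_per_deg = 10 µV/°` (≈140 µV deflections at the horizontal
extrema, the magnitude range of real saccadic artifacts) and convolved with
a 50 ms Hann kernel so deflection edges have saccade-like rise times. Real
saccades are ballistic (step-like with overshoot) rather than sinusoidal;
blink artifacts and electrode drift are deliberately not modelled.

**SSVEP.** LED-on recordings add a 7 Hz sinusoid with a 14 Hz harmonic at
relative weight 0.25 and random (seeded) phases, occupying the 10 s task
window. The response is strongest on the occipital channels (weight 1.0);
a reduced frontal weight of 0.4 is injected so that the frontal-channel
gate is exercisable as published — physiologically SSVEP is occipital, and
this weight is a modelling device, not a physiological claim. The amplitude
default `ssvep_amp_uv = 20 µV` was fixed by a one-time calibration: at
5 µV the gate operates around 75 % accuracy, at 10 µV around 96 %, and at
20 µV near ceiling; 20 µV puts the default conditions in the high-accuracy
regime the paradigm reports while zero amplitude demonstrably reduces the
gate to chance.

**Cohort structure.** 10 subjects × (4 trajectories × 2 LED conditions ×
10 repetitions) = 800 recordings. Per-subject multiplicative jitter
(uniform ±20 %, seeded) on the EOG gain, SSVEP amplitude and noise amplitude
makes per-subject evaluation non-degenerate. Identical configuration and
seed give bit-identical recordings; the cohort driver draws per-recording
seeds from one master generator.

Beep pads carry background noise only — they are removed by trimming before
any analysis, so their content is irrelevant by construction.

## Preprocessing

Trimming removes the 3 s pads (4096 → 2560 samples). Segmentation cuts the
10 s task block into five 3 s windows. Five windows with the often-quoted
"1 s overlap" cannot fit in 10 s (they would span 11 s); the window *count*
drives every downstream number (200 illuminated segments per subject), so
the package honors the count and uses equally spaced starts
{0, 448, 896, 1344, 1792} samples — a 1.75 s hop, i.e. 1.25 s overlap.

Filtering is per segment, fifth-order Butterworth, applied as second-order
sections: the stage-1 path is causal (single-pass) 1–15 Hz, the stage-2
path zero-phase (forward–backward) 1–45 Hz. Both are configurable. Note the
1 Hz corner has a transient of roughly a second per side; tests of filter
properties therefore assess steady-state sections. Z-scoring maps
zero-variance input to zeros (with a warning) instead of raising, so
degenerate synthetic fixtures cannot abort a batch run.

## Spectral features

Welch PSD: Hamming window of 637 samples, overlap 636, no zero padding
(nfft = 637, so the frequency resolution 256/637 ≈ 0.402 Hz is the window's
own), no detrending, one-sided density scaling. On a 768-sample segment
this averages 132 heavily overlapped periodograms; the overlap means the
effective number of independent averages is close to one, so single-segment
PSDs are noisy — a property, not a bug, of the configuration.

Bands are half-open `[lo, hi)` so the touching edges (4–8 vs 8–13 Hz)
assign each bin exactly once; gamma closes at 45 Hz inclusive. Per band:

- mean, variance, skewness, **excess** kurtosis of the PSD values
  (zero-variance slices map skewness/kurtosis to 0);
- trapezoidal band power (composite trapezoid over the bin grid);
- spectral entropy: Shannon entropy (natural log) of the slice normalized
  to a probability vector — scale-invariant;
- Hjorth mobility and complexity computed **on the PSD value sequence**
  (first/second difference-quotient ratios). Hjorth parameters are
  classically time-domain quantities; applying them to the band's PSD
  sequence follows the stated feature-extraction order of the paradigm
  (all eight statistics per identified frequency band of the PSD).

Feature ids are 1-based, channel-major (AF3, F7, F8, AF4), band-major
(delta → gamma), statistic-minor in the order (kurtosis, mean, skewness,
trapz, entropy, variance, mobility, complexity):
`id = 40·(channel−1) + 8·(band−1) + statistic`. This is the only order
consistent with the worked ids (42 = F7 delta mean, 53 = F7 theta entropy,
82/83 = F8 delta mean/skewness, 92/93 = F8 theta trapz/entropy), which the
tests verify by round-trip arithmetic.

## Stage 1: the LED gate

The gate feature is `z' = trapz(6–8 Hz) / trapz(1–10 Hz)` per frontal
channel, after the causal 1–15 Hz filter. Because the numerator band is a
subset of the denominator band, `z' ≤ 1` for every non-negative spectrum
and is invariant under global amplitude scaling. (Descriptions of the
illuminated ratio being "greater than 1" are not realizable under this
formula; the implementation keeps the literal ratio and lets the classifier
learn the threshold — separation, not the absolute level, is what matters.)
Gate decisions are per segment; no cross-window voting is applied by
default, keeping segment counts interpretable.

## Stage 2 and the cascade

One-way ANOVA F per feature is computed from the explicit between/within
sum-of-squares decomposition, `F = [SSB/(k−1)] / [SSW/(N−k)]`; features
with zero within-group variance are skipped (NaN) with a warning. The
packaged consensus set is fixed a priori (the 16 ids above); adaptive
ranking utilities (`anova_rank`, `top_k_curve`, `consensus_features`) are
provided for exploration and, when used inside an evaluation, should be fit
on training folds to avoid selection leakage.

Cascade evaluation links the stages through a single stratified 75/25
split per repeat (stratified jointly on LED condition × trajectory,
10 repeats): the gate trains on the training fold; the trajectory
classifier trains on the fold's illuminated segments; on the test fold the
gate fires first, stage 2 predicts only segments declared illuminated and
is scored on the correctly gated ones. Overall system accuracy divides
stage-2 correct predictions by *all* segments the gate declared illuminated
— gate false alarms therefore lower it below stage-2 accuracy, and the two
coincide exactly when the gate is perfect.

Classifiers are standard library implementations with seeded determinism:
random forest (100 trees), SVM with RBF kernel, LDA, and kNN with
k = ⌊√n_train⌋ rounded down to odd. Scale-sensitive learners (SVM, kNN,
LDA) see z-scored features via a standardizer fit on the training fold;
the forest consumes raw features.

ITR uses K = 4 and T = 3 s (one analysis segment per selection; this is the
only T for which perfect accuracy yields the reference 40 bits/min). The
p = 1 and p = 0 endpoints are computed as analytic limits, never as
0·log 0. Cohort-level ITR is the mean of per-subject ITRs (each from that
subject's averaged accuracy); note that the ITR of the pooled accuracy is a
different number because the formula is nonlinear.

## Channel ranking

Channels are ranked by single-channel accuracy using each channel's own 40
features. The score is the mean of two task accuracies — the binary LED
gate on all segments and the four-class trajectory discrimination on
illuminated segments — because those are the two jobs the cascade needs a
channel for. On the synthetic cohort a pure gate score would favor the
occipital channels (where the simulated SSVEP is strongest), while the
trajectory task isolates the EOG-carrying frontal channels; the combined
score reproduces the frontal top-four finding the paradigm reports.

## Problem sizes in the packaged tests

Unit and property tests run on small cohorts (1–2 subjects, 1–3
repetitions). The study-scale checks use the full default cohort
(10 subjects × 10 repetitions, seed 0) for gate and trajectory parameter
recovery, a 2 × 3 zero-amplitude cohort for the chance-band control, and
the first three subjects (full 14-channel feature bank, 3 holdout repeats)
for channel ranking — sizes chosen to exercise subject heterogeneity while
keeping a full run in a few minutes on one CPU.

## What passing tests show — and what they do not

The synthetic generator demonstrates that the pipeline's machinery is
correct and that, under the stated signal model, the cascade recovers the
planted structure (gate ≥ 95 % at the calibrated SSVEP amplitude, chance at
zero amplitude; trajectory accuracy ≥ 85 % with the 16-feature consensus
set; frontal channels top-ranked). It does not validate the paradigm on
real EEG: real SSVEP amplitudes, saccade morphology, artifact diversity
(blinks, EMG), inter-session variability and electrode non-stationarity are
outside the model, and headline accuracies obtained on synthetic data say
nothing quantitative about human recordings.

## Known limitations

- Sinusoidal (not ballistic) gaze kinematics; no blinks, no smooth-pursuit
  catch-up saccades.
- No alpha peak or line noise in the background spectrum.
- Frontal SSVEP weight is a device to make the published frontal gate
  exercisable, not a physiological statement.
- The cascade's stage-2 training set excludes gate-rejected illuminated
  segments only at test time; training always uses the true illuminated
  fold (the deployed system would train on curated data anyway).
- Per-subject ITRs are derived from averaged accuracies; alternative
  per-repetition averaging conventions give values that differ by a few
  tenths of a bit/min.
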