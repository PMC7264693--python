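# Methods

This note documents the models, algorithms and numerical choices behind
`olferp`, and what its synthetic test bed does and does not establish.

## The task and its design

The pipeline models a bimodal categorization experiment: on every trial
an odor and a picture (lemon, pear, lavender or lilac — two fruits, two
flowers) are presented together, and after a variable 1000–2000 ms delay
an auditory tone instructs the participant to categorize either the odor
(olfactory decision) or the picture (visual decision) as fruit or
flower. Half the trials are congruent (odor and picture denote the same
object), half incongruent (objects from different categories). The full
factorial crosses congruence × target modality × target category × the
two exemplars per category, with eight repetitions, yielding 128 trials
over four blocks; a 16-trial training block (one trial per cell) carries
a modality-cue display flag. Incongruent targets co-occur with each of
the two cross-category distractors equally often, which requires an even
repetition count. Delays are drawn balanced over the six 200-ms steps
within each congruence × modality group (the protocol only says the
delay varied randomly; balancing where divisibility allows removes a
nuisance confound without changing the marginal distribution). The four
tone-meaning × button-assignment combinations are counterbalanced
round-robin over participants. All randomization is seeded and the seed
is stored in the output table.

Stimulus geometry uses the standard visual-angle formula
θ = 2·arctan(extent / 2·distance); the published picture sizes (10.5 cm
high, 5.5/8 cm wide at 1 m) reproduce 6.01°, 3.15° and 4.58°.

## Behavioral models

Reaction times are modelled on the natural-log scale and accuracy on the
log-odds scale, both with fixed effects for congruence, modality, their
interaction, object category, sex, trial number, delay and a perceptual
similarity index; crossed random intercepts for participant and item
(the 12 odor–picture pairings); and a by-participant random slope for
trial. Binary factors are effect-coded through centering (±0.5 when
balanced), continuous covariates are centred and divided by two standard
deviations, making coefficients comparable across predictor types. The
simple effect of modality within one congruence level uses the dummy
scheme with the olfactory cell of that level as reference, so the
`visual-<level>` coefficient is the within-level contrast; on noiseless
data this is exactly `modality + interaction/2` (or `− interaction/2`
within congruent), an identity the tests verify.

Estimation is by REML (statsmodels `MixedLM`, the crossed factors
expressed as variance components of a single all-encompassing group) for
linear outcomes and by the variational-Bayes fit of
`BinomialBayesMixedGLM` for logistic outcomes, with a deterministic
start vector so fits are reproducible. The backend contract is point
estimate, SE, 95% interval and a two-sided p per term; the p-value is
the frequentist analogue of a doubled posterior tail probability. The
weak normal prior of the VB fit doubles as the ridge guard against
quasi-separation. If the full random structure fails to converge the
fitter falls back to a reduced structure (dropping the trial slope, then
the item intercept) and records the fallback in the fit's notes.

The similarity index z-scores all of a participant's between-category
similarity ratings jointly (so it is invariant to affine transforms of
an individual's scale use) and averages the four standardized ratings
per cue stimulus × modality (two competitor stimuli × two repetitions).
Standardization pools both modalities' ratings within a participant.
A zero-variance participant contributes indices of 0, with a log notice.

## The synthetic generator

The generator is the ground truth against which every downstream stage
is validated. Its defaults are the study conditions:

- **Log-RT fixed effects** equal the published mixed-model estimates
  (congruence 0.45, modality 0.04, interaction 0.06, trial −0.35, delay
  0.02, category 0.02, sex 0.14, similarity 0.01). The intercept is not
  taken from the published table: it is calibrated in closed form from
  lognormal moments so that the analytic mean RT difference between
  visual-incongruent and olfactory-incongruent trials is exactly 70 ms,
  the study's headline behavioral asymmetry (the published intercept is
  mutually inconsistent with that gap given the 0.07 simple effect).
  Random-effect SDs (participant 0.20, item 0.05, trial slope 0.05,
  residual 0.25 log units) are typical magnitudes for RT mixed models;
  the published table does not report them.
- **Accuracy logits** equal the published estimates (intercept 3.68,
  congruence −1.34, modality 0.58, interaction −0.8, …), with
  participant/item/slope SDs of 1.0/0.2/0.3 — large enough that a
  realistic minority of simulated participants falls below the 75%
  exclusion threshold, as in the study sample.
- **ERP structure**: every trial carries a common auditory evoked kernel
  (N1–P2 fronto-central complex plus a modest domain-general
  centro-parietal P3). Incongruent trials add (i) a centro-frontal P300
  bump spanning 320–580 ms, scaled so the ROI-window mean difference is
  0.71 µV, independent of modality, and (ii) a centro-occipital positive
  slow wave whose peak and extent depend on the decision modality:
  olfactory 652 ms within 600–700 ms, visual 683 ms within 600–900 ms.
  All bumps are raised cosines. The visual slow wave is a sum of two
  raised cosines — the peak bump (half-width 83 ms) plus a half-
  amplitude late bump filling the extent out to 900 ms — because a
  single flat-topped asymmetric bump makes the grand-average peak
  latency ill-determined under noise, whereas the composite keeps a
  sharp, stable maximum at 683 ms while reproducing the three-window
  effect cascade (600–700 ms in both modalities; 700–900 ms visual
  only). One published passage reports later slow-wave peaks (738/673
  ms) than the primary results section (683/652 ms); the generator
  follows the primary values and this discrepancy is simply noted here.
- **Amplitude–RT coupling**: a trial-level latent "attention" variable
  z ~ N(0,1) raises P300 gain by a per-condition slope (0, 0, 1, 2 µV/SD
  for olfactory/visual congruent and olfactory/visual incongruent) and
  lowers log RT by 0.1·z, producing the negative single-trial
  P300-amplitude–RT association confined to incongruent trials and
  strongest for visual-incongruent decisions. The regression slopes this
  induces are data-dependent; only their sign and ordering are design
  targets.
- **Noise**: spatially correlated 1/f + white noise (exponent 1, white
  fraction 0.3, 15 µV per-sample SD — typical for 0.2–40 Hz scalp EEG),
  mixed over channels through the Cholesky factor of a Gaussian
  angular-distance kernel (scale 0.6 rad) with unit channel variances.
- **Continuous recordings** lay trials out sequentially (sniff cue,
  picture +400 ms, tone after the 1.5 s stimulus plus its delay,
  response after the trial's RT) with four markers per trial, add
  raised-cosine blinks (250 µV on VEOG, propagated to anterior channels
  by a Gaussian falloff from Fpz, 12/min) and corrupt a configurable
  number of channels (flat, noisy, or drifting "disconnected"). With
  blinks and corruption disabled, epoching a continuous recording
  reproduces the epoch generator bit for bit — the round-trip the tests
  rely on.

What the generator does *not* emulate: dipolar source topographies and
volume conduction, saccades and muscle artifact, line noise, drifts in
electrode impedance, non-stationary noise, and any real variability in
component latency across participants. Passing tests therefore show
that the pipeline recovers known effects embedded in realistic noise —
not that it would behave identically on human data.

## Preprocessing

The chain runs filter → resample → bad-channel detection →
interpolation → average reference → ocular correction → epoching →
baseline correction → epoch rejection → participant exclusion.

- Band-pass 0.2–40 Hz, zero-phase Hamming-windowed FIR with the
  high-pass transition placed so the −6 dB cutoff sits at 0.1 Hz;
  resampling to 512 Hz by polyphase filtering with event-sample
  rescaling.
- Bad channels: (a) peak-to-peak above 500 µV in more than half of the
  non-overlapping 1-s windows (the protocol's printed "500 mV" is read
  as µV — scalp EEG never reaches millivolts — and the threshold is
  configurable); (b) correlation below 0.75 with a robust estimate,
  implemented as the per-sample inverse-distance-weighted median of the
  16 nearest channels, summarized as the median over 1-s windows of the
  windowed correlations; (c) SNR — band power 1–40 Hz over residual
  power above 40 Hz, in dB — deviating more than 4 SD (two-sided) from
  the across-channel mean. The SNR criterion presumes broadband input,
  so the pipeline detects bad channels after the high-pass but treats
  the 40 Hz low-pass as part of the same filter stage; on already
  low-passed data the criterion degrades gracefully (residual power is
  uniformly tiny, deviations remain comparable).
- Interpolation: spherical splines (order m=4, 7-term Legendre
  truncation, regularization 1e−5 — standard Perrin parameters), solved
  with an explicit constant term so constants are reproduced exactly.
- Average reference: plain per-sample mean subtraction over the 64 EEG
  channels; EOG channels are excluded. Rank bookkeeping is documented,
  not enforced.
- Ocular correction: per-channel least-squares regression of the EOG
  channels onto the EEG, estimated on the top decile of 1-s windows by
  EOG variance (where blinks dominate) and subtracted everywhere.
  All-zero EOG is a logged no-op. This regression substitutes a simple,
  fully deterministic method for component-based ocular rejection;
  component decomposition is out of scope.
- Epochs: −200…1000 ms around the target tone (t=0 at the event sample;
  615 samples at 512 Hz), baseline-corrected by the mean of the 200 ms
  pre-stimulus window (windows half-open [t0, t1)). Rejection removes
  epochs with any-channel peak-to-peak above 120 µV, per-channel
  peak-to-peak beyond 6 SD of that channel's across-epoch mean, four or
  more channels beyond 4 SD, or trial RTs outside 200–5000 ms; the
  "amplitude difference" statistic is peak-to-peak (max − min), and
  zero-variance channels skip the SD criteria with a warning. Every
  removal is logged with its criterion; surviving + removed = input.
- Participants are excluded below 75% accuracy within either congruence
  condition, or with fewer than 15 surviving epochs in any
  congruence × modality cell (15 itself survives).

## Cluster-based permutation test

Paired condition contrasts on subject-average channels × time data:
one-sample t of the difference at every location; locations with |t| > 2
are grouped into positive and negative clusters under spatial adjacency
(angular distance below 0.55 rad, giving a mean sensor degree of ~5 on
the 64-channel montage; the neighborhood definition is exposed in
config) plus temporal contiguity; each cluster is scored by its summed
t ("mass"). The null distribution of the largest positive and smallest
negative mass is built by sign-flipping the paired differences within
random subject subsets — all 2^n flips are enumerated when n ≤ 12
(sign flips only move the mean, so the per-location sum of squares is
reused across permutations). Because both polarities are searched,
each cluster's |mass| is tested against the per-permutation most
extreme mass of either polarity (the two-sided max-statistic
reference): testing each polarity against its own one-sided null at α
would double the two-sided family-wise error to ~2α, which simulation
confirms. Cluster p-values use the add-one estimate
p = (1 + #{null at least as extreme}) / (1 + P), which is valid (never
anti-conservative) for both the Monte-Carlo and the enumerated null.
Zero-variance locations receive a ±1e6 sentinel t, participate in
connectivity, and are excluded from mass sums. Defaults: threshold 2,
α = 0.05, 2000 permutations, mandatory seed.

The validated property is family-wise error control: over 200 pure-noise
simulations the significant-cluster rate at α = 0.05 stays within the
binomial 95% band [0.02, 0.09], Monte-Carlo p-values agree with
exhaustive enumeration to within 0.02 at n = 8, and cluster formation
equals a brute-force breadth-first search on toy grids (and MNE's
implementation on matched inputs). The particular clusters a given
dataset produces are data-dependent and are not reproduction targets.

## Single-trial ROI models

Mean amplitudes are extracted per trial over the centro-frontal ROI
(AF3, AFz, AF4, F1, Fz, F2, FC1, FCz, FC2) in the 320–580 ms P300
window and over the centro-occipital ROI (P4, P2, Pz, P1, P3, PO8, PO4,
POz, PO3, PO7, O2, Oz, O1 — the conventional label includes parietal
sites and is kept verbatim) in the 600–700, 700–800 and 800–900 ms
slow-wave windows. Amplitude models mirror the behavioral models.
The amplitude–RT model drops the global intercept and regresses
amplitude on the four condition indicators plus condition ×
standardized-log-RT interactions, so each slope tests the
within-condition amplitude–RT association; it is fitted on correct,
in-bounds trials.

Grand-average peak latency is measured after zero-phase 8 Hz Butterworth
smoothing (standard practice for latency estimation on noisy averages)
by the argmax within the 600–900 ms window; validation averages the
grand-average difference waveform over a few seeded generator
replicates before picking the peak, because a single 30-participant
grand average leaves the late shoulder of the slow wave within noise of
its maximum.

## Problem sizes and reproducibility

Simulation scales used by the validation suite and the acceptance
script are design choices balancing Monte-Carlo precision against
runtime on a single core: behavioral recovery uses 100 replicates of 35
participants × 128 trials (Monte-Carlo SE ≈ 0.002 on the RT congruence
coefficient); the RT asymmetry uses 50 replicates; the slow-wave
latency uses 30 participants and 3 replicate-averaged waveforms; the
family-wise-error check uses 200 null simulations of 8 subjects ×
8 channels × 30 samples with exact enumeration. All randomness flows
from explicit integer seeds through named child streams, so every
stage — including the variational-Bayes fits — is bit-reproducible.

## Known limitations

- The logistic VB posterior SD slightly understates frequentist SEs in
  small samples; intervals are calibrated in the tested regimes but are
  not exact.
- The EDF writer targets the plain 16-bit EDF profile (no annotations
  channel; events travel in a TSV sidecar); quantization noise is
  bounded by the per-channel physical range over 2^16.
- `MixedLM` with single-group variance components scales roughly with
  (random-effect columns)²; the formulation is comfortable at study
  scale but not intended for hundreds of participants.
- The spatial noise model is a stationary distance kernel; it does not
  produce realistic topographic artifact structure, so precision (as
  opposed to recall) of bad-channel detection on real data is untested.
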