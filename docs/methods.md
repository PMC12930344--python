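# Methods

`korosound` analyses Korotkoff sounds — the beat-synchronous sounds a
partially compressed brachial artery emits while a blood-pressure cuff
deflates from above systolic (SBP) to below diastolic (DBP) pressure —
as carriers of arterial-stiffness information. Because no public
recording corpus exists for this problem, the package pairs the
analysis pipeline with a synthetic cuff-deflation generator whose
ground truth makes every downstream stage testable. This note records
the model, the defaults and why they were chosen, the numerical
decisions, and what the synthetic validation does and does not show.

## The synthetic recording model

A recording is a two-channel series at 1 kHz: microphone signal
(arbitrary sensor units) and cuff pressure (mmHg).

**Cuff pressure.** Linear deflation at `deflation_rate` (default
3 mmHg/s, a typical clinical deflation; from SBP + 30 mmHg down to
DBP − 10 mmHg). The Korotkoff window is the span with
DBP < pressure < SBP; at the default 120/80 this is ≈ 13 s.

**Beats.** A renewal process at the heart rate (default 75 bpm) with a
fractional interval jitter (default SD 4%), emitting beats only inside
the window. Each beat is a damped sinusoid
`exp(−τ/beat_decay)·sin(2πfτ)` with `beat_decay` = 40 ms and a per-beat
frequency drawn uniformly from `beat_center_freq ± beat_bandwidth/2`.
Two parameters therefore map directly onto the spectral features:
the band centre onto peak/centroid frequency, the damping onto
spectral width.

**Envelope.** Beat peak amplitudes follow a Beta-density bump over the
window riding on a small pedestal (`envelope_floor`, default 8% of the
peak amplitude — Korotkoff sounds stay faintly audible across the whole
window until muffling near DBP; without the pedestal the envelope tails
vanish below any noise-aware threshold and the window-recovery problem
becomes ill-posed at strong skew). The Beta shapes are solved from a
single signed dial, `envelope_skew`, with the concentration a + b fixed
at 6 (both shapes stay > 1, so the density is bounded; the attainable
skew range is about ±1.1). Positive `envelope_skew` places amplitude
mass early in the window — at higher cuff pressures, the compliant-
artery pattern; negative places it late, the stiff-artery pattern.

**Nuisance structure.** Sinusoidal baseline wander (default amplitude
0.3, 0.4 Hz) and additive white noise (default SD 0.02 against a unit
peak amplitude) overlay the record. All randomness flows from one
integer seed; identical parameters give bitwise-identical records.

### Sign conventions (important)

* **Skewness** is the amplitude-weighted third standardized moment of
  beat peak times. Mass early ⇒ long late tail ⇒ positive skewness
  (the ordinary statistical convention for a right-skewed density).
* **Center of mass** is the amplitude-weighted mean beat time measured
  from the detected window midpoint *along the deflation direction*:
  `t_mid − Σwᵢtᵢ`, in seconds. Sound mass at higher cuff pressures
  (earlier) gives positive values. With this orientation the two
  statistics carry the *same* sign for a given envelope asymmetry —
  compliant/young recordings are (+,+), stiff/older recordings (−,−) —
  which is the empirically reported pattern. Measuring the center of
  mass from the window midpoint in raw time order instead would flip
  its sign and make the pair internally contradictory for any unimodal
  envelope.
* Both statistics negate under time reversal of the beat train.

### Cohort presets

Three presets mirror the study design this generator emulates:

* `young` — ages 25.9 ± 2.2, BMI 22.8 ± 1.1, BP 118/77, HR 76;
  `envelope_skew` +0.55 ± 0.35; beat band 40 ± 5 Hz.
* `older` — ages 67.5 ± 6.7, BMI 23.4 ± 1.5, BP 120/79, HR 78;
  `envelope_skew` −0.55 ± 0.35; beat band 29 ± 4 Hz.
* `hospital` — ages 20–79, realistic BMI/BP spread, diabetes 19%,
  smoking 13%; a latent stiffness variable z ~ N(0,1) shifts the skew
  dial by −0.45·z and the beat band by −4 Hz·z, and drives simulated
  brachial-ankle pulse-wave velocity through a linear covariate model
  `baPWV = 400 + 8·age + 4·SBP + 5·BMI + 80·diabetes + 150·z + ε`,
  ε ~ N(0, 120) cm/s — coefficient magnitudes chosen to land the cohort
  near 1,400 cm/s with age and blood pressure as the dominant
  determinants, as in clinical baPWV regressions. Subjects are labelled
  high/low baPWV by the cohort median.

The acoustic group contrast (skew ±0.55, bands 40 vs 29 Hz, with the
stated SDs) was set once to give overlapping groups with large but
non-degenerate effect sizes for the three discriminative features
(center of mass, skewness, peak frequency), reproducing the reported
sign structure while leaving the non-discriminative features
(amplitude, crest/impulse/form factors) to differ only incidentally.
Absolute placement of the beat band in Hz is a generator choice; the
published frequency-feature units are not mutually reconstructible
under standard definitions, so calibration targets signs and orderings,
never absolute feature values.

Per-subject seeds derive from the cohort seed as
`SeedSequence((cohort_seed, subject_index))` — reproducible and
mutually independent.

## Preprocessing

* **Baseline removal**: 4th-order Butterworth high-pass at 5 Hz applied
  forward-backward (zero phase). DC is annihilated; the 20–60 Hz
  Korotkoff band passes within 1%. A caveat: no finite-order filter is
  exactly idempotent on content inside its transition band (the abrupt
  beat attack leaks Lorentzian tails below 10 Hz), so "second
  application changes nothing" holds to < 1% only once the out-of-band
  drift has been removed.
* **Denoising**: DWT (`db6`, 4 levels), soft universal threshold
  `σ√(2 ln N)` on all detail levels, σ from the MAD of the finest
  level. All four choices are config-exposed.
* **Window detection**: beats are envelope peaks (analytic-signal
  magnitude, 50 ms moving average) above an adaptive threshold (10% of
  the window maximum for edge-finding), with a beat-likeness guard —
  the envelope maximum must exceed 5× its median, which scale-free
  noise cannot do. The strong-beat span is extended outward over
  fainter beats at a lower noise-aware threshold while they remain
  contiguous (within two beat intervals), then padded by half a beat
  interval and reconciled with the pressure channel. Annotated windows
  return verbatim; inflation-only (rising-pressure) records are
  rejected.
* **Beat segmentation**: envelope peaks at 20% of the window maximum,
  minimum separation 0.3 s (of two closer candidates the more prominent
  survives); segments tile the window, split at inter-peak midpoints.
  Beats are detected once and shared by all envelope features.

## The ten features

Computed on the concatenated denoised beat segments (amplitude and
spectral statistics) and on the beat peak train (envelope moments):

| feature | definition |
|---|---|
| max_amplitude | max \|x\| (sensor units) |
| kurtosis | fourth standardized central moment, non-excess |
| peak (crest) factor | max \|x\| / RMS |
| pulse (impulse) factor | max \|x\| / mean \|x\| |
| form factor | RMS / mean \|x\| |
| skewness | weighted third moment of beat times (see above) |
| center of mass | `t_mid − Σwᵢtᵢ`, deflation-direction sign, seconds |
| peak frequency | argmax of the Welch PSD, Hz |
| centroid frequency | Σf·P/ΣP, Hz |
| mean-square frequency | Σf²·P/ΣP, Hz² |

The factor ratios use raw moments (RMS and mean absolute value about
zero, the vibration-analysis convention), so `pulse = peak × form` is
an exact identity, and Jensen's inequality guarantees
`msf ≥ centroid²`. The PSD is an averaged periodogram (Hann, 1-s
segments, 50% overlap, capped at half the window length). All
dimensionless features are invariant to positive amplitude scaling.

## Scalograms and the compact classifier

The continuous wavelet transform uses an analytic Morlet
(bandwidth 1.5), 64 log-spaced centre frequencies over 5–100 Hz,
computed on the detected window (whole-record optional). Rendering
min-max normalizes the log-magnitude, resizes bilinearly, and applies a
fixed 256-entry viridis lookup table — bit-identical across runs and
backends. Since the analysis band sits far below Nyquist, the dataset
builder decimates 4× before the CWT, cutting its cost ~16-fold without
touching the band.

The classifier is a small from-scratch convolutional network written on
numpy: three 3×3-conv/ReLU/2×2-max-pool blocks (8/16/32 channels) and a
64-unit dense head (~10⁵ parameters at 64 px input), softmax
cross-entropy, Adam (lr 10⁻³), trained on grayscale-collapsed,
train-set-standardized images. Splits are stratified at the subject
level — a subject never straddles splits, asserted in the container —
with default fractions 70/15/15. Training is single-threaded and
seeded, hence reproducible to the bit.

## Statistics

* **Group comparison**: per-feature KS normality, Levene (centre =
  mean, threshold 0.05) choosing pooled vs Welch t, two-sided p,
  pooled-SD Cohen's d, Bonferroni flag at family α / #features (0.005
  for ten features at α = 0.05). Zero-variance groups force Welch with
  a small-variance guard.
* **Logistic regression**: Newton maximum likelihood (statsmodels),
  SEs from observed information; derived columns fixed as
  OR = exp(β), Wald = (β/SE)², CI = exp(β ∓ 1.959964·SE) — the z chosen
  so published 95% CIs reproduce to printed precision. Perfect
  separation raises explicitly. Accuracy is apparent (training)
  accuracy at threshold 0.5.
* **Hosmer–Lemeshow**: decile-of-risk quantile bins (ties share a
  bin), statistic Σ(O−E)²/(E(1−E/n)), reference χ² with (groups − 2)
  df — the canonical construction, valid when the probabilities come
  from a fitted model (the type-I-error simulation refits per
  replicate for exactly that reason). Saturated designs with too few
  distinct risk levels record NaN rather than a bogus p.
* **Correlation with power**: Pearson r, t-transform p, and post-hoc
  power by the Fisher-z normal approximation at the observed r —
  validated by its own closed form and simulation, since published
  post-hoc power columns for this kind of table are generally not
  reproducible without knowing the exact formula and α used.
* **Adjusted models**: OLS of baPWV on one acoustic feature plus age,
  diabetes, BMI, SBP; continuous variables z-scored (betas
  standardized), binary covariates left 0/1; VIF from auxiliary
  regressions with an explicit collinearity error naming the offending
  predictor.

In the orchestrated pipeline the calibrated presets separate the groups
almost perfectly, so the all-features exploratory logistic is often
non-identified; the pipeline then falls back to a clearly-flagged
ridge-penalized fit reporting accuracy and standardized coefficients
only.

## Problem sizes and what the validation shows

Default validation sizes: cohorts of 100/100 (directionality, 10
seeds), 500-replicate calibration simulations at n = 1000,
1000-replicate family-wise-error nulls at n = 100/100, a 5 × 20
envelope-skew recovery grid, and a 60-recording classifier check at
32 px — sizes chosen so the whole suite runs on one CPU in minutes
while keeping Monte-Carlo error well inside the asserted bands.

Passing these checks shows that the pipeline's arithmetic, sign
conventions, error-rate control, and parameter recovery are correct on
signals *of the assumed form*. The generator is phenomenological: it
does not model the fluid–wall mechanics of sound genesis, sensor
coupling, tissue filtering, motion artifacts, arrhythmia, or the
dependence of beat morphology on cuff pressure. Classification
accuracies on synthetic cohorts therefore say nothing quantitative
about accuracy on human recordings; published real-data accuracies are
not reproduction targets here.

## Known limitations

* The envelope family is unimodal-plus-pedestal; bimodal or silent-gap
  (auscultatory-gap) envelopes are not generated and would stress the
  window detector.
* Center-of-mass magnitudes scale with window length and hence with
  pulse pressure and deflation rate; between-cohort comparisons assume
  comparable deflation protocols.
* The Hosmer–Lemeshow χ² reference needs ≥ 2 observations per risk
  decile and a genuinely fitted model.
* The compact CNN is a minimal reference classifier, not a tuned
  architecture; an adapter to pretrained backbones is out of scope.
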