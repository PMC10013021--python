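# Methods

## Scope and model

`cardiosleep` implements an epoch-level analysis of sleep inferred from
cardiorespiratory signals. The setting it targets is one where EEG-based
polysomnography is impractical (most notably the intensive care unit) and
sleep stages are instead produced by two independent automatic stagers —
one driven by heart-rate variability (HRV), one by respiratory effort —
each emitting one stage per 30-s epoch from the set W, N1, N2, N3, R.
The package does not contain the stagers themselves; any pair of
epoch-aligned hypnograms can be supplied, and a synthetic generator
provides stager-like hypnograms for testing and simulation studies.

The analysis rests on a concordance relation between the two model
outputs. NREM depth is treated as an ordinal continuum W < N1 < N2 < N3:
a simultaneous stage pair is *concordant* when the two labels are within
one ordinal step of each other, while REM is concordant only when both
models assign R. This partitions the 15 unordered stage pairs into 8
concordant and 7 discordant ones. Epochs where either model lacks signal
are excluded from every denominator.

Downstream of the concordance labels the package computes:

- **Sleep indices** per 08:00-anchored 24-h segment (day = 08:00–20:00,
  night = 20:00–08:00): total/concordant/discordant sleep hours,
  discordant proportion, sleep fraction of available data, stage
  percentages of sleep (R, N1, N2, N3, N2+N3), the sleep fragmentation
  index SFI (transitions (N2,N3,R)→(N1,W) per hour of sleep) and wake
  transitions per hour of sleep ((N1,N2,N3,R)→W). The two models'
  records are combined as x_mean = (x_HRV + x_breathing)/2. Three
  sensitivity approaches control segment inclusion and basis: A1 (any
  sleep, total-sleep basis), A2 (≥ 2 h concordant sleep, total basis),
  A3 (≥ 2 h concordant sleep, concordant basis).
- **Fragmentation metrics**: day/night sleep proportions, the day share
  of sleep and of REM, and counts of sleep periods lasting ≥ 1 min and
  ≥ 5 min per 24 h (at 30-s epochs, runs of ≥ 2 and ≥ 10 epochs).
- **Breathing features** from the effort belt: respiratory rate
  (inspiratory peaks per 10-s window × 6), inter-breath intervals,
  a minute-ventilation proxy (windowed sum of positive amplitude
  changes × 6) with its coefficient of variation over 30 s, IBI CVar,
  and the variability index (mean of the two CVars).
- **HRV/CPC features**: mean NN and RMSSD after physiological NN
  filtering, Welch band powers (VLF 0.003–0.04, LF 0.04–0.15, HF
  0.15–0.4 Hz) of the 4 Hz-interpolated NN series, and cardiopulmonary
  coupling (coherence-weighted cross-spectral power between the NN
  series and the belt signal, summed over 0.01–0.1 and 0.1–0.4 Hz).
- **Cohort statistics**: a normality gate (non-Gaussian if Shapiro–Wilk
  *or* D'Agostino K² rejects at 0.05), the dual-test rule (a group
  difference requires Mann-Whitney U *and* Mood's median test both
  below 0.05), Kruskal–Wallis subgroup tests, a per-(feature, stage)
  Mann-Whitney screen of concordant vs discordant sleep at alpha 0.01,
  LASSO-penalized regression of the log discordant proportion on
  segment-level features with an OLS refit on the selected support,
  and Pearson + Spearman dose/severity correlations. No
  multiple-testing correction is applied; alphas are per test.

## Synthetic data generator

The generator defines the study conditions for every test. It emulates:

- **Stage dynamics** as a first-order Markov chain over (W, N1, N2, N3,
  R) with scenario-specific transition matrices; the initial stage is
  drawn from the chain's stationary distribution (computed by
  eigen-decomposition).
- **Stager error** as epoch-independent substitution: with probability
  `substitution_rate` an epoch's true stage is re-drawn from a
  per-stage confusion distribution whose mass sits mostly on ordinally
  adjacent stages plus a smaller REM/wake component, so both concordant
  and discordant disagreements occur and the induced discordant
  fraction is computable in closed form.
- **Respiratory effort** breath by breath: periods drawn with stage
  mean 60/rate and CV `rate_cv`, amplitudes with CV `amp_cv`, rendered
  as a raised-cosine inspiration followed by an exponential-decay
  expiration (asymmetric, one dominant inspiratory peak), plus additive
  Gaussian sensor noise (SD 0.05 of unit breath amplitude).
  Inspiratory time is held near-constant at min(1.5 s, period/2) while
  expiration absorbs the period variability — the physiological
  pattern, and necessary for detected inter-breath intervals to carry
  the injected timing variance rather than a smoothed version of it.
- **R-peak trains** with stage-conditioned mean RR, two sinusoidal RR
  modulations (an LF tone at 0.095 Hz and an HF tone at 0.25 Hz, with
  variance split according to the configured LF/HF ratio) and white
  jitter. The white-noise SD is solved analytically per stage so the
  RMSSD of the generated train matches the configured target exactly in
  expectation, using the identities E[Δ²] = 2σ² for white noise and
  E[Δ²] = 2A² sin²(πfT) for a sinusoid of amplitude A sampled every T
  seconds.

Three presets define scenario conditions. `icu-like`: stationary-mean
breathing rate 17.4 breaths/min (the per-stage rates are rescaled so the
stationary-weighted mean hits the target exactly), high breath-to-breath
variability, fragmented stage dynamics, depressed HRV (RMSSD 12–20 ms)
and stager substitution rate 0.35. `lab-nosdb`: 14.0 breaths/min, low
variability, consolidated sleep, RMSSD 25–40 ms, substitution 0.12.
`lab-sdb`: 15.5 breaths/min with the highest breath-level variability
(sleep-disordered breathing-like), substitution 0.20. Simulations start
at 20:00 by default so that 08:00-anchored segmentation and day/night
splits are exercised with partial head/tail segments.

What the generator does *not* emulate — and hence what passing tests do
not establish about real recordings: apnea/hypopnea events and periodic
breathing, movement and electrode artifact beyond stationary Gaussian
noise, autocorrelated (bursty) stager errors, circadian drift of HRV,
mechanical-ventilation waveforms, and realistic ECG morphology (R-peak
trains are generated directly; the QRS detector is validated separately
on synthetic pulse trains).

## Numerical and design choices

- **Belt QC.** Non-wear is a window that is simultaneously high (mean
  |amplitude| above 5× the median window amplitude) and flat (variance
  below 0.1× the median window variance); medians make the thresholds
  robust to the artifact's own mass. Low signal quality flags windows
  whose detected breath rate leaves [4, 60] breaths/min, gaps > 15 s
  without a peak, and windows with under half of their spectral power
  in the 0.05–1.0 Hz respiratory band — the band criterion is what
  rejects broadband noise, which refractory-limited peak picking alone
  would pass. All thresholds are keyword arguments.
- **Normalization** subtracts the plain mean of usable samples and
  divides by the SD of the 1–99% quantile-clipped usable samples
  (linear-interpolation quantiles). QC masks are applied before the
  statistics are computed. For reference, this scale factor is 0.982
  for standard-normal input.
- **Breath detection** low-pass filters at 1.5 Hz (zero-phase), then
  takes local maxima with prominence ≥ 0.3 normalized units and spacing
  ≥ 1 s. Feature windows step by 30 s aligned to epoch boundaries so
  features map 1:1 onto epochs; windows with < 80% usable samples are
  missing. CVs use the n−1 sample SD.
- **NN filtering** drops intervals outside 300–2000 ms and intervals
  changing more than 20% from the previously accepted one. Welch
  settings everywhere: 4 Hz series, 2-min Hann segments, 50% overlap.
  CPC uses the measured belt signal rather than ECG-derived
  respiration.
- **Transitions across gaps** (MISSING epochs, and non-concordant
  epochs under the A3 basis) are never counted in SFI or wake
  transitions; counting across gaps would inflate fragmentation on
  sparse recordings. SFI/wake-transition denominators are the record's
  own sleep time (total or concordant per basis).
- **Segment-level concordant sleep** (the A2/A3 inclusion quantity) is
  defined as epochs labelled concordant in which *both* models stage
  sleep; a (W, N1) epoch is concordant but is not concordant sleep.
- **Per-24-h fragmentation counts** are normalized by 24/available_h on
  partial segments (raw counts are also emitted); day/night proportions
  use available time in each half as denominator.
- **Regression.** y = discordant proportion is log-transformed as
  log(y + 1e-3) since fully concordant segments have y = 0. Features
  are standardized; the LASSO penalty comes from seeded 5-fold
  cross-validation with the one-standard-error rule. The 1-SE rule is
  deliberate: selecting the CV-minimum penalty and then running an OLS
  F-test on the selected support rejects far above nominal on
  pure-noise designs (post-selection inference), while the 1-SE choice
  keeps the null calibrated and still recovers a planted support
  exactly on noiseless designs. Coefficients below 1e-6 (standardized
  scale) are treated as zero.
- **Mood's median test** pools observations tied at the grand median
  into the "≤ median" cell.
- **Degenerate inputs**: constant samples are flagged non-Gaussian by
  the gate; fully tied dual tests return p = 1 and a degenerate flag;
  zero-variance correlation inputs return missing; zero-sleep segments
  report zero durations and missing rates/percentages; a single-class
  kappa comparison returns NaN.

## Problem sizes

Tests and the acceptance script run on deliberately small instances
chosen to give stable statistics: 10,000-epoch hypnograms for
discordance recovery, 2-h recordings (plus ten 15-min recordings per
cohort) for breathing-rate recovery, 20-min single-stage trains for
RMSSD recovery, 100 replicates for dual-test null calibration and 30
for regression null calibration, and n = 200 × 20 designs for the
planted-support check. These sizes keep every tolerance comfortably
inside its binomial or Monte-Carlo error.

## Known limitations

- The epoch-substitution error model is memoryless; real stagers err in
  bursts, so real-data discordance is likely more autocorrelated than
  simulated discordance.
- HRV presets are plausible clinical values, not calibrated to any
  cohort; no per-stage HRV reference values exist for critically ill
  patients.
- The CPC implementation couples the NN series with the measured belt
  signal; implementations using ECG-derived respiration will differ in
  absolute coupling power (band *ratios* are comparable).
- The QRS detector is validated on clean synthetic pulse trains; noisy
  clinical ECG should go through a dedicated toolbox, and the pipeline
  accepts precomputed R-peak times for exactly that reason.
- Kappa against an expert reference is only as aligned as the input
  grids; the package requires exact 30-s grid alignment and does not
  attempt automatic clock correction.
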