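# Methods

This note documents the models, conventions and numerical choices behind
`spatialhear`, and what the synthetic-data tests do and do not establish
about real data.

## Experimental design model

The design module reproduces the combinatorics of a multi-talker
localization/intelligibility session:

- **CRM corpus.** 8 call signs × 4 colors × 8 numbers × 8 talkers = 2048
  sentences; the target stream is the one carrying "Hopper".
- **Speaker ring.** 12 active speakers at exactly 30° spacing.  Absolute
  placement is configurable through a ring offset (default 15°, i.e. ±15°,
  ±45°, …, ±165°), constrained so no speaker sits on a quadrant boundary
  (0°, ±90°, 180°) — otherwise hemifield and quadrant labels would be
  ambiguous.  Azimuth convention: degrees in (−180, 180], 0° straight ahead,
  positive clockwise from above; front hemifield is |azimuth| < 90°.
- **Schedules.** 6 listening conditions × 96 trials; both SNRs (+5, +10 dB)
  interleaved with no more than 4 consecutive repeats (rejection-sampled
  permutation); target azimuth stratified 4× over each speaker within every
  condition × SNR cell so hemifields are balanced (24 trials per
  condition × SNR × hemifield cell).  Bare-ear blocks always come first and
  each low-pass-filtered block is anchored directly after its unfiltered
  partner, so only the OTE/ITE order counterbalances across subjects.
- Within a trial the four streams get distinct colors, numbers and talkers
  by default (configurable); this keeps the intelligibility key unambiguous.
  The full 8-talker pool is used; restrict `talker_pool` if a male-only
  subset is wanted.

## Head-orienting detection

Velocity is estimated from the azimuth trace by unwrapping across the ±180°
seam, moving-average smoothing of position (default 5 samples), central
differences (`np.gradient`), and moving-average smoothing of velocity
(default 5 samples).  Detection marks:

- **onset** — first sample of the first run of ≥ 3 consecutive samples with
  |velocity| > 20°/s, then walked back to the last sample with |velocity|
  below a low threshold (default 8°/s, i.e. 40% of the main threshold).
  The two-threshold (hysteresis) refinement exists because a smooth saccade
  reaches 20°/s only ~20–25 ms (amplitude-dependent) after the movement
  actually starts; the single-threshold marker is systematically late by
  about that much.  Setting `onset_backtrack_threshold=None` restores the
  literal single-threshold marker.
- **offset** — start of the first run of ≥ 5 sub-threshold samples after the
  last supra-threshold run (so a corrective second movement postpones the
  offset, and the endpoint describes where the head finally settled).
- **endpoint** — circular median of position over 100 ms after offset,
  robust to residual noise and the angular seam.

Absolute velocity is used, so movements in either direction count.  The
smoothing windows and the low threshold were chosen together (grid search
against the detector's functional requirements on synthetic saccades):
noiseless movements must be recovered within one sample, and with 0.5° RMS
position noise at 100 Hz the median onset error must stay well under one
sample period.  The shipped defaults achieve ~8 ms median onset error and
~0.13° median endpoint error under those conditions.  Degenerate traces
return flagged records (`no_movement`, `multiple_movements`,
`moving_at_end`, `gap`) rather than raising, mirroring how such trials are
set aside for manual review; `qc_review_table` merges reviewer overrides.

## Dependent variables

- **Intelligibility.** Each trial contributes two scored items (color,
  number), so a cell of *T* trials has N = 2T items — this keeps X ≤ N in
  the rationalized arcsine transform even though scoring descriptions are
  often written per trial.  RAU = (146/π)·AU − 23 with
  AU = arcsin √(X/(N+1)) + arcsin √((X+1)/(N+1)).  A variant without the
  square-root radicals (as the transform is sometimes typeset) is available
  behind `printed_variant=True` for auditing; it is not the standard
  transform.
- **Localization.** MAE over trials with a detected movement; angular error
  is circular by default (a 350° numeric difference is a 10° error). The
  literal linear difference is available behind `convention="linear"`.
  Front–back reversal rate is emitted as a diagnostic but reversed trials
  are *not* excluded from MAE.
- **Promptness.** 1/RT in s⁻¹, analyzed on the reciprocal scale; RTs in
  seconds are kept for the descriptive responder split.
- Trials without a detected movement are excluded from MAE and promptness
  but still scored for intelligibility (the report happens regardless of
  head movement).  Hemifield of a trial is the hemifield of its target
  speaker.

## Repeated-measures ANOVA

One observation per subject × condition × SNR × hemifield cell (6 × 2 × 2 =
24 cells).  The classical univariate decomposition is computed exactly: for
every factor subset E, the effect array is the Möbius (inclusion–exclusion)
combination of marginal means, SS_E is its sum of squares over the full
grid, and the matching error term is the E × subject interaction.  Then
F_E = MS_E / MS_{E×S}, partial η² = SS_E/(SS_E + SS_{E×S}).  The
decomposition is verified to reconstruct the data to ≤ 1e−8 (standardized
scale), and the table is cross-checked against an independent implementation
in the test suite.

Sphericity is never guaranteed for the 6-level factor, so each effect also
carries a Greenhouse–Geisser epsilon (from the covariance of
orthonormal-contrast scores, Kronecker-combined across the factors of the
effect, floored at 1/df and capped at 1) and the corrected p-value as a
supplementary column; uncorrected dfs remain the primary report.

Missing cells (e.g. a subject with no detected movement in some cell) make
the balanced decomposition undefined; `rm_anova` fails loudly naming the
subject and cell, and the pipeline offers an explicit
`drop_incomplete_subjects` option rather than imputing.

Pairwise follow-ups are paired t-tests on subject-level marginal means with
Bonferroni correction over all C(k,2) pairs in the factor (the conventional
behavior of mainstream statistics packages).  Correlations among DVs are
Pearson product–moment on subject × condition aggregates.

## Synthetic listener model

The generator is phenomenological — it produces data with the statistical
structure the analysis assumes, not an auditory model.

- **Intelligibility**: per-item Bernoulli with logit = base + β_SNR·[+10 dB]
  + β_back·[rear] + β_back,5·[rear ∧ +5 dB] + β_cond.  Defaults (base 1.2;
  β_SNR 1.1; β_back −0.8; β_back,5 −0.45; condition offsets 0 to −0.65 from
  NH to ITE-LPF) produce hemifield/SNR differences of roughly 15–25 RAU and
  a NH→ITE-LPF deficit of ~13 RAU at n = 10 — the directions and rough
  magnitudes such experiments report.
- **Localization**: endpoint = target + wrapped-normal error whose SD is a
  base dispersion (6°) times condition (largest under the earmuff
  conditions, 1.8–1.9×), rear (1.9×) and +5 dB (1.5×) factors; with
  probability 0.05 the endpoint is first mirrored about the interaural axis
  (front–back confusion).
- **Reaction times**: lognormal; fast listeners median 0.9 s (σ = 0.25)
  with rear (1.25×) and +5 dB (1.2×) slowing — about 0.23 s and 0.21 s on
  the mean; slow listeners median 1.9 s (σ = 0.15) with *no* factor effects,
  emulating listeners who wait for the color/number before orienting.  The
  population draw bounds fast medians at 1.1 s and slow medians at 1.6 s:
  the fast/slow phenotype is bimodal, not a graded tail, so the classes sit
  cleanly on either side of the 1.5 s classification cutoff.
- **Cohort**: per-subject parameters drawn from normal (logit effects) or
  lognormal (positive scales) population distributions; by default 3 of 10
  subjects are slow responders.  `CohortHyperparameters.null()` zeroes every
  factor effect while keeping subject heterogeneity — the type-I calibration
  condition.
- **Kinematics**: minimum-jerk position profile s(τ) = 10τ³ − 15τ⁴ + 6τ⁵
  between onset and endpoint, duration 0.2 s + 2.5 ms/deg of amplitude
  (main-sequence-like), so velocity is smooth, bell-shaped, monophasic and
  peaks far above 20°/s even for 15° movements.  White Gaussian position
  noise (default SD 0.5°) models tracker jitter.  Traces are sampled at
  100 Hz for 4.5 s by default.

Two generator routes exist and are cross-checked against each other: the
*trace route* synthesizes head traces that must pass through the detector,
and the *record route* emits the same per-trial draws directly as a response
table (as a perfectly reviewed detection pass would).  Monte-Carlo studies
(500-replicate null calibration, 150-replicate power) use the record route;
one 10-subject replicate then costs ~80 ms, which keeps those studies at
about a minute of CPU.  Because both routes share the single drawing
function, the record route is statistically identical up to detector
measurement error (~8 ms onset, ~0.13° endpoint — negligible at cell level).

What passing these tests shows: the pipeline recovers planted effects, is
calibrated under the null, and the detector/metrics/statistics chain is
internally consistent.  What it does not show: that real head-orienting
behavior follows minimum-jerk kinematics, that real intelligibility follows
an additive logit model, or anything about acoustics — multi-step search
strategies, anticipatory movements, drifting fixation and non-stationary
noise are all absent (a two-saccade stress generator exists only for
detector tests).

## Numerical choices and degenerate inputs

- Angles are wrapped to (−180, 180] everywhere; position is unwrapped before
  differentiation and endpoints are re-wrapped.
- The simulated-hearing-loss filter is a linear-phase FIR of length
  order + 1 (default 101 taps, Hamming window, 2.5 kHz cutoff): −58 dB at
  5 kHz, < 0.03 dB ripple at 500 Hz.  A 100th-order *recursive* filter would
  be numerically fragile; a Butterworth cascade (second-order sections) is
  available as the alternative family.  Cutoffs at or above Nyquist are
  rejected.
- SNR scaling uses full-band RMS over the whole waveform; silent inputs are
  rejected.
- Constant-DV ANOVA cells (zero error variance) are reported as degenerate
  (F = 0 or ∞) rather than raising.
- All randomness flows through `numpy.random.Generator`; cohorts are
  reproducible from a single seed via `SeedSequence` spawning, and pipeline
  runs are byte-identical given the same `RunConfig`.

## Known limitations

- The ANOVA layer assumes the complete balanced 24-cell design; unbalanced
  or missing-cell data require subject dropping (no mixed-model fallback).
- Circular statistics are used only where they matter (error metric,
  endpoint median); dispersion is modeled as wrapped-normal with moderate
  SDs, which is indistinguishable from von Mises in this regime but not for
  very large dispersions.
- The conditional pairwise contrasts some reports quote ("in the front at
  +5 dB") can be formed by filtering the cell table before
  `bonferroni_pairwise`, but the package takes no position on the family
  size for such conditional families; the default family is all pairs
  within the factor being followed up.
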