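# Methods

## The analysis model

The pipeline treats a recording session as three jointly registered event
streams: trials (1 s face presentations separated by a 0.5–0.75 s uniformly
jittered inter-stimulus interval, ~9% of them immediate one-back repeats),
gaze events (alternating saccades and fixations, each fixation labeled with
the facial ROI it lands on — eyes, mouth, nose, or other — and each saccade
with the ROI of the following fixation), and spike trains of simultaneously
recorded units from the amygdala and the anterior/posterior hippocampus
(pooled to "hippocampus" in all regional contrasts).

All event windows are half-open `[t0, t1)`: a spike on a boundary belongs to
the later window, which makes counts additive over abutting windows. The
fixation analysis window runs from 200 ms before fixation onset to 200 ms
after fixation offset, so its duration tracks the fixation (~815 ms on
average under the default fixation-duration model); the saccade window is
the fixed 400 ms around saccade onset. Baseline rate is the mean rate in the
0.5 s before stimulus onset, averaged across trials — the interval length is
a package choice (the minimum inter-stimulus interval) since only "the
interval right before face onset" is determined by the task structure; it is
configurable.

Inclusion rules: a session enters analysis only if every ROI received at
least 10 fixations; a unit only if its mean rate over the whole task is at
least 0.15 Hz. Both thresholds are inclusive.

### Selectivity and the FSI

Units are classified from per-event window rates by a two-tailed two-sample
t test (pooled variance, the classical df = n₁+n₂−2 form; Welch available by
configuration), at α = 0.05, labeled by the sign of the eyes−mouth mean
difference. The per-fixation selectivity index normalizes each event's rate
by the unit's own mouth reference and baseline,

    FSI_i = (FR_i − mean(FR_mouth)) / mean(FR_baseline) · 100% ,

sign-flipped for mouth-preferring *units* only. Two analytic consequences
are exploited as tests: the mean FSI over mouth fixations is exactly zero
for every unit, and positive over eye fixations for correctly-classified
selective units in expectation. Units with zero baseline or no mouth events
are excluded from index analyses with a logged reason, never imputed.

The permutation test statistic is the across-unit mean of each unit's mean
eye-fixation FSI; the null shuffles eyes/mouth labels within unit,
recomputing the mouth reference under each shuffle, and p uses the +1
correction, p = (1 + #{null ≥ observed})/(1 + B), so it is never exactly
zero. Serial-order controls rerun the same machinery restricted to fixations
of serial order {1}, {2}, {3,4}; the one-back control restricts the KS
comparison to repeat-trial fixations.

Group PSTHs count spikes in 50 ms bins aligned to event onset; each unit's
binned rates are divided by its mean window rate over all analyzed events
(z-scoring is available) before averaging, and per-bin condition differences
use a two-tailed paired t across units, Bonferroni-corrected over bins.

Per-unit ROC analysis thresholds spike counts at 20 linearly spaced values
between the observed minimum and maximum, takes the higher-mean class as
positive, and integrates by the trapezoid rule; the AUC is ≥ 0.5 by
construction and equals the exhaustive-threshold (Mann–Whitney) area
whenever the counts span at most 20 distinct values.

### Population decoding

Units from all sessions form a pseudo-population; each unit contributes an
equal number of events per class (subsampled from its own session). Spike
counts are taken in 27 bins of 500 ms stepped by 50 ms starting at −600 ms,
and z-scored per unit and bin using training-fold statistics only — applying
held-out normalization prevents leakage; a zero-variance training SD is
floored at 1. The maximal-correlation-coefficient classifier stores the
per-class mean template and assigns a test vector to the class with the
larger Pearson correlation (zero-variance vectors correlate 0; exact ties go
to the first class in sorted label order). Accuracy is assessed by
stratified 8-fold cross-validation repeated over random splits, a different
classifier per bin. Significance per bin counts the runs at or below the 50%
chance level, p = (1 + #{acc ≤ 0.5})/(1 + n_runs), with Benjamini–Hochberg
FDR across bins; group comparisons count runs by sign the same way. With 10
runs this run-counting p cannot fall below 1/11, so FDR-corrected claims use
the 50-run mode; 10 runs is the default for calibration work where only the
mean accuracy matters.

### Associations

Per-unit Pearson correlations between per-fixation window rates and an
external scalar (saliency value under the fixation, viewed face's ROI
luminance, or the face's consensus trait rating) are always computed within
a declared ROI scope, because eyes and mouth differ systematically in both
the scalar maps and the neural response — an unscoped correlation would just
re-detect the classification contrast. Records with fewer than 10 in-scope
fixations or degenerate variance are flagged and excluded from group tests
(one-sample t against zero per group; two-sample t between selective and
non-selective units; Bonferroni over the declared family, e.g. 8 traits × 2
scopes). Trait ratings enter as the across-rater arithmetic mean per face;
correlations are computed per fixation (repeated face values), with per-face
aggregation available.

## The synthetic generator

The generator's defaults are the study conditions: 500 trials/session, 1 s
presentations, 0.5–0.75 s ISI, 9% one-back repeats placed non-adjacently,
500 faces (50 identities × 10 photos), stationary ROI fixation probabilities
(eyes .22, mouth .14, nose .25, other .39), a +10% eye bias on the first
fixation of each trial (compensated on the second fixation so the overall
shares keep the stationary values), lognormal fixation durations with mean
415 ms and CV 0.4 truncated at 50 ms (so the padded analysis window averages
~815 ms), uniform 20–80 ms saccades, lognormal baseline rates with mean 3 Hz
(floored at 0.3 Hz so all units pass inclusion), and 55/365 eyes-preferring
plus 19/365 mouth-preferring units with a 2× rate gain during preferred-ROI
fixations, switched on at the preceding saccade's onset so selectivity
precedes fixation onset (switchable to fixation onset for ablations).

Spikes are piecewise-constant-rate Poisson: the session span is partitioned
at modulation boundaries and each segment draws a Poisson count with uniform
placement — exact for this process and correct also for sub-unity
multipliers. Units are conditionally independent given the event stream.

External maps are planted through a latent standard-normal per-fixation
"drive": selective units' rates during eyes and mouth fixations are
multiplied by exp(σd − σ²/2) with σ = 0.3; saliency values are generated
with latent correlation 0.3 to the drive (plus a +0.15 offset inside
eyes/mouth, motivating the scoped analysis); trait ratings for the planted
traits (warm, practical) add a 0.3-weighted standardized per-face mean
drive to otherwise independent clipped 1–7 ratings. After Poisson
attenuation the measured per-neuron correlations come out near 0.1 — a few
times the small values reported for recorded units, a deliberate choice so
that desk-scale cohorts (tens of selective units rather than hundreds of
sessions) recover the planted coupling reliably; the scoping *pattern*
(within-preferred significant, outside and non-selective at chance), not
the coefficient magnitude, is the validated property. Eye-ROI luminance is
drawn darker than mouth luminance and independently of the drive, making
the luminance control null by construction.

What the generator does not emulate: inter-neuron correlations, rate
adaptation and slow drift, oculomotor dynamics beyond event chains,
eye-tracker noise and mislabeled ROIs, and the heavy-tailed unit-rate
distribution of real extracellular recordings. Passing recovery tests
therefore demonstrates correctness of the analysis code under the assumed
generative model, not robustness to those real-data complications.

## Numerical and scale choices

- Times are stored as decimal text (6 fractional digits; spike times 9, with
  a 5 ns minimum spacing enforced by the generator) so written sessions are
  byte-deterministic and round-trip losslessly.
- All randomness flows through a single PCG64 generator seeded from a master
  seed and an integer key path, so any stage is reproducible in isolation.
- The uncorrected chi-square is used throughout (no Yates correction): it is
  the form that reproduces the classical single-unit prevalence contrasts
  this battery emulates, to their printed precision.
- Calibration suites run at deliberate desk scale: decoder null calibration
  uses 365 units with 500 events/class and 10 shuffle runs (the label
  shuffle is refreshed every run, the standard permutation-null
  construction, so run-averaged accuracy converges to chance); the planted
  decoding check uses 50 runs; selection calibration uses 1000 null units
  sharing one session's gaze events. The pipeline's default decoding mode
  runs 10 CV repeats, with the 50-run mode a configuration switch (~5×
  longer).
- Fixations extending past stimulus offset are kept whole (windows are not
  truncated at offset); the area-normalized ROI-share mode divides counts by
  mean ROI pixel area before renormalizing to 100% — both are package
  readings of under-determined details, flagged here.

## Known limitations

- The asymptotic KS p-value is used at all sample sizes; for very small FSI
  record sets the exact method would differ.
- The run-counting significance rule has granularity 1/(n_runs+1); temporal
  generalization (train one bin / test another) and non-MCC classifiers are
  out of scope.
- The overlap chi-square compares the saccade-selective subset against the
  full population (the published construction), which mildly violates
  independence of the two proportions; it is kept for comparability.
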