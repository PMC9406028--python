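# Methods

This note records the modelling choices behind `actipred`: what is
simulated and why, how the activity features are defined in edge cases,
how windows are labeled and folded, how the classifier is trained, and
what the package's tests do and do not establish about real cohorts.

## Synthetic cohort model

The generator emulates a home-monitoring cohort of COPD patients
wearing a wrist accelerometer continuously. Per patient and day it
draws, at `sampling_rate` Hz (default 20, i.e. 100 samples per
5-second epoch):

- a gravity baseline of exactly 1 g along the device z-axis;
- isotropic Gaussian jitter with SD `night_activity_level`
  (default 0.02 g) at all times — wrist tremor and posture shifts;
- daytime activity bouts from a Poisson process (`bout_rate` = 4/h
  between 06:00 and 23:00, `bout_duration` = 10 min), during which the
  per-axis noise SD rises to √(night² + day²) with
  `day_activity_level` = 0.15 g;
- non-wear gaps (Poisson `nonwear_rate` = 0.5/day, 3 h each) emitted as
  *absent* rows, never zeros, so the wear-validity rule has something
  real to reject.

Readmissions are scheduled by a per-day Bernoulli hazard
(`readmission_hazard` = 0.0055/day, chosen so that the default
16 × 243-day cohort carries on the order of 20 events, matching the
scale of the clinical cohort this pipeline models: ~3.9k patient-days
and 21 events). In the `decline_days` = 10 days before each event the
bout amplitude is multiplied by a factor falling linearly from 1 to
`decline_floor` = 0.5 on the event day. The decline is applied to bout
amplitude, not to the gravity baseline, because the epoch SD removes
constant components — a decline on the baseline would be invisible to
the features by construction. After each event, `hospital_stay_days`
= 5 days carry no samples at all (device off in hospital).

Determinism: each patient derives an independent RNG from
`SeedSequence([cohort_seed, patient_index])`; identical configurations
produce byte-identical CSV exports.

What the generator does **not** model: physiologically realistic gait
or posture spectra, device orientation changes, temperature/battery
artifacts, weekly or seasonal routines, heterogeneous patient
phenotypes. Consequently a classifier that performs well here is shown
to *detect the engineered decline through the full pipeline* — not to
achieve any particular accuracy on real patients, where the
pre-readmission signature is weaker, noisier, and sometimes absent
(abrupt exacerbations).

Memory note: one patient-day at 20 Hz is 1.73 M samples, so a full
patient (~4 × 10⁸ samples) is not materialized; the generator exposes a
per-day iterator that the pipeline consumes, fusing simulation with
feature extraction. `generate_patient` / `generate_cohort` return whole
in-memory streams and are intended for small cohorts and CSV export.

## Feature definitions and edge cases

- Epoch SD uses the population (1/N) form, with N the number of samples
  actually present in the epoch; an empty epoch is a missing value, not
  zero.
- Epochs, minutes, and hours are anchored to the patient's local
  midnight. Minute AI sums the present epoch SDs and records an epoch
  count (0–12) as a coverage flag; an all-missing minute is missing.
  Hourly PA sums the non-missing minutes.
- RI is the Pearson correlation of consecutive days' 24 hourly-PA
  values and is **undefined** (stored as NaN) on the first observed
  day, when the previous day is not wear-valid, or when either pattern
  has zero variance. QoA substitutes RI := 0 in that case
  (regularity-neutral), so QoA stays defined without inventing
  regularity. QoA of day d uses RI(d−1, d).
- Wear validity: ≥16 h of recorded coverage per 24-h day, read
  cumulatively; an optional `max_gap_seconds` tightens this to reject
  days with any single longer interruption (off by default).
- Invariances the tests enforce: σ_k is exactly invariant to a constant
  additive component of the resultant acceleration (this is the precise
  sense in which the SD "removes gravity" — a constant *vector* offset
  changes resultant magnitudes nonlinearly and is not an invariance of
  this feature family); all features are 1-homogeneous under positive
  scaling of the samples except RI, which is scale-invariant.

## Windows, labels, folds

Windows are 7 consecutive wear-valid calendar days, sliding by one day;
runs are additionally broken at readmission dates so no window spans a
hospitalization. A window is valid iff follow-up covers
`last_day + 30`; positive iff a readmission lies in
`(last_day, last_day + 30]` (an event on the last recorded day is not a
future readmission; day 30 counts).

The 48-element feature vector is: per day, (AI sum, AI mean, AI median,
AI CoV, RI-or-0, QoA) — the activity-based parameters plus the standard
statistical representatives — and six cross-window aggregates: mean and
CoV of daily AI sum, mean RI, mean QoA, and least-squares trend slopes
of daily AI sum and QoA. The two slopes exist because the clinical
rationale for the retrospective window is precisely a gradual
pre-readmission decline; they are the only components not named
day-by-day.

Cross-validation is blocked: windows are grouped into runs of
contiguous last-days per patient; if there are fewer runs than folds,
the largest run is cut with a 6-day guard (the minimum for 7-day
windows; the six windows straddling a cut are discarded) until k blocks
exist; runs are then assigned largest-first to the currently smallest
fold. The tests verify exhaustively that no patient-day occurs on both
sides of any train/validation boundary. Windows dropped by guard cuts
receive no out-of-fold prediction and are excluded from evaluation.

## Classifier

Plain SGD on the log-loss: ŷ = σ(w·x + b), updates
w ← w − α(ŷ − y)x, b ← b − α(ŷ − y), examples reshuffled each epoch.
Defaults: α = 0.01, up to 200 epochs, early stop when the epoch-mean
log-loss improves by < 1e−6, weights initialized N(0, 0.01²) from the
run seed. Features are z-scored with training-fold statistics only;
constant features pass through with SD set to 1. The decision threshold
is 0.5, inclusive (a tie predicts readmission); it is configurable, as
is optional per-class loss weighting (off by default — the pipeline's
synthetic cohorts yield roughly 15–40% positive windows, mild enough
for unweighted training).

The final model averages the k fold models' weights and biases
element-wise and carries pooled (all-data) standardization. Weight
averaging was chosen over a full-data refit because the fold models are
trained on largely overlapping data and their mean is a stable
consensus; a refit alternative would differ only in discarding the
cross-validation structure. Fold scores are the held-out log-loss and
thresholded classification accuracy.

## Evaluation

Prediction-based: TP (predicted window, readmission within 30 days)
and FP; accuracy = 100·TP/(TP+FP). Event-based: TE (event with ≥1
predicting window ending in [event − 30, event − 1]) and ME; precision
= 100·TE/(TE+ME). A window ending on the event day is not "prior" and
does not count toward TE. Events with *no* valid window in their
30-day pre-window (e.g. immediately after observation start or a prior
hospitalization) cannot be adjudicated for any classifier; they are
excluded from the TE+ME denominator and reported separately
(`n_events_total` vs `n_events_evaluable`). Zero-denominator ratios are
reported as null, never 0 or 100. Percentages are rounded to two
decimals only at serialization.

The signal-detection check holds the cross-validated window predictions
fixed and re-draws each patient's event dates uniformly over their
observation period (200 replicates), recomputing event-based precision
each time; the observed precision must exceed the null's 95th
percentile. This tests association between predictions and true event
timing without asserting any absolute accuracy.

## Problem sizes used by the tests

Unit and property tests run on reduced problem sizes chosen to exercise
the same code paths: short or sparsely sampled days (1–5 Hz) for the
brute-force feature oracles, a 50-patient × 40-day cohort at 2 Hz for
the decline property (Mann–Whitney, α = 0.01), 3–4-patient cohorts at
5 Hz for pipeline determinism, and the full default 16 × 243-day 20 Hz
cohort for the end-to-end signal-detection test. The acceptance script
runs the full default cohort. The epoch/minute/day formulas are
rate-agnostic (the epoch SD is over whatever N samples the epoch
holds), so the reduced rates change noise levels, not semantics.

## Known limitations

- The synthetic decline is monotone and deterministic in shape; real
  pre-exacerbation trajectories vary and may be absent entirely.
- Hourly-PA regularity in the generator comes only from the day/night
  split and bout Poisson statistics; RI on synthetic data is therefore
  high and relatively uniform across patients.
- The feature vector is one defensible assembly of the named
  quantities; the exact composition used in the original clinical
  analysis is not public, so alternatives (e.g. without trend slopes)
  are configurable rather than hard-coded.
- Event-based precision on small cohorts is a coarse statistic (a
  handful of events); the permutation null, not the point value, is the
  meaningful comparison.
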