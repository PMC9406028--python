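# actipred

Predicting 30-day hospital readmission of COPD patients from the
physical activity (PA) of daily living, recorded by a wrist-worn
tri-axial accelerometer.

Patients with COPD have the highest 30-day readmission burden of any
major disease group, and their day-to-day physical activity is a strong
correlate of health status: activity volume and routine regularity
typically decline in the days before an exacerbation that ends in
readmission. `actipred` implements, as a tested and reusable pipeline,
an analysis that exploits this: continuous accelerometry is reduced to
daily activity features, overlapping 7-day windows of those features
are labeled by whether a readmission followed within 30 days, and a
logistic-regression classifier trained by stochastic gradient descent
turns each new window into a readmission prediction for the following
day. Because clinical accelerometry cohorts are rarely shareable, the
package ships a synthetic cohort generator that reproduces the
statistical structure the analysis relies on — circadian bout activity,
a gravity-dominated 1 g resting signal, non-wear gaps, and a
progressive pre-readmission decline — so every stage is testable end to
end with known ground truth.

## The features and the model

From the raw samples (ax, ay, az in g-units), per 5-second epoch of
N samples:

- resultant acceleration `A_i = √(ax_i² + ay_i² + az_i²)`
- epoch mean `μ = (1/N) Σ A_i`
- epoch SD `σ_k = √((1/N) Σ (A_i − μ)²)` — the population SD removes
  the constant gravity component, leaving quantified PA

and from the epochs:

- **Activity Index** `AI_m = Σ_{k=1..12} σ_k`, one value per minute
  (12 epochs = 60 s)
- **hourly PA** = the sum of the 60 minute-AI values of each clock hour
- **Regularity Index** `RI_d = corr(hourlyPA_{d−1}, hourlyPA_d)`, the
  Pearson correlation of consecutive days' 24-hour activity patterns
- **Quality of Activity** `QoA_d = (Σ_{m=1..1440} AI_m) × (1 + RI_d)`

A day enters the analysis only if ≥16 h of PA data were recorded over
the 24-h period. Each 7-day run of valid days yields stride-1 sliding
windows (a "dataset"); a window is *valid* when 30 days of clinical
follow-up exist beyond its last day, and *positive* when a readmission
occurred in those 30 days. The classifier is logistic regression
`p = σ(w·x + b)` trained with the per-example updates
`w_i ← w_i − α(ŷ − y)x_i`, `b ← b − α(ŷ − y)`, validated by blocked
10-fold cross-validation (contiguous time blocks with a 6-day guard gap
so overlapping windows never leak days between training and
validation), and the final model averages the fold models' weights.

Performance is reported from two angles:

- **prediction-based**: of the windows where a readmission was
  predicted, accuracy = TP / (TP + FP) × 100;
- **event-based**: of the actual readmission events, precision =
  TE / (TE + ME) × 100, where an event counts as truly predicted (TE)
  if any predicting window ended within the 30 days before it.

## Worked example

A study-scale cohort (16 patients × 243 days ≈ 3.9k patient-days) at a
reduced 5 Hz sampling rate, which runs in about two minutes:

```python
from actipred import CohortConfig, RunConfig, run_all

cfg = RunConfig(
    cohort=CohortConfig(n_patients=16, days_per_patient=243,
                        sampling_rate=5, seed=1),
    seed=1,
)
res = run_all(cfg)
print(res.report.to_dict())
```

prints

```
{'n_valid_datasets': 2945, 'n_datasets_with_prediction': 112,
 'true_predictions': 111, 'false_predictions': 1,
 'truly_predicted_events': 16, 'mispredicted_events': 0,
 'n_events_total': 17, 'n_events_evaluable': 16,
 'accuracy_prediction_based_pct': 99.11, 'false_prediction_rate_pct': 0.89,
 'precision_event_based_pct': 100.0, 'event_miss_rate_pct': 0.0}
```

Of the 2945 valid 7-day windows, the cross-validated model predicted a
readmission for 112; 111 of those were followed by an actual
readmission within 30 days (99.11% prediction-based accuracy), and all
16 evaluable readmission events had at least one predicting window in
their preceding 30 days (100% event-based precision). The synthetic
cohort's pre-readmission decline (bout amplitude ramping down to 50%
over 10 days) is a clean, noise-free signal compared with real
patients, which is why these numbers are optimistic; the
signal-detection test instead compares this precision against a
200-replicate permutation null (95th percentile ≈ 41% here).

The same pipeline is scriptable from the shell:

```sh
actipred run-all --seed 1 --out results/run1
actipred simulate --config run.yaml --out cohort/   # staged variant
```

## Layout

- `actipred.synth` — synthetic cohort generator (streams + event logs)
- `actipred.features` — AI / RI / QoA and wear validity
- `actipred.windows` — sliding windows, labeling, blocked folds
- `actipred.model` — SGD logistic regression and cross-validation
- `actipred.evaluate` — prediction-based and event-based reports
- `actipred.pipeline` / `actipred.cli` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, parameters, limitations
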