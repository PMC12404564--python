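# Methods

## Problem

Tacrolimus has a narrow therapeutic range, and inpatient dosing after kidney
or liver transplant is adjusted daily against the morning trough
concentration (C0, ng/mL). `tacrodose` implements a decision-support
pipeline for this setting: (1) a causal sequence model that predicts the
next morning's C0 from each day's EHR-derived features, (2) classification
of troughs as under/therapeutic/over against organ- and time-dependent
target windows, and (3) a constrained search over feasible twice-daily dose
pairs whose counterfactually predicted C0 best centers the window, scored
retrospectively by a sigmoid reward.

## Forecasting model

The forecaster is a stacked LSTM applied to per-patient daily feature
sequences. Each day `t` contributes one feature vector (today's trough,
tacrolimus dose totals in three 8-hour bins for days `t` and `t-1`,
3-day interacting-drug exposure flags, last-known labs and vitals, diet,
demographics, comorbidities, organ, days post-transplant); the output at
step `t` is the predicted trough of day `t+1`. Strict causality holds by
construction — the recurrence consumes rows in day order, so a prediction
never depends on later data. Targets and features are min-max scaled into
(0,1) on the training split only; predictions are inverse-scaled and floored
at 0 ng/mL.

Because no deep-learning framework is assumed, the LSTM (two layers, hidden
size 48, inter-layer dropout 0.1 by default) is implemented directly in
NumPy with backpropagation through time, verified against finite-difference
gradients in the test suite. Training uses Adam (learning rate 2e-3, batch
16, coupled L2 weight decay 1e-5 — the model's published-style defaults),
MSE on the scaled target over all prediction days, global gradient-norm
clipping at 5, plateau learning-rate decay (x0.5 after 8 stagnant epochs,
floor 1e-4), and early stopping on validation MSE (patience 20 by default);
the best-validation epoch's weights are restored. All randomness (weight
init, batch shuffling, dropout) flows from one named seed; runs are exactly
reproducible.

A day `t` is a *prediction instance* when the trough was measured on
mornings `t` and `t+1` and at least one tacrolimus administration followed
the day-`t` measurement; patients are adults with a single transplanted
organ. Splits are by patient: everyone transplanted in the test year (2024
by default) is test, the remainder are shuffled 90/10 into train/validation.

### Extreme-trough emphasis

Troughs below 5 or above 13 ng/mL are rare but clinically critical. The
table-level operation `oversample_training_set` duplicates such instances
three extra times (4 rows each). Inside the sequence trainer the same rule
is realized as a per-timestep loss weight of 4 (duplicating individual
timesteps of a sequence is ill-defined); this is exactly the duplication
rule in expectation. It is exposed as `ForecasterConfig.oversample` and is
intended for the classification use of the model; for pure regression
evaluation it is better left off, since weighting extremes trades typical-
case MAE for tail recall.

### Feature importance

Permutation importance (model class reliance): one feature at a time is
shuffled across the pooled patient-day axis of a held-out split, predictions
recomputed, and the degradation (permuted MAE − baseline MAE) averaged over
repeated shuffles (default 10, seeded). Pooled — rather than within-patient —
permutation matches the standard formulation and also breaks the
between-patient component of a feature's signal.

## Therapeutic windows, classification and metrics

The window registry is piecewise-constant in days post-transplant: kidney
10–13 ng/mL through day 90, then 8–10; liver 7–10 through day 365, then 5–7.
The source windows are stated in calendar months/years; the breakpoints are
fixed here at 90 and 365 days with the earlier window inclusive of its
breakpoint day, and window bounds are inclusive for "therapeutic" — both
boundary conventions were open choices. The 3-class label is obtained by
thresholding a trough (predicted or actual) against the window
(regression-as-classifier); a separately trained classification head is not
used because the same trained model underlies both tasks. Metrics: MAE and
MAPE for regression; per-class, microaveraged and macroaveraged precision/
recall/F1 (via scikit-learn) for classification, with absent classes
contributing zeros to the macroaverage under a warning.

## Dose recommendation

Candidates are ordered (AM, PM) pairs on a 0.5 mg grid, each single dose in
[0, 15] mg, |AM − PM| ≤ 1 mg, and daily total at most 1.5x the previous
day's total. The cap is read as an upper bound only — holds and decreases
must remain feasible (a symmetric lower bound is available behind a flag).
The 0 mg single dose is kept in the grid (a dose hold). The recommended pair
minimizes |predicted C0 − window midpoint|, the midpoint operationalizing
"best predicted C0 within the window"; ties break to the lower total, then
the lower AM dose. Counterfactual prediction substitutes the candidate into
the day-`t` dose bins at the default administration times (AM → 8–16 h bin,
PM → 16–24 h bin, 0–8 h bin cleared) and re-runs the forecaster; the hidden
state through day `t-1` is computed once per day and shared across
candidates.

The reward of a realized trough is
`R(x) = c·[σ(x − b_lower) − σ(x − b_upper)]` with
`c = 1/(2σ((b_upper−b_lower)/2) − 1)` by default, which normalizes the
maximum (at the window midpoint) to exactly 1; R is symmetric about the
midpoint and decays to 0 in both tails. Retrospective evaluation bins the
distance (actual − recommended daily total, mg; default bin width 1 mg,
centered at 0) and reports the per-bin mean reward with its standard error.

## Synthetic cohort generator

The generator emulates the *structure* of an inpatient transplant cohort so
the whole pipeline is testable with known ground truth. The morning trough
of day `d` is

    C0(d) = dose(d-1) / CL_eff(d) · exp(ε),   ε ~ N(0, σ_resid²)
    CL_eff = cl_pop · organ_factor · inhibitor_factor · exp(b_i + a_{i,d})

a steady-state one-compartment-style dose/clearance ratio with lognormal
noise: `b_i ~ N(0, ω_bsv²)` is a between-subject effect and `a_{i,d}` a
stationary AR(1) within-subject drift (autocorrelation ρ, marginal SD
ω_iov). Full PK ODEs are deliberately out of scope — this is the simplest
mechanism producing autocorrelated, covariate-dependent troughs for a
sequence model to exploit.

Defaults, chosen once from the cohort summary statistics the generator
emulates and held fixed: `cl_pop = 0.595` mg·mL/ng/day so the median trough
at the typical 5 mg/day is 5/0.595 = 8.4 ng/mL (kidney);
`organ_factor = 1.12` for liver so the liver median is 7.5 ng/mL;
`ω_bsv = 0.30`, `ω_iov = 0.15`, `ρ = 0.90`, `σ_resid = 0.15`, which give a
cohort trough IQR ratio of ≈1.65, matching the ≈1.7 of the emulated
population; `inhibitor_factor = 0.60` on days following an active azole.
Other structure: twice-daily administrations at 08:00/20:00 with ±90 min
jitter (so the 8-hour dose bins are nontrivially exercised), morning trough
draws at ~06:00 (5% skipped), lower-limit censoring — any value ≤ 2 ng/mL is
stored as the literal string "<2" and resolved to 1 ng/mL downstream —
irregular missingness in labs/vitals (20% of cells by default), diet orders,
interacting-drug episodes (0.5/patient-month), transplant dates spanning
2016–2024 so the temporal split is exercisable, and a simple titration
policy (±1 mg/day against the window, occasional ±1–2 mg clinician
variability, 2% dose-hold days) so doses and levels co-evolve. The titration
policy is a stand-in, not a claim about clinician behavior. Latent
per-patient-day effects are emitted alongside the tables, so the irreducible
error floor — the MAE of the conditional-median oracle `mu = dose/CL_eff`
against realized troughs — is computable exactly.

What the generator does **not** emulate: rejection episodes, readmissions,
infection physiology, formulation changes, assay drift, free-text notes, or
any real between-feature correlation structure in labs/vitals. Passing the
recovery tests therefore shows the pipeline can extract a dose/clearance
signal of realistic magnitude and autocorrelation from EHR-shaped data —
not that it attains any particular accuracy on real patients.

## Test and evaluation scales

Recovery tests train at sizes chosen to keep the full suite in the
minutes range on one CPU: the noise-free recovery cohort uses 200 patients
(σ_resid = ω_iov = 0, no inhibitor episodes or holds — the trough is then an
exact function of observed dose and the level-inferable subject clearance);
the noisy recovery cohort uses 400 patients at the default noise levels,
where the trained model's test MAE is required to come within 1.5x the
irreducible floor. The distance–reward analysis and permutation-importance
negative control (an injected iid uniform feature) reuse those trained
models. The acceptance script re-runs the same computations from scratch at
the same sizes.

## Known limitations

* The generator's missingness is completely at random; real EHR missingness
  is informative.
* The forecaster sees only data through day `t`; a planned next-day dose is
  never an input except through the recommender's counterfactual
  substitution. Whether the emulated workflow fed the planned dose to its
  model is ambiguous; this implementation takes the strictly causal reading.
* Whether dose bins for both the current and previous day (all six) were
  used in the emulated feature set is not certain; the default manifest
  includes all six, and the manifest is configurable.
* Min-max scaling clips out-of-training-range values at evaluation time;
  extrapolation behavior is otherwise unspecified.
* The NumPy LSTM is single-threaded BLAS-bound and sized for cohorts of
  hundreds of patients; it is not a GPU-scale training stack.
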