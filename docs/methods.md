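# Methods

This note documents the models, rules and numerical choices implemented in
`akiattn`, and what the synthetic experiments do and do not show.

## Problem setting

Each ICU stay is one sample. Data from a fixed *observation interval*
(24 or 48 h from ICU entry) are used to predict, over the following
*prediction interval* (24 h to 6 days), three targets: whether the patient
becomes an AKI case, the maximal KDIGO stage reached, and the *onset
interval* — which equal-length subinterval of the prediction window contains
the onset. Three interval settings are built in:

| setting | observation | prediction | onset interval | onset classes |
|---------|------------|------------|----------------|---------------|
| case1   | 24 h       | 24 h       | 12 h           | 2             |
| case2   | 24 h       | 6 d        | 24 h           | 6             |
| case3   | 48 h       | 5 d        | 24 h           | 5             |

## KDIGO labeling

AKI case: (a) serum creatinine (SCr) rise ≥ 0.3 mg/dl between any ordered
pair of measurements at most 48 h apart (all pairs, not only adjacent ones);
(b) SCr ≥ 1.5× the baseline within 7 days, the baseline being the first
in-hospital measurement and the window anchored at that measurement's time;
(c) urine output < 0.5 ml/kg/h sustained ≥ 6 h. Stages take the maximum
over: ratio bands ≥1.5/≥2.0/≥3.0 → 1/2/3; rise ≥0.3 (48 h) → 1; rise
≥4.0 mg/dl (48 h) → 3; urine < 0.5 ml/kg/h for 6–12 h → 1, ≥ 12 h → 2;
< 0.3 for ≥ 24 h → 3; anuria (rate exactly 0) ≥ 12 h → 3; renal replacement
therapy → 3; age < 18 with eGFR < 35 ml/min/1.73 m² → 3 (eGFR is accepted
as a precomputed input; if absent the rule is skipped with a warning).

Numerical conventions:

* charted urine volumes become rates over each charting gap; a sustained-low
  run is a maximal stretch of consecutive sub-threshold intervals, and a
  charting gap longer than 6 h breaks the run (sparse data cannot attest a
  sustained rate). A run "fires" at run start + required duration.
* onset time is the earliest time any criterion first holds; onset bins are
  half-open `[start, end)`, so a boundary time belongs to the later bin.
* onsets beyond the prediction horizon yield "not AKI for this setting";
  AKI already present during observation excludes the stay.
* SCr charted in µmol/l is divided by 88.4.

Ambiguities resolved here (the source rules can be read two ways): the
7-day ratio window is anchored at the baseline measurement rather than
rolling; urine criteria use the admission weight throughout the stay.

## Input schema (50 positions)

The predictor reads one fixed-order sequence per stay: age, gender,
ethnicity one-hot (white/other + configurable vocabulary), BMI (mass and
height folded in), 26 lab/vital channels (the association-table set), 8
medication ATC classes (A10, B01, C02, C03, C09, C10, M01, plus V08 keying
contrast media, which has no single therapeutic letter class), and 11
comorbidity keywords matched case-insensitively in the admission note.
Continuous features are min–max normalized to [0, 1] with bounds fitted on
the training split only and clipping at inference; a degenerate feature
(max = min) maps to 0.5 with a warning. Channels unobserved during the
observation window receive one synthetic observation at the window end with
a configured default normal value. Duplicate chart timestamps keep the
last-written value (charting corrections). NDC prescription codes map to
ATC classes through a replaceable two-column table; the bundled table is
synthetic and test-scale.

## TCN forecaster

Each temporal channel's normalized observation-interval values, ordered by
chart time and treated as an evenly spaced ordinal sequence, feed a
three-layer dilated causal convolution stack (dilations 1, 2, 4; kernel 3;
16 hidden channels; ReLU; receptive field 1 + 2·(1+2+4) = 15). Causality is
realized by zero left-padding, so output length always equals input length
and outputs depend only on past inputs. Training is one-step-ahead
regression with squared loss — input `x_0..x_{L-2}`, target `x_1..x_{L-1}`,
so every output position including the last carries a target — with Adam at
learning rate 0.001 for 100 epochs. The forecast "future value" is the last
output element, clipped to [0, 1]. One model per channel by default
(channels have distinct dynamics); pooling series from several channels
into one fit gives a shared model. Variable-length batches left-pad with
zeros, which is exact under causal zero-padding.

## Attention predictor

An LSTM encoder (hidden size 64, one recurrent unit per schema position)
produces states `h_0..h_t`; dot-product attention uses the final state as
query: `s_i = h_t·h_i`, `w = softmax(s)`, `cv = Σ w_i h_i`,
`av = [cv, h_t]` (dimension 128). The decoder is dense(128) → ReLU →
dropout(0.2, training only) → task head: sigmoid scalar (case), 3-way
softmax (stage), or softmax over the setting's onset intervals (onset).
Losses are binary/categorical cross-entropy; the optimizer is Adam at
initial learning rate 0.001 with a 0.9 multiplicative decay applied on a
monitored-loss plateau (patience 10 by default; the cadence is
configurable); defaults are 1,000 epochs and batch size 128. Decisions
threshold probabilities with a strict "exceeds" comparison at 0.5 by
default; AUC does not depend on the threshold.

The implementation is plain numpy: forward passes in float32, analytic
backward passes for the full chain (decoder → attention → backprop through
time), gradient-checked against finite differences in the test suite.
Numerical choices: per-gate orthogonal recurrent initialization, Glorot
input/dense weights, forget-gate bias 1, and a fixed affine recentering of
the [0,1] inputs onto [−1,1] before the recurrence (invertible, improves
conditioning; the normalization contract is unchanged). Fits are bitwise
deterministic per seed. Stage and onset heads train on AKI-positive stays
only, since those heads carry no "no AKI" class; this is configurable by
passing a different training subset.

## Evaluation protocol

Stays split 8:1:1 into train/validation/test with exact largest-remainder
allocation per stratum (jointly by case × stage × onset interval, degrading
to case-only with a warning when a stratum has fewer than 3 members).
Splits are canonically sorted by stay id before shuffling, so they depend
only on ids, labels and seed. Per repeat: normalizer fitted on train →
TCNs fitted on train series → sequences assembled → predictor trained →
specificity (TN/(TN+FP)), sensitivity (TP/(TP+FN)) and AUC (rank statistic
with tie correction) on test, reported as mean ± sd over repeated reseeded
splits and trainings (default 5). LR/RF/GBT comparison rows use
scikit-learn on the flattened feature table and are clearly non-novel.

## Feature-impact analysis

Step 1, associations: for continuous features, group means of the per-stay
last observed normalized value (a mean-over-stay summary is available as an
alternative), delta = mean(AKI) − mean(not AKI), and ratio = 100·delta/mean(AKI),
flagged when the denominator is zero. For categorical features, contingency
percentages 100·n_AKI/(n_AKI+n_not) at two decimals with half-up rounding.
Step 2, attention importance: per-stay attention weights averaged
position-wise over an evaluation set (the test split), mapped to feature
names through the schema, grouped (comorbidity / medication /
lab-test-and-vital-sign) and sorted descending.

## Synthetic cohort generator

The generator emulates the MIMIC-shaped table layout at reduced scale with
irregular sampling, per-observation dropout (10%), whole-channel
missingness (8%), note text with planted comorbidity keywords, planted
empty-note and AKI-note stays for the exclusion filters, and NDC-coded
prescriptions. A logistic latent-risk model decides which stays are
AKI-destined: log-odds 2.4 per sd on each of two latent severities that
shift the creatinine baseline up and the urine-output baseline down (the
two *planted channels*), plus comorbidity and medication log-odds of
±0.4–1.2; the intercept is calibrated by bisection to a 30% target
prevalence. Destined stays receive an onset time uniform in the prediction
interval, a piecewise-linear creatinine excursion whose peak-ratio tier
(1.7/2.4/3.4 with probabilities 0.5/0.3/0.2) controls the stage mixture,
and a depressed urine rate; a leakage parameter (0.5 of a 0.2 mg/dl
pre-trend over the last 8 observation hours, and a 12.5% urine-rate
depression) lets part of the pre-onset trend appear during late
observation. Labels are always derived from the trajectories by the KDIGO
engine, never set directly, so noise can fire or miss criteria exactly as
in real charts. Realized prevalence lands within ±3 percentage points of
target at n ≥ 2000.

The generator is structurally realistic, not physiologically faithful:
trajectories are piecewise-linear plus Gaussian noise, the non-planted
channels are pure noise, and covariates are sampled independently. Passing
tests therefore demonstrate that the pipeline recovers a known signal under
controlled conditions — they say nothing about performance on real ICU
data.

## Reduced-scale experiment conditions

The documented validation experiment uses n = 2000 stays, the case1
intervals, 10 seeds (cohort, split, and initialization reseeded together),
and 100 training epochs. Because the number of gradient updates per epoch
scales with cohort size over batch size, the full-scale optimization
settings would leave the predictor far short of convergence at this scale;
the scaled runs therefore use batch size 32 with learning rate 3e-3, defer
the 0.9 learning-rate decay to a 30-epoch plateau of the training loss, and
fit each channel's TCN on a 256-series subsample. The zero-signal control
additionally scores the trained model on a second fully held-out
zero-signal cohort of the same size, because a 200-stay test split alone
gives a null-AUC estimate with standard error of several points.

## Known limitations

* Mean attention weight is a weak feature-attribution device here. The
  trained models reach high held-out AUC on planted-signal cohorts, yet
  their mean per-position attention weights are dominated by positional
  structure (states near the sequence end resemble the query `h_t`) and do
  not consistently rank the planted channels highly — on clean
  single-signal toys the informative position is often *down*-weighted.
  This matches the broader finding that attention weights over recurrent
  prefix states need not align with feature importance. The importance
  report is faithful to the method; interpret it accordingly.
* The ordinal treatment of temporal series discards inter-measurement
  spacing; timestamp-aware encodings are out of scope.
* Urine criteria use admission weight; real weight trajectories are not
  modeled.
* The NDC→ATC table is a synthetic test-scale fixture; real crosswalks are
  licensed and must be supplied by the user.
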