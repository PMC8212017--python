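# akiattn

Temporal risk prediction of acute kidney injury (AKI) for ICU patients,
with an interpretable attention-based neural model — built for clinical
data scientists working with MIMIC-shaped electronic health records and
for methods researchers who need a fully testable, self-contained pipeline.

AKI is defined and staged by the KDIGO consensus criteria from serum
creatinine (SCr) and urine output. Given data from an *observation
interval* (the first 24–48 h of an ICU stay), the pipeline predicts, over
a following *prediction interval*, three targets:

* **case** — will the patient become an AKI case (binary),
* **stage** — the maximal KDIGO stage 1–3 reached (3-way),
* **onset interval** — which equal-length subinterval of the prediction
  window contains the onset (multi-class).

## The model

For each stay a fixed 50-element feature sequence `x_0..x_t` is assembled:
demographics, BMI, the forecast *future values* of 26 lab/vital channels,
medication ATC classes (multi-hot) and comorbidity keywords from the
admission note (multi-hot), all normalized to [0, 1] by
`x̂ = (x − min)/(max − min)` with bounds fitted on the training split.

Future values come from a **temporal convolutional network**: a stack of
dilated causal convolutions

    F_v = Σ_{i=0}^{k−1} f(i) · X_{v − d·i}        (d = 1, 2, 4;  k = 3)

whose output has the input's length, depends only on past inputs, and is
trained one-step-ahead per channel; the last output element is the
channel's forecast.

The predictor is an **LSTM encoder with dot-product attention**: states
`h_0..h_t` (dimension 64), scores `s_i = h_t · h_i`, weights
`w = softmax(s)`, context vector `cv = Σ w_i h_i`, attention output
`av = [cv, h_t]` (dimension 128), decoded by dense(128) → dropout(0.2) →
sigmoid or softmax head. Both networks are implemented in pure numpy with
analytic, gradient-checked backpropagation; fits are deterministic per
seed.

Two companion analyses mirror the model's interpretability story:
association tables (group means / contingency percentages of each feature
by AKI outcome) and attention-weight feature importance (mean per-position
attention weight over an evaluation set, grouped by comorbidity /
medication / lab-and-vital). A synthetic MIMIC-shaped cohort generator
with a controllable latent AKI-risk structure makes every stage testable
without credentialed data.

## Worked example

Generate a synthetic cohort, label it with the KDIGO engine, and run the
24 h → 24 h experiment end to end (reduced settings shown to keep the
example fast):

```python
from akiattn import SyntheticCohortSpec, generate_cohort, run_experiment

spec = SyntheticCohortSpec(n_stays=600)       # 30% target AKI prevalence
cohort = generate_cohort(spec, seed=7)
result = run_experiment(
    cohort, case="case1", tasks=("case",), seeds=[0], epochs=100,
    predictor_params={"batch_size": 32, "learning_rate": 3e-3,
                      "decay_patience": 30, "validation_fraction": 0.0},
)
print(result.metrics.to_string(index=False))
```

```
task class      metric     mean  sd
case       specificity 0.925000 0.0
case       sensitivity 0.588235 0.0
case               auc 0.875000 0.0
```

Specificity and sensitivity are read at the default 0.5 decision
threshold; the AUC of 0.88 on a 600-stay cohort (57 held-out stays) shows
the pipeline recovering the planted creatinine/urine risk signal — at the
documented scale of 2,000 stays the held-out AUC averages about 0.9
across ten seeds. The same `run_experiment` call accepts `tasks=("case", "stage",
"onset")`, `baselines=("LR", "RF", "GBT")` and any of the three interval
settings (`case1` = 24 h/24 h/12 h, `case2` = 24 h/6 d/24 h, `case3` =
48 h/5 d/24 h).

The command-line surface wraps the same functions:

```bash
akiattn simulate --n-stays 2000 --seed 7 --out cohort/
akiattn label --events events.csv --stays stays.csv --scheme case2 --out labels.csv
akiattn evaluate --cohort cohort/ --case case1 --task case --out results/
akiattn impact --model model/ --features features.parquet --labels labels.csv --out report/
```

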