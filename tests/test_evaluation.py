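"""Splits, metrics, and the experiment driver."""

import numpy as np
import pandas as pd
import pytest

from akiattn.evaluation import (
    baseline_comparators,
    compute_metrics,
    multiclass_metrics,
    run_experiment,
    stratified_split,
)
from akiattn.synthetic import SyntheticCohortSpec, generate_cohort


def pairwise_auc(y, p):
    """Exhaustive pairwise rank statistic with half-credit for ties."""
    pos = [pi for pi, yi in zip(p, y) if yi == 1]
    neg = [pi for pi, yi in zip(p, y) if yi == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


# -------------------------------------------------------------------- metrics

def test_auc_matches_pairwise_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(10, 200))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        p = np.round(rng.random(n), 2)  # coarse grid forces ties
        m = compute_metrics(p, y)
        assert m["auc"] == pytest.approx(pairwise_auc(y, p), abs=1e-12)


def test_metric_edge_cases():
    assert compute_metrics([0.9, 0.1, 0.8, 0.2], [1, 0, 1, 0]) == {
        "sensitivity": 1.0,
        "specificity": 1.0,
        "auc": 1.0,
    }
    m = compute_metrics([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
    assert m["auc"] == 0.5  # fully tied ranks
    with pytest.raises(ValueError, match="single class"):
        compute_metrics([0.5, 0.6], [1, 1])


def test_sensitivity_specificity_at_threshold():
    m = compute_metrics([0.7, 0.4, 0.55, 0.2], [1, 1, 0, 0], threshold=0.5)
    assert m["sensitivity"] == 0.5  # one of two positives exceeds 0.5
    assert m["specificity"] == 0.5


def test_multiclass_one_vs_rest():
    proba = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
    out = multiclass_metrics(proba, np.array([0, 1, 2]), np.array([0, 1, 2]))
    assert (out["auc"] == 1.0).all() and len(out) == 3


# --------------------------------------------------------------------- splits

def test_exact_stratified_allocation():
    strata = [1] * 30 + [0] * 70
    tr, va, te = stratified_split(strata, (8, 1, 1), seed=0)
    assert len(tr) == 80 and len(va) == 10 and len(te) == 10
    y = np.array(strata)
    assert y[te].sum() == 3 and y[va].sum() == 3  # 3/10 AKI in each holdout


def test_split_reproducible_and_partition(rng):
    strata = list(rng.integers(0, 2, 57))
    a = stratified_split(strata, seed=4)
    b = stratified_split(strata, seed=4)
    for x, y in zip(a, b):
        assert np.array_equal(x, y)
    allidx = np.concatenate(a)
    assert sorted(allidx) == list(range(57))  # disjoint and exhaustive


def test_split_invariant_to_input_order(rng):
    n = 60
    ids = np.arange(100, 100 + n)
    strata = list(rng.integers(0, 2, n))
    perm = rng.permutation(n)
    base = stratified_split(strata, seed=1, stay_ids=ids)
    shuf = stratified_split([strata[i] for i in perm], seed=1, stay_ids=ids[perm])
    base_ids = [sorted(ids[s]) for s in base]
    shuf_ids = [sorted(ids[perm][s]) for s in shuf]
    assert base_ids == shuf_ids


def test_split_small_stratum_falls_back():
    strata = [(0, 0, -1)] * 48 + [(1, 3, 1)] * 2  # joint stratum of size 2
    with pytest.warns(UserWarning, match="stratum"):
        tr, va, te = stratified_split(strata, seed=0)
    assert len(tr) + len(va) + len(te) == 50


def test_split_rejects_tiny_cohorts():
    with pytest.raises(ValueError):
        stratified_split([0, 1] * 4)


# ------------------------------------------------------------------ baselines

def test_baselines_fit_and_are_deterministic(rng):
    X = rng.random((80, 6))
    y = (X[:, 0] > 0.5).astype(int)
    for which in ("LR", "RF", "GBT"):
        a = baseline_comparators(X, y, which, seed=0).predict_proba(X)
        b = baseline_comparators(X, y, which, seed=0).predict_proba(X)
        assert np.allclose(a, b)
    with pytest.raises(ValueError, match="unknown baseline"):
        baseline_comparators(X, y, "SVM")


# ----------------------------------------------------------------- experiment

@pytest.fixture(scope="module")
def tiny_result():
    spec = SyntheticCohortSpec(n_stays=150)
    cohort = generate_cohort(spec, 2)
    return run_experiment(
        cohort,
        case="case1",
        tasks=("case",),
        seeds=[0, 1],
        epochs=3,
        tcn_epochs=2,
        baselines=("LR",),
        predictor_params={"hidden_size": 16, "decoder_hidden": 32, "batch_size": 32},
    )


def test_experiment_aggregates_mean_sd(tiny_result):
    m = tiny_result.metrics
    case_rows = m[(m.task == "case")]
    assert set(case_rows.metric) == {"specificity", "sensitivity", "auc"}
    assert (case_rows["sd"] >= 0).all()
    assert ((m["mean"] >= 0) & (m["mean"] <= 1)).all()
    assert "baseline_LR" in set(m.task)


def test_experiment_manifest_records_conditions(tiny_result):
    man = tiny_result.manifest
    assert man["seeds"] == [0, 1]
    assert man["case"] == "case1"
    assert "filter_report" in man and "schema_hash" in man


def test_single_repeat_has_zero_sd():
    spec = SyntheticCohortSpec(n_stays=150)
    cohort = generate_cohort(spec, 2)
    res = run_experiment(
        cohort,
        case="case1",
        tasks=("case",),
        seeds=[0],
        epochs=2,
        tcn_epochs=1,
        use_future_values=False,
        predictor_params={"hidden_size": 8, "decoder_hidden": 16, "batch_size": 32},
    )
    assert (res.metrics["sd"] == 0).all()


def test_experiment_saves_artifacts(tmp_path, tiny_result):
    tiny_result.save(tmp_path / "out")
    assert (tmp_path / "out" / "metrics.csv").exists()
    assert (tmp_path / "out" / "manifest.json").exists()


def test_experiment_stage_and_onset_heads():
    """Stage/onset heads train on AKI-positive stays and report one-vs-rest
    metrics for every class with both outcomes present in the test split."""
    spec = SyntheticCohortSpec(n_stays=400)
    cohort = generate_cohort(spec, 6)
    res = run_experiment(
        cohort,
        case="case1",
        tasks=("stage", "onset"),
        seeds=[0],
        epochs=2,
        tcn_epochs=1,
        use_future_values=False,
        predictor_params={"hidden_size": 8, "decoder_hidden": 16, "batch_size": 32},
    )
    m = res.metrics
    assert set(m.task) <= {"stage", "onset"}
    if len(m):
        assert ((m["mean"] >= 0) & (m["mean"] <= 1)).all()
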