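"""Experiment orchestration: splits, metrics, end-to-end runs, baselines.

The three experimental settings share one protocol: stays are split
8:1:1 into train/validation/test with every label stratum (AKI case, stage,
onset interval) kept at its global proportion; the normalizer is fitted on
the training split only; one TCN per temporal channel forecasts the future
values; the attention predictor is trained per task; and specificity,
sensitivity and AUC are reported as mean +/- standard deviation over
repeated reseeded splits and trainings.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .attention import AttentionAKIClassifier, threshold_decision
from .kdigo import EXPERIMENTAL_SCHEMES, IntervalScheme
from .pipeline import (
    Normalizer,
    PatientStay,
    assemble_input_sequence,
    filter_cohort,
    impute_missing,
    order_temporal,
)
from .schema import FeatureSchema, default_schema
from .synthetic import GeneratedStay, label_generated
from .tcn import TCNForecaster

__all__ = [
    "stratified_split",
    "compute_metrics",
    "run_experiment",
    "baseline_comparators",
    "ExperimentResult",
]

log = logging.getLogger("akiattn")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def _allocate(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n items over len(ratios) buckets."""
    total = sum(ratios)
    ideal = [n * r / total for r in ratios]
    base = [int(np.floor(x)) for x in ideal]
    rem = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: (ideal[i] - base[i], -i), reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


def stratified_split(
    strata,
    ratios: tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
    stay_ids=None,
    min_stratum: int = 3,
):
    """8:1:1 stratified split with exact largest-remainder allocation.

    ``strata`` is a sequence of hashable stratum keys (e.g. ``(is_aki,
    stage, onset_interval)`` tuples).  Any stratum smaller than
    ``min_stratum`` triggers a fallback to coarser stratification (the first
    element of the key, normally the AKI case flag) with a warning.
    Members are canonically sorted by ``stay_ids`` (or input position) before
    shuffling, so the split depends only on ids, strata and seed.

    Returns three disjoint, exhaustive index arrays (train, val, test).
    """
    strata = list(strata)
    n = len(strata)
    if n < 10:
        raise ValueError("need at least 10 stays to split 8:1:1")
    keys = [k if isinstance(k, tuple) else (k,) for k in strata]
    counts: dict = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    if min(counts.values()) < min_stratum and any(len(k) > 1 for k in keys):
        warnings.warn(
            "stratum too small for joint stratification; falling back to the "
            "leading stratum component",
            stacklevel=2,
        )
        return stratified_split(
            [k[0] for k in keys], ratios, seed, stay_ids, min_stratum=1
        )
    ids = np.asarray(stay_ids) if stay_ids is not None else np.arange(n)
    rng = np.random.default_rng(seed)
    splits: list[list[int]] = [[], [], []]
    for key in sorted(counts):
        members = [i for i, k in enumerate(keys) if k == key]
        members = [members[j] for j in np.argsort(ids[members], kind="stable")]
        members = [members[j] for j in rng.permutation(len(members))]
        n_tr, n_val, n_te = _allocate(len(members), ratios)
        splits[0] += members[:n_tr]
        splits[1] += members[n_tr : n_tr + n_val]
        splits[2] += members[n_tr + n_val :]
    return tuple(np.sort(np.array(s, dtype=int)) for s in splits)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> dict[str, float]:
    """Specificity, sensitivity and AUC for one binary task.

    Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) at the decision
    threshold (strict >); AUC is the rank statistic with tie correction.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    d = threshold_decision(p, threshold)
    tp = int(np.sum((d == 1) & (y == 1)))
    tn = int(np.sum((d == 0) & (y == 0)))
    fp = int(np.sum((d == 1) & (y == 0)))
    fn = int(np.sum((d == 0) & (y == 1)))
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "auc": float(roc_auc_score(y, p)),
    }


def multiclass_metrics(
    proba: np.ndarray, labels: np.ndarray, classes: np.ndarray, threshold: float = 0.5
) -> pd.DataFrame:
    """One-vs-rest metrics per class for the stage / onset tasks."""
    rows = []
    for ci, cls in enumerate(classes):
        y = (np.asarray(labels) == cls).astype(int)
        if len(np.unique(y)) < 2:
            continue
        m = compute_metrics(proba[:, ci], y, threshold)
        rows.append({"class": cls, **m})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Aggregated mean +/- sd metrics plus per-repeat artifacts."""

    case: str
    metrics: pd.DataFrame
    per_repeat: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1, default=str))


def _collect_channel_series(
    stays: list[PatientStay],
    schema: FeatureSchema,
    normalizer: Normalizer,
    observation_end: float,
) -> dict[str, list[np.ndarray]]:
    """Per-channel normalized observation-interval series, stay-aligned."""
    out: dict[str, list[np.ndarray]] = {ch: [] for ch in schema.temporal_channels}
    for stay in stays:
        for ch in schema.temporal_channels:
            t, v = stay.channel(ch)
            inside = t <= observation_end + 1e-9
            t, v = order_temporal(t[inside], np.asarray(v)[inside])
            out[ch].append(normalizer.transform(ch, v))
    return out


def prepare_design(
    stays: list[PatientStay],
    labels: pd.DataFrame,
    scheme: IntervalScheme,
    schema: FeatureSchema | None = None,
) -> tuple[list[PatientStay], pd.DataFrame, dict]:
    """Filter the cohort and align labels; returns kept stays + label rows."""
    schema = schema or default_schema()
    excluded = {
        int(r.stay_id): r.excluded
        for r in labels.itertuples()
        if r.excluded
    }
    kept, report = filter_cohort(stays, excluded)
    kept_imputed = []
    for stay in kept:
        imp, _ = impute_missing(schema, stay, scheme.observation_hours)
        kept_imputed.append(imp)
    lab = labels.set_index("stay_id")
    rows = lab.loc[[s.stay_id for s in kept_imputed]].reset_index()
    return kept_imputed, rows, report


def run_experiment(
    stays: list[PatientStay] | list[GeneratedStay],
    case: str = "case1",
    labels: pd.DataFrame | None = None,
    schema: FeatureSchema | None = None,
    tasks: tuple[str, ...] = ("case",),
    n_repeats: int = 5,
    seeds: list[int] | None = None,
    epochs: int = 1000,
    tcn_epochs: int = 100,
    use_future_values: bool = True,
    baselines: tuple[str, ...] = (),
    threshold: float = 0.5,
    predictor_params: dict | None = None,
    tcn_params: dict | None = None,
    external_eval=None,
    out_dir: str | Path | None = None,
) -> ExperimentResult:
    """Run the full pipeline for one experimental case.

    For each repeat: split 8:1:1 -> fit normalizer on train -> train the
    per-channel TCNs -> assemble sequences (forecast future values when
    ``use_future_values``) -> train the predictor per task -> evaluate on
    the test split.  Metrics aggregate as mean +/- sd over repeats.

    ``external_eval`` may name a second, fully held-out cohort (a list of
    stays or generated stays, or a ``(stays, labels)`` pair); the fitted
    pipeline of every repeat is additionally evaluated on it (case task),
    reported as ``case_external``.
    """
    t_start = time.time()
    scheme = EXPERIMENTAL_SCHEMES[case]
    schema = schema or default_schema()
    if stays and isinstance(stays[0], GeneratedStay):
        if labels is None:
            labels = label_generated(stays, scheme)
        stays = [g.stay for g in stays]
    if labels is None:
        raise ValueError("labels are required for non-generated cohorts")
    seeds = seeds if seeds is not None else list(range(n_repeats))

    predictor_params = predictor_params or {}
    tcn_params = tcn_params or {}
    kept, lab, filter_report = prepare_design(stays, labels, scheme, schema)
    log.info("cohort: %d stays kept, exclusions %s", len(kept), filter_report)
    ext_kept, ext_y = None, None
    if external_eval is not None:
        ext_stays, ext_labels = (
            external_eval if isinstance(external_eval, tuple) else (external_eval, None)
        )
        if ext_stays and isinstance(ext_stays[0], GeneratedStay):
            if ext_labels is None:
                ext_labels = label_generated(ext_stays, scheme)
            ext_stays = [g.stay for g in ext_stays]
        ext_kept, ext_lab, _ = prepare_design(ext_stays, ext_labels, scheme, schema)
        ext_y = ext_lab["is_aki"].to_numpy().astype(int)
    y_case = lab["is_aki"].to_numpy().astype(int)
    stage = lab["stage"].to_numpy()
    onset_idx = lab["onset_interval_index"].to_numpy()
    strata = [
        (int(a), int(s), int(o) if pd.notna(o) else -1)
        for a, s, o in zip(y_case, stage, onset_idx)
    ]
    stay_ids = [s.stay_id for s in kept]

    per_repeat: list[dict] = []
    for seed in seeds:
        t0 = time.time()
        tr, va, te = stratified_split(strata, (8, 1, 1), seed=seed, stay_ids=stay_ids)
        trval = np.sort(np.concatenate((tr, va)))

        normalizer = Normalizer()
        obs: dict[str, list] = {ch: [] for ch in schema.temporal_channels}
        for i in tr:
            for ch in schema.temporal_channels:
                t, v = kept[i].channel(ch)
                obs[ch].extend(np.asarray(v)[t <= scheme.observation_hours + 1e-9])
        normalizer.fit({ch: np.asarray(v) for ch, v in obs.items()})
        for const in ("age", "bmi"):
            normalizer.fit({const: np.array([getattr(kept[i], const) for i in tr])})

        series = _collect_channel_series(kept, schema, normalizer, scheme.observation_hours)
        ext_series = (
            _collect_channel_series(ext_kept, schema, normalizer, scheme.observation_hours)
            if ext_kept is not None
            else None
        )
        future: list[dict[str, float]] = [dict() for _ in kept]
        ext_future: list[dict[str, float]] = [dict() for _ in (ext_kept or [])]
        if use_future_values:
            for ch in schema.temporal_channels:
                train_series = [series[ch][i] for i in tr if len(series[ch][i]) >= 2]
                if not train_series:
                    continue
                tcn = TCNForecaster(epochs=tcn_epochs, random_state=seed, **tcn_params)
                tcn.fit(train_series)
                preds = tcn.predict(series[ch])
                for i, p in enumerate(preds):
                    future[i][ch] = float(p)
                if ext_series is not None:
                    for i, p in enumerate(tcn.predict(ext_series[ch])):
                        ext_future[i][ch] = float(p)

        X = np.stack(
            [
                assemble_input_sequence(kept[i], schema, normalizer, future[i])
                for i in range(len(kept))
            ]
        )
        repeat = {"seed": seed, "n_train": len(tr), "n_val": len(va), "n_test": len(te)}
        for task in tasks:
            if task == "case":
                Xtr, ytr = X[trval], y_case[trval]
                model = AttentionAKIClassifier(
                    task="case", epochs=epochs, random_state=seed,
                    threshold=threshold, **predictor_params
                )
                model.fit(Xtr, ytr)
                p_test = model.predict_proba(X[te])[:, 1]
                repeat["case"] = compute_metrics(p_test, y_case[te], threshold)
                repeat["case_model"] = model
                repeat["X_test"], repeat["y_test"] = X[te], y_case[te]
                if ext_kept is not None:
                    X_ext = np.stack(
                        [
                            assemble_input_sequence(s_, schema, normalizer, f_)
                            for s_, f_ in zip(ext_kept, ext_future)
                        ]
                    )
                    p_ext = model.predict_proba(X_ext)[:, 1]
                    repeat["case_external"] = compute_metrics(p_ext, ext_y, threshold)
            else:
                # stage / onset heads are trained on AKI-positive stays only
                pos = y_case == 1
                target = stage if task == "stage" else onset_idx
                sel_tr = np.array([i for i in trval if pos[i]])
                sel_te = np.array([i for i in te if pos[i]])
                if len(sel_tr) == 0 or len(sel_te) == 0:
                    continue
                ytr = target[sel_tr].astype(int)
                if len(np.unique(ytr)) < 2:
                    continue
                model = AttentionAKIClassifier(
                    task=task, epochs=epochs, random_state=seed,
                    threshold=threshold, **predictor_params
                )
                model.fit(X[sel_tr], ytr)
                proba = model.predict_proba(X[sel_te])
                repeat[task] = multiclass_metrics(
                    proba, target[sel_te].astype(int), model.classes_, threshold
                )
        for name in baselines:
            bl = baseline_comparators(X[trval], y_case[trval], name, seed=seed)
            p_test = bl.predict_proba(X[te])[:, 1]
            repeat[f"baseline_{name}"] = compute_metrics(p_test, y_case[te], threshold)
        repeat["runtime_s"] = time.time() - t0
        log.info("repeat seed=%s done in %.1fs", seed, repeat["runtime_s"])
        per_repeat.append(repeat)

    metrics = _aggregate(per_repeat, tasks, baselines)
    result = ExperimentResult(
        case=case,
        metrics=metrics,
        per_repeat=per_repeat,
        manifest={
            "case": case,
            "seeds": seeds,
            "n_stays": len(kept),
            "filter_report": filter_report,
            "epochs": epochs,
            "tcn_epochs": tcn_epochs,
            "use_future_values": use_future_values,
            "schema_hash": schema.hash(),
            "runtime_s": time.time() - t_start,
        },
    )
    if out_dir is not None:
        result.save(out_dir)
    return result


def _aggregate(per_repeat: list[dict], tasks, baselines) -> pd.DataFrame:
    rows = []
    keys = [t for t in tasks] + [f"baseline_{b}" for b in baselines]
    for key in keys:
        entries = [r[key] for r in per_repeat if key in r]
        if not entries:
            continue
        if isinstance(entries[0], dict):
            for metric in ("specificity", "sensitivity", "auc"):
                vals = [e[metric] for e in entries]
                rows.append(
                    {
                        "task": key, "class": "", "metric": metric,
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=0)) if len(vals) > 1 else 0.0,
                    }
                )
        else:  # per-class DataFrames
            all_classes = sorted({c for e in entries for c in e["class"]})
            for cls in all_classes:
                for metric in ("specificity", "sensitivity", "auc"):
                    vals = [
                        float(e.loc[e["class"] == cls, metric].iloc[0])
                        for e in entries
                        if (e["class"] == cls).any()
                    ]
                    rows.append(
                        {
                            "task": key, "class": str(cls), "metric": metric,
                            "mean": float(np.mean(vals)),
                            "sd": float(np.std(vals, ddof=0)) if len(vals) > 1 else 0.0,
                        }
                    )
    return pd.DataFrame(rows)


def baseline_comparators(X: np.ndarray, y: np.ndarray, which: str, seed: int = 0):
    """Off-the-shelf comparison classifiers on the flattened feature table.

    These are standard scikit-learn models included for comparison rows
    only; nothing novel lives here.
    """
    which = which.upper()
    if which == "LR":
        model = LogisticRegression(max_iter=2000, random_state=seed)
    elif which == "RF":
        model = RandomForestClassifier(n_estimators=200, random_state=seed)
    elif which == "GBT":
        model = GradientBoostingClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown baseline {which!r}; use LR, RF or GBT")
    return model.fit(X, y)
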