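"""Two-step feature-impact analysis.

Step 1 — association tables: continuous lab/vital features are compared
between AKI and not-AKI stays by their mean normalized values (delta =
mean_aki - mean_not, ratio = 100 * delta / mean_aki); categorical features
(comorbidities, medication classes) by contingency percentages
100 * n_aki / (n_aki + n_not).

Step 2 — attention-weight importance: the per-position softmax weights of a
trained case model are averaged position-wise over an evaluation set, mapped
back to feature names through the schema, and reported per group
(comorbidity / medication / lab-test-and-vital-sign) in descending order.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .schema import FeatureSchema

__all__ = [
    "AssociationRow",
    "CategoricalAssociationRow",
    "association_table",
    "categorical_association",
    "attention_importance",
    "plot_importance",
]


@dataclass
class AssociationRow:
    feature: str
    mean_aki: float
    mean_not: float

    @property
    def delta(self) -> float:
        return self.mean_aki - self.mean_not

    @property
    def ratio_pct(self) -> float | None:
        """100 * delta / mean_aki; None (flagged) when mean_aki is zero."""
        if self.mean_aki == 0:
            return None
        return 100.0 * self.delta / self.mean_aki


@dataclass
class CategoricalAssociationRow:
    category: str
    n_aki: int
    n_not: int

    @property
    def pct_aki(self) -> float:
        """100 * n_aki / (n_aki + n_not), two decimals, half-up rounding."""
        total = self.n_aki + self.n_not
        if total == 0:
            raise ZeroDivisionError(f"category {self.category!r} has zero total")
        exact = Decimal(100 * self.n_aki) / Decimal(total)
        return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    @property
    def pct_not(self) -> float:
        return float(
            (Decimal(100) - Decimal(str(self.pct_aki))).quantize(Decimal("0.01"))
        )


def association_table(
    features: pd.DataFrame, labels: np.ndarray, feature_names: list[str] | None = None
) -> list[AssociationRow]:
    """Continuous-feature association rows, sorted by ratio descending.

    ``features`` holds one normalized summary value per stay per feature
    (the pipeline uses the last observed normalized value in the observation
    interval); ``labels`` is the binary AKI case vector.
    """
    labels = np.asarray(labels).astype(bool)
    names = feature_names or list(features.columns)
    if labels.sum() == 0 or (~labels).sum() == 0:
        group = "AKI" if labels.sum() == 0 else "not-AKI"
        raise ValueError(f"empty group: no {group} stays in the cohort")
    rows = [
        AssociationRow(
            name,
            float(features[name].to_numpy()[labels].mean()),
            float(features[name].to_numpy()[~labels].mean()),
        )
        for name in names
    ]
    return sorted(
        rows, key=lambda r: -np.inf if r.ratio_pct is None else r.ratio_pct, reverse=True
    )


def categorical_association(
    counts: dict[str, tuple[int, int]]
) -> list[CategoricalAssociationRow]:
    """Contingency rows from per-category (n_aki, n_not) counts, sorted by
    AKI percentage descending; zero-total categories are flagged and
    excluded from the sort order (appended last)."""
    rows, flagged = [], []
    for name, (n_aki, n_not) in counts.items():
        if n_aki < 0 or n_not < 0:
            raise ValueError(f"negative count for {name!r}")
        row = CategoricalAssociationRow(name, int(n_aki), int(n_not))
        (flagged if n_aki + n_not == 0 else rows).append(row)
    rows.sort(key=lambda r: r.pct_aki, reverse=True)
    return rows + flagged


@dataclass
class ImpactWeight:
    feature: str
    group: str
    mean_weight: float


def attention_importance(
    model, X: np.ndarray, schema: FeatureSchema
) -> dict[str, list[ImpactWeight]]:
    """Mean attention weight per schema position over an evaluation set.

    Each stay's softmax weights sum to 1 across encoder positions; the mean
    over stays is grouped (comorbidity / medication / lab-test-and-vital-
    sign / demographic) and each group is sorted descending.  Invariant to
    stay ordering.
    """
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValueError("evaluation set is empty")
    if X.shape[1] != len(schema):
        raise ValueError("schema length does not match model input length")
    weights = model.attention_weights(X)  # (n, T)
    mean_w = weights.mean(axis=0)
    groups: dict[str, list[ImpactWeight]] = {}
    for name, w in zip(schema.names, mean_w):
        grp = schema.group_of(name)
        groups.setdefault(grp, []).append(ImpactWeight(name, grp, float(w)))
    for grp in groups:
        groups[grp].sort(key=lambda iw: iw.mean_weight, reverse=True)
    return groups


def importance_frame(groups: dict[str, list[ImpactWeight]]) -> pd.DataFrame:
    records = [
        {"feature": iw.feature, "group": iw.group, "mean_weight": iw.mean_weight}
        for grp in sorted(groups)
        for iw in groups[grp]
    ]
    return pd.DataFrame(records)


def plot_importance(groups: dict[str, list[ImpactWeight]], path) -> None:
    """Grouped bar chart of mean attention weights (SVG/PNG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    show = {g: v for g, v in groups.items() if g != "demographic"}
    fig, axes = plt.subplots(1, max(len(show), 1), figsize=(4.5 * max(len(show), 1), 3.5))
    if len(show) == 1:
        axes = [axes]
    for ax, (grp, items) in zip(np.atleast_1d(axes), sorted(show.items())):
        names = [iw.feature.split(":", 1)[-1] for iw in items]
        vals = [iw.mean_weight for iw in items]
        ax.bar(range(len(vals)), vals)
        ax.set_xticks(range(len(vals)))
        ax.set_xticklabels(names, rotation=90, fontsize=7)
        ax.set_title(grp)
        ax.set_ylabel("mean attention weight")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
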