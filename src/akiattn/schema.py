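"""Feature schema: the ordered 50-element input layout of the predictor.

The predictor consumes one fixed-length sequence per ICU stay.  Each position
is one feature: a normalized continuous value (constant demographics/BMI or
the forecast future value of a temporal lab/vital channel) or one slot of a
one-hot / multi-hot block (ethnicity, medication ATC classes, comorbidities).

The shipped default schema pins exactly 50 positions:

====================  =====
block                 slots
====================  =====
age, gender            2
ethnicity one-hot      2
BMI                    1
lab/vital channels    26
medication classes     8
comorbidities         11
====================  =====

The source feature list enumerates a few more raw items than 50 (mass and
height are folded into BMI, laboratory and fingerstick glucose are merged,
and the ethnicity vocabulary is collapsed to white/other); the schema is
fully overridable in configuration for other layouts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

__all__ = [
    "FeatureSpec",
    "FeatureSchema",
    "default_schema",
    "COMORBIDITY_KEYWORDS",
    "ATC_CATEGORIES",
    "TEMPORAL_CHANNELS",
]

#: the 11 comorbidity keywords retrieved from admission notes, in block order:
#: (slot name, substring matched case-insensitively)
COMORBIDITY_KEYWORDS: list[tuple[str, str]] = [
    ("chf", "congestive heart failure"),
    ("peripheral_vascular", "peripheral vascular"),
    ("hypertension", "hypertension"),
    ("diabetes", "diabetes"),
    ("liver_disease", "liver disease"),
    ("mi", "myocardial infarction"),
    ("cad", "coronary artery disease"),
    ("cirrhosis", "cirrhosis"),
    ("jaundice", "jaundice"),
    ("sleep_apnea", "sleep apnea"),
    ("uti", "urinary tract infection"),
]

#: medication classes (ATC 2nd level; V08 keys contrast media, which has no
#: single therapeutic letter class)
ATC_CATEGORIES: dict[str, str] = {
    "A10": "drugs used in diabetes",
    "B01": "antithrombotic agents",
    "C02": "antihypertensives",
    "C03": "diuretics",
    "C09": "agents acting on the renin-angiotensin system",
    "C10": "lipid-lowering medication",
    "M01": "non-steroidal anti-inflammatory drugs",
    "V08": "contrast media",
}

# temporal lab/vital channels: name -> (plausible min, plausible max, normal default)
# bounds are generation/config ranges; normalization bounds are re-fit on
# training data by the pipeline Normalizer.
TEMPORAL_CHANNELS: dict[str, tuple[float, float, float]] = {
    "lactate": (0.3, 20.0, 1.0),
    "creatinine": (0.2, 15.0, 1.0),
    "bun": (2.0, 150.0, 15.0),
    "pt": (8.0, 60.0, 12.0),
    "ptt": (18.0, 150.0, 30.0),
    "glucose": (30.0, 1000.0, 100.0),
    "anion_gap": (2.0, 40.0, 12.0),
    "potassium": (2.0, 9.0, 4.0),
    "bilirubin": (0.1, 40.0, 0.7),
    "wbc": (0.5, 80.0, 8.0),
    "chloride": (70.0, 130.0, 102.0),
    "spo2": (50.0, 100.0, 97.0),
    "temperature": (32.0, 42.0, 36.8),
    "sodium": (110.0, 170.0, 140.0),
    "sbp": (50.0, 250.0, 120.0),
    "bicarbonate": (5.0, 50.0, 24.0),
    "albumin": (1.0, 6.0, 4.0),
    "resp_rate": (4.0, 60.0, 16.0),
    "mbp": (30.0, 180.0, 85.0),
    "heart_rate": (20.0, 220.0, 80.0),
    "dbp": (20.0, 150.0, 70.0),
    "platelet": (5.0, 1200.0, 250.0),
    "hemoglobin": (3.0, 20.0, 13.0),
    "hematocrit": (10.0, 60.0, 40.0),
    "urine_rate": (0.0, 4.0, 1.0),
    "inr": (0.5, 12.0, 1.1),
}

KIND_CONSTANT = "constant-continuous"
KIND_BINARY = "constant-categorical"
KIND_TEMPORAL = "temporal-continuous"


@dataclass(frozen=True)
class FeatureSpec:
    """One schema position."""

    name: str
    kind: str  # constant-continuous | constant-categorical | temporal-continuous
    bounds: tuple[float, float] = (0.0, 1.0)
    default: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (KIND_CONSTANT, KIND_BINARY, KIND_TEMPORAL):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError(f"{self.name}: bounds min must be < max")


@dataclass
class FeatureSchema:
    """Ordered feature list; its length defines the encoder input length."""

    features: list[FeatureSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def temporal_channels(self) -> list[str]:
        return [f.name for f in self.features if f.kind == KIND_TEMPORAL]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def spec(self, name: str) -> FeatureSpec:
        return self.features[self.index(name)]

    def group_of(self, name: str) -> str:
        """Impact-analysis group of a feature position."""
        if name.startswith("com:"):
            return "comorbidity"
        if name.startswith("med:"):
            return "medication"
        if name in TEMPORAL_CHANNELS:
            return "lab-test-and-vital-sign"
        return "demographic"

    def hash(self) -> str:
        payload = json.dumps(
            [(f.name, f.kind, list(f.bounds), f.default) for f in self.features]
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> list[dict]:
        return [
            {"name": f.name, "kind": f.kind, "bounds": list(f.bounds), "default": f.default}
            for f in self.features
        ]

    @classmethod
    def from_dict(cls, entries: list[dict]) -> "FeatureSchema":
        return cls(
            [
                FeatureSpec(e["name"], e["kind"], tuple(e["bounds"]), e["default"])
                for e in entries
            ]
        )


def default_schema(ethnicity_vocab: tuple[str, ...] = ("white",)) -> FeatureSchema:
    """The pinned 50-position default layout (see module docstring).

    ``ethnicity_vocab`` lists explicit categories; an ``other`` bucket is
    always appended, so the default vocabulary of one yields a 2-slot block.
    """
    feats: list[FeatureSpec] = [
        FeatureSpec("age", KIND_CONSTANT, (18.0, 95.0), 65.0),
        FeatureSpec("gender_male", KIND_BINARY, default=0.0),
    ]
    for eth in tuple(ethnicity_vocab) + ("other",):
        feats.append(FeatureSpec(f"ethnicity={eth}", KIND_BINARY))
    feats.append(FeatureSpec("bmi", KIND_CONSTANT, (12.0, 60.0), 26.0))
    for name, (lo, hi, normal) in TEMPORAL_CHANNELS.items():
        feats.append(FeatureSpec(name, KIND_TEMPORAL, (lo, hi), normal))
    for atc in ATC_CATEGORIES:
        feats.append(FeatureSpec(f"med:{atc}", KIND_BINARY))
    for com, _ in COMORBIDITY_KEYWORDS:
        feats.append(FeatureSpec(f"com:{com}", KIND_BINARY))
    return FeatureSchema(feats)
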