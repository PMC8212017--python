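"""Cohort pipeline: filter, map, impute, normalize and encode ICU stays.

Transforms raw MIMIC-shaped tables into the fixed-length, [0,1]-normalized
feature sequences the predictor consumes.  The stages are

1. exclusion filtering (AKI already in the admission note, no labs, no note,
   AKI during the observation interval),
2. NDC -> ATC drug-class mapping,
3. comorbidity keyword retrieval from admission notes (multi-hot),
4. default-normal-value imputation of unobserved channels,
5. min-max normalization fitted on the training split only, and
6. assembly of the per-stay input sequence in schema order, with temporal
   channels contributing their (forecast) future values.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    COMORBIDITY_KEYWORDS,
    KIND_CONSTANT,
    KIND_TEMPORAL,
    FeatureSchema,
)

__all__ = [
    "PatientStay",
    "Normalizer",
    "NdcAtcMap",
    "normalize_linear",
    "extract_comorbidities",
    "map_ndc_to_atc",
    "filter_cohort",
    "impute_missing",
    "order_temporal",
    "assemble_input_sequence",
    "read_cohort_dir",
    "write_features",
    "read_features",
]

# phrases that mark an AKI diagnosis already present at admission;
# "aki" is matched on word boundaries so e.g. "taking" never matches
_AKI_NOTE_PATTERNS = re.compile(
    r"\b(acute kidney injury|acute renal failure|aki)\b", re.IGNORECASE
)


@dataclass
class PatientStay:
    """One ICU stay: demographics, temporal channels, exposures, note text."""

    stay_id: int
    age: float = np.nan
    gender: str = ""
    ethnicity: str = ""
    weight_kg: float = np.nan
    height_m: float = np.nan
    bmi: float = np.nan
    channels: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    atc_codes: set[str] = field(default_factory=set)
    note_text: str = ""
    rrt: bool = False
    egfr: float | None = None

    def __post_init__(self) -> None:
        if (
            np.isnan(self.bmi)
            and np.isfinite(self.weight_kg)
            and np.isfinite(self.height_m)
            and self.height_m > 0
        ):
            self.bmi = self.weight_kg / self.height_m**2

    def channel(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        return self.channels.get(name, (np.empty(0), np.empty(0)))

    def has_labs(self) -> bool:
        return any(len(t) for t, _ in self.channels.values())


def normalize_linear(x, lo: float, hi: float):
    """Linear min-max normalization onto [0,1], clipping out-of-bound values.

    A degenerate feature (hi == lo) maps everything to 0.5 with a warning.
    """
    if hi < lo:
        raise ValueError("max must be >= min")
    if hi == lo:
        warnings.warn("degenerate feature: max == min; returning 0.5", stacklevel=2)
        return np.full_like(np.asarray(x, dtype=float), 0.5) if np.ndim(x) else 0.5
    return np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


class Normalizer:
    """Per-feature min-max bounds, fitted on the training split only."""

    def __init__(self, bounds: dict[str, tuple[float, float]] | None = None):
        self.bounds: dict[str, tuple[float, float]] = dict(bounds or {})

    def fit(self, observations: dict[str, np.ndarray]) -> "Normalizer":
        """Fit bounds from raw training-split observations per feature."""
        for name, vals in observations.items():
            vals = np.asarray(vals, dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            self.bounds[name] = (float(np.min(vals)), float(np.max(vals)))
        return self

    def transform(self, name: str, x):
        if name not in self.bounds:
            raise KeyError(f"no fitted bounds for feature {name!r}")
        lo, hi = self.bounds[name]
        return normalize_linear(x, lo, hi)

    def inverse(self, name: str, x):
        lo, hi = self.bounds[name]
        return lo + np.asarray(x, dtype=float) * (hi - lo)

    def to_json(self) -> str:
        return json.dumps({k: list(v) for k, v in sorted(self.bounds.items())})

    @classmethod
    def from_json(cls, text: str) -> "Normalizer":
        return cls({k: tuple(v) for k, v in json.loads(text).items()})


def extract_comorbidities(
    note_text: str, keyword_lists: list[tuple[str, str]] | None = None
) -> np.ndarray:
    """Multi-hot comorbidity vector from an admission note.

    Position i is 1 iff keyword i occurs (case-insensitive substring) in the
    note.  Defaults to the 11 configured comorbidity keywords.
    """
    keywords = keyword_lists if keyword_lists is not None else COMORBIDITY_KEYWORDS
    note = (note_text or "").lower()
    return np.array([1.0 if kw.lower() in note else 0.0 for _, kw in keywords])


def _normalize_ndc(ndc: str) -> str | None:
    digits = re.sub(r"\D", "", str(ndc))
    if len(digits) not in (10, 11):
        return None
    return digits.zfill(11)


class NdcAtcMap:
    """NDC -> ATC category lookup backed by a two-column (ndc, atc) CSV.

    Ships with a small synthetic test-scale table covering the eight
    medication classes; pass ``path`` to substitute a real crosswalk.
    """

    def __init__(self, path: str | Path | None = None):
        if path is None:
            with resources.files("akiattn.data").joinpath("ndc_atc_synthetic.csv").open() as fh:
                table = pd.read_csv(fh, dtype=str)
        else:
            table = pd.read_csv(path, dtype=str)
        self._map: dict[str, set[str]] = {}
        for _, row in table.iterrows():
            key = _normalize_ndc(row["ndc"])
            if key is not None:
                self._map.setdefault(key, set()).add(row["atc"][:3].upper())
        self.unmapped_count = 0
        self.malformed_count = 0

    def ndc_codes_for(self, atc: str, exclusive: bool = False) -> list[str]:
        """NDC codes mapped to category ``atc`` (``exclusive``: only codes
        mapping to that single category)."""
        return sorted(
            k
            for k, v in self._map.items()
            if atc in v and (not exclusive or v == {atc})
        )

    def lookup(self, ndc: str) -> set[str]:
        key = _normalize_ndc(ndc)
        if key is None:
            warnings.warn(f"malformed NDC code {ndc!r}", stacklevel=2)
            self.malformed_count += 1
            return set()
        cats = self._map.get(key)
        if not cats:
            self.unmapped_count += 1
            return set()
        return set(cats)


def map_ndc_to_atc(ndc: str, mapping: NdcAtcMap) -> set[str]:
    """Map one NDC product code to its ATC category set (possibly empty)."""
    return mapping.lookup(ndc)


# exclusion rule identifiers, in application order
EXCLUSION_RULES = (
    "aki_in_admission_note",
    "no_lab_results",
    "no_admission_note",
    "aki_in_observation",
)


def filter_cohort(
    stays: list[PatientStay],
    observation_excluded: dict[int, str] | None = None,
) -> tuple[list[PatientStay], dict[str, int]]:
    """Apply the four cohort exclusion rules, preserving order.

    ``observation_excluded`` maps stay_id -> reason for stays whose KDIGO
    labeling found AKI already during the observation interval.  Each rule is
    tested independently, so a stay violating several rules increments every
    matching counter; ``total_excluded`` counts it once.
    """
    observation_excluded = observation_excluded or {}
    report = {rule: 0 for rule in EXCLUSION_RULES}
    report["total_excluded"] = 0
    kept: list[PatientStay] = []
    for stay in stays:
        violations = []
        if stay.note_text and _AKI_NOTE_PATTERNS.search(stay.note_text):
            violations.append("aki_in_admission_note")
        if not stay.has_labs():
            violations.append("no_lab_results")
        if not (stay.note_text or "").strip():
            violations.append("no_admission_note")
        if observation_excluded.get(stay.stay_id):
            violations.append("aki_in_observation")
        if violations:
            for rule in violations:
                report[rule] += 1
            report["total_excluded"] += 1
        else:
            kept.append(stay)
    return kept, report


def order_temporal(times: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stable sort by chart time; duplicate timestamps keep the last-written
    value (charting corrections overwrite)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(times, kind="stable")
    times, values = times[order], values[order]
    if len(times) > 1:
        # keep last occurrence of each timestamp
        last = np.concatenate((times[1:] != times[:-1], [True]))
        times, values = times[last], values[last]
    return times, values


def impute_missing(
    schema: FeatureSchema,
    stay: PatientStay,
    observation_end: float,
) -> tuple[PatientStay, list[str]]:
    """Impute unobserved features with their default normal values.

    A temporal channel with no observation inside the observation interval
    receives a single synthetic observation at the interval end; missing
    constants get their schema default.  Returns the (copied) stay and the
    list of imputed feature names.
    """
    imputed: list[str] = []
    channels = {}
    for spec in schema:
        if spec.kind != KIND_TEMPORAL:
            continue
        t, v = stay.channel(spec.name)
        inside = t <= observation_end + 1e-9
        if inside.any():
            channels[spec.name] = (t[inside], np.asarray(v)[inside])
        else:
            channels[spec.name] = (
                np.array([observation_end]),
                np.array([spec.default]),
            )
            imputed.append(spec.name)
    out = PatientStay(
        stay_id=stay.stay_id,
        age=stay.age,
        gender=stay.gender,
        ethnicity=stay.ethnicity,
        weight_kg=stay.weight_kg,
        height_m=stay.height_m,
        bmi=stay.bmi,
        channels=channels,
        atc_codes=set(stay.atc_codes),
        note_text=stay.note_text,
        rrt=stay.rrt,
        egfr=stay.egfr,
    )
    for const in ("age", "bmi"):
        if not np.isfinite(getattr(out, const)):
            try:
                setattr(out, const, schema.spec(const).default)
                imputed.append(const)
            except ValueError:
                raise KeyError(f"no configured default for constant feature {const!r}")
    return out, imputed


def _constant_value(stay: PatientStay, name: str, comorbidity_vec: np.ndarray) -> float:
    if name == "gender_male":
        return 1.0 if str(stay.gender).upper().startswith("M") else 0.0
    if name.startswith("ethnicity="):
        cat = name.split("=", 1)[1]
        eth = (stay.ethnicity or "other").strip().lower()
        return 1.0 if eth == cat else 0.0
    if name.startswith("med:"):
        return 1.0 if name.split(":", 1)[1] in stay.atc_codes else 0.0
    if name.startswith("com:"):
        idx = [c for c, _ in COMORBIDITY_KEYWORDS].index(name.split(":", 1)[1])
        return float(comorbidity_vec[idx])
    raise KeyError(name)


def assemble_input_sequence(
    stay: PatientStay,
    schema: FeatureSchema,
    normalizer: Normalizer,
    future_values: dict[str, float] | None = None,
) -> np.ndarray:
    """Build the encoder input: one element per schema feature, in schema
    order (never input dict order).

    Temporal features contribute their forecast future value (already
    normalized) when given in ``future_values``, otherwise the normalized
    last observed value.  Constants contribute normalized / one-hot values.
    """
    future_values = future_values or {}
    com = extract_comorbidities(stay.note_text)
    # the ethnicity "other" bucket: set when no explicit category matches
    eth_slots = [f.name for f in schema if f.name.startswith("ethnicity=")]
    explicit = [s for s in eth_slots if s != "ethnicity=other"]
    eth = (stay.ethnicity or "other").strip().lower()
    in_vocab = any(eth == s.split("=", 1)[1] for s in explicit)

    out = np.empty(len(schema))
    for i, spec in enumerate(schema):
        if spec.kind == KIND_TEMPORAL:
            if spec.name in future_values:
                out[i] = np.clip(future_values[spec.name], 0.0, 1.0)
            else:
                t, v = stay.channel(spec.name)
                if len(t) == 0:
                    raise ValueError(
                        f"stay {stay.stay_id}: channel {spec.name!r} unresolvable; "
                        "run impute_missing first"
                    )
                t, v = order_temporal(t, v)
                out[i] = normalizer.transform(spec.name, v[-1])
        elif spec.kind == KIND_CONSTANT:
            val = getattr(stay, spec.name if spec.name != "bmi" else "bmi", np.nan)
            if not np.isfinite(val):
                raise ValueError(f"stay {stay.stay_id}: constant {spec.name!r} missing")
            out[i] = normalizer.transform(spec.name, val)
        else:  # binary
            if spec.name == "ethnicity=other":
                out[i] = 0.0 if in_vocab else 1.0
            else:
                out[i] = _constant_value(stay, spec.name, com)
    return out


# ---------------------------------------------------------------------------
# MIMIC-shaped table I/O
# ---------------------------------------------------------------------------

#: minimal column subsets read from each table (gzip-transparent via pandas)
TABLE_COLUMNS = {
    "PATIENTS": ["SUBJECT_ID", "GENDER", "AGE_YEARS"],
    "ADMISSIONS": ["SUBJECT_ID", "HADM_ID", "ETHNICITY"],
    "ICUSTAYS": ["ICUSTAY_ID", "HADM_ID", "SUBJECT_ID", "WEIGHT_KG", "HEIGHT_M", "RRT"],
    "LABEVENTS": ["ICUSTAY_ID", "CHANNEL", "CHARTTIME_HOURS", "VALUENUM", "VALUEUOM"],
    "CHARTEVENTS": ["ICUSTAY_ID", "CHANNEL", "CHARTTIME_HOURS", "VALUENUM", "VALUEUOM"],
    "PRESCRIPTIONS": ["ICUSTAY_ID", "NDC"],
    "NOTEEVENTS": ["ICUSTAY_ID", "CATEGORY", "TEXT"],
}


def _read_table(dirpath: Path, name: str) -> pd.DataFrame:
    dtypes = {"NDC": str, "TEXT": str} if name in ("PRESCRIPTIONS", "NOTEEVENTS") else None
    for suffix in (".csv", ".csv.gz"):
        path = dirpath / f"{name}{suffix}"
        if path.exists():
            df = pd.read_csv(path, dtype=dtypes)
            missing = set(TABLE_COLUMNS[name]) - set(df.columns)
            if missing:
                raise ValueError(f"{path}: missing columns {sorted(missing)}")
            return df
    return pd.DataFrame(columns=TABLE_COLUMNS[name])


def read_cohort_dir(
    dirpath: str | Path, ndc_map: NdcAtcMap | None = None
) -> list[PatientStay]:
    """Read MIMIC-shaped CSV tables from a directory into PatientStay objects.

    Chart times are hours since ICU entry.  SCr rows charted in umol/l are
    converted to mg/dl via the unit column.
    """
    from .kdigo import UMOL_PER_MGDL

    dirpath = Path(dirpath)
    ndc_map = ndc_map or NdcAtcMap()
    patients = _read_table(dirpath, "PATIENTS").set_index("SUBJECT_ID")
    admissions = _read_table(dirpath, "ADMISSIONS").set_index("HADM_ID")
    icustays = _read_table(dirpath, "ICUSTAYS")
    events = pd.concat(
        [_read_table(dirpath, "LABEVENTS"), _read_table(dirpath, "CHARTEVENTS")],
        ignore_index=True,
    )
    prescriptions = _read_table(dirpath, "PRESCRIPTIONS")
    notes = _read_table(dirpath, "NOTEEVENTS")
    notes = notes[notes["CATEGORY"].astype(str).str.lower().str.contains("admission")]
    note_by_stay = dict(zip(notes["ICUSTAY_ID"], notes["TEXT"].fillna("")))

    events_by_stay = dict(iter(events.groupby("ICUSTAY_ID"))) if len(events) else {}
    rx_by_stay = dict(iter(prescriptions.groupby("ICUSTAY_ID"))) if len(prescriptions) else {}

    stays: list[PatientStay] = []
    for _, row in icustays.sort_values("ICUSTAY_ID").iterrows():
        sid = int(row["ICUSTAY_ID"])
        subj = patients.loc[row["SUBJECT_ID"]] if row["SUBJECT_ID"] in patients.index else None
        adm = admissions.loc[row["HADM_ID"]] if row["HADM_ID"] in admissions.index else None
        channels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if sid in events_by_stay:
            for channel, grp in events_by_stay[sid].groupby("CHANNEL"):
                t = grp["CHARTTIME_HOURS"].to_numpy(dtype=float)
                v = grp["VALUENUM"].to_numpy(dtype=float)
                if channel == "creatinine" and "VALUEUOM" in grp:
                    umol = grp["VALUEUOM"].astype(str).str.lower().str.contains("mol").to_numpy()
                    v = v.copy()
                    v[umol] = v[umol] / UMOL_PER_MGDL
                channels[str(channel)] = order_temporal(t, v)
        atc: set[str] = set()
        if sid in rx_by_stay:
            for ndc in rx_by_stay[sid]["NDC"]:
                atc |= ndc_map.lookup(ndc)
        stays.append(
            PatientStay(
                stay_id=sid,
                age=float(subj["AGE_YEARS"]) if subj is not None else np.nan,
                gender=str(subj["GENDER"]) if subj is not None else "",
                ethnicity=str(adm["ETHNICITY"]) if adm is not None else "",
                weight_kg=float(row.get("WEIGHT_KG", np.nan)),
                height_m=float(row.get("HEIGHT_M", np.nan)),
                channels=channels,
                atc_codes=atc,
                note_text=str(note_by_stay.get(sid, "")),
                rrt=bool(row.get("RRT", False)),
            )
        )
    return stays


def write_features(
    path: str | Path,
    stay_ids: list[int],
    X: np.ndarray,
    schema: FeatureSchema,
    normalizer: Normalizer,
) -> None:
    """Persist assembled sequences as a columnar file + JSON sidecar
    (fitted normalizer bounds and schema hash)."""
    path = Path(path)
    df = pd.DataFrame(X, columns=schema.names)
    df.insert(0, "stay_id", stay_ids)
    df.to_parquet(path)
    sidecar = {
        "schema_hash": schema.hash(),
        "schema": schema.to_dict(),
        "normalizer_bounds": {k: list(v) for k, v in sorted(normalizer.bounds.items())},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_features(path: str | Path) -> tuple[list[int], np.ndarray, FeatureSchema, Normalizer]:
    path = Path(path)
    df = pd.read_parquet(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    schema = FeatureSchema.from_dict(sidecar["schema"])
    normalizer = Normalizer({k: tuple(v) for k, v in sidecar["normalizer_bounds"].items()})
    stay_ids = df["stay_id"].tolist()
    X = df[schema.names].to_numpy(dtype=float)
    return stay_ids, X, schema, normalizer
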