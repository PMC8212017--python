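"""Synthetic MIMIC-shaped ICU cohort generator with a latent AKI-risk model.

Every stay draws demographics, comorbidity flags, medication exposures and
two latent severity variables ``z_scr`` and ``z_urine`` that shift the
baseline level of the two designated channels (serum creatinine up, urine
output down).  A logistic latent-risk model

    p_j = sigmoid(b0 + a_scr z_scr + a_urine z_urine + C gamma + M delta)

decides which stays are *AKI-destined*; ``b0`` is calibrated by bisection so
the destined rate matches the target prevalence.  Destined stays receive an
onset time sampled uniformly inside the prediction interval, an upward
piecewise-linear creatinine excursion whose peak ratio tier controls the
KDIGO stage mixture, and a depressed urine-output rate; a leakage parameter
lets a configurable fraction of the pre-onset trend appear during late
observation.  KDIGO labels are always *derived* from the generated
trajectories by :mod:`akiattn.kdigo`, never set directly, so labels can
disagree with the latent intent when noise fires or misses a criterion —
exactly as in real charts.

Trajectories are piecewise-linear plus Gaussian noise; the generator aims at
structural realism (irregular sampling, missing channels, note text with
planted keywords, NDC-coded prescriptions), not physiological fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kdigo import (
    CreatinineSeries,
    IntervalScheme,
    UrineSeries,
    EXPERIMENTAL_SCHEMES,
    label_stay,
)
from .pipeline import NdcAtcMap, PatientStay
from .schema import ATC_CATEGORIES, COMORBIDITY_KEYWORDS, TEMPORAL_CHANNELS

__all__ = ["SyntheticCohortSpec", "GeneratedStay", "generate_cohort", "write_mimic_shaped", "label_generated"]

#: sampling cadence (hours) per channel kind
_VITALS = {"spo2", "temperature", "sbp", "mbp", "dbp", "heart_rate", "resp_rate", "glucose"}
_LAB_PERIOD, _VITAL_PERIOD, _URINE_PERIOD = 6.0, 2.0, 1.0


@dataclass
class SyntheticCohortSpec:
    """Distributions, effect sizes, noise, missingness of a synthetic cohort.

    Fully serializable; a cohort is reproducible from (spec, seed).
    """

    n_stays: int = 2000
    scheme_name: str = "case1"
    prevalence: float = 0.30
    # planted two-channel signal: log-odds per sd of latent severity
    creatinine_effect: float = 2.4
    urine_effect: float = 2.4
    comorbidity_logodds: dict = field(
        default_factory=lambda: {
            "chf": 0.9, "diabetes": 0.7, "cad": 0.8, "hypertension": 0.5,
            "cirrhosis": 1.2, "mi": 0.4, "liver_disease": 0.4,
        }
    )
    comorbidity_prevalence: dict = field(
        default_factory=lambda: {
            "chf": 0.20, "diabetes": 0.30, "cad": 0.25, "hypertension": 0.35,
            "cirrhosis": 0.04, "mi": 0.12, "liver_disease": 0.05,
            "peripheral_vascular": 0.06, "jaundice": 0.03, "sleep_apnea": 0.05,
            "uti": 0.10,
        }
    )
    medication_logodds: dict = field(
        default_factory=lambda: {
            "A10": 0.6, "C03": 0.5, "M01": 0.4, "C09": -0.6, "C10": -0.5, "B01": -0.4,
        }
    )
    medication_prevalence: dict = field(
        default_factory=lambda: {
            "A10": 0.30, "B01": 0.40, "C02": 0.15, "C03": 0.35,
            "C09": 0.20, "C10": 0.25, "M01": 0.15, "V08": 0.10,
        }
    )
    # creatinine excursion: stage-tier mixture of peak ratios vs baseline
    stage_tier_probs: tuple = (0.5, 0.3, 0.2)
    stage_tier_ratios: tuple = (1.7, 2.4, 3.4)
    drift_scale: float = 1.0  # multiplies the excursion above baseline
    rise_hours: float = 12.0
    # depressed urine rate after onset (ml/kg/h) per tier
    urine_depressed: tuple = (0.38, 0.38, 0.15)
    # pre-onset leakage into late observation
    leak_fraction: float = 0.5
    leak_hours: float = 8.0
    # noise / missingness
    scr_noise_sd: float = 0.04
    urine_noise_sd: float = 0.12
    channel_noise_frac: float = 0.03  # of each channel's configured range
    channel_spread_frac: float = 0.06
    obs_dropout: float = 0.10  # per-observation missingness
    channel_missing_rate: float = 0.08  # whole-channel missingness (null channels)
    aki_note_rate: float = 0.02
    empty_note_rate: float = 0.01
    scr_unit: str = "mg/dl"  # "umol/l" exercises unit conversion

    @property
    def scheme(self) -> IntervalScheme:
        return EXPERIMENTAL_SCHEMES[self.scheme_name]

    def validate(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0,1)")
        if self.n_stays < 1:
            raise ValueError("n_stays must be positive")
        s = self.scheme
        if s.prediction_hours < self.rise_hours:
            raise ValueError("onset excursion cannot fit inside the prediction interval")
        if abs(sum(self.stage_tier_probs) - 1) > 1e-9:
            raise ValueError("stage_tier_probs must sum to 1")

    @classmethod
    def zero_signal(cls, **kw) -> "SyntheticCohortSpec":
        """No-signal control: every observable effect and leak set to zero."""
        return cls(
            creatinine_effect=0.0,
            urine_effect=0.0,
            comorbidity_logodds={},
            medication_logodds={},
            leak_fraction=0.0,
            **kw,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GeneratedStay:
    """PatientStay plus generation-time ground truth (never used as a label)."""

    stay: PatientStay
    destined: bool
    latent_risk: float
    onset_time: float | None
    tier: int | None
    urine_times: np.ndarray = None
    urine_volumes: np.ndarray = None

    def kdigo_inputs(self) -> tuple[CreatinineSeries, UrineSeries]:
        t, v = self.stay.channel("creatinine")
        scr = CreatinineSeries(t, v)
        urine = UrineSeries(self.urine_times, self.urine_volumes, self.stay.weight_kg)
        return scr, urine


def _calibrate_intercept(risk: np.ndarray, target: float) -> float:
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        p = float(np.mean(1.0 / (1.0 + np.exp(-(mid + risk)))))
        if p < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _note_text(flags: dict[str, bool], rng: np.random.Generator) -> str:
    phrases = [kw for (name, kw) in COMORBIDITY_KEYWORDS if flags.get(name)]
    body = "; ".join(phrases) if phrases else "no significant past medical history"
    return f"Admission note. History of: {body}. Admitted to the ICU for monitoring."


def generate_cohort(spec: SyntheticCohortSpec, seed: int) -> list[GeneratedStay]:
    """Deterministically generate a cohort from (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_stays
    scheme = spec.scheme
    horizon = scheme.prediction_end
    com_names = [c for c, _ in COMORBIDITY_KEYWORDS]
    atc_names = list(ATC_CATEGORIES)

    age = np.clip(rng.normal(65, 15, n), 18, 95)
    male = rng.random(n) < 0.55
    ethnicity = rng.choice(["white", "other"], size=n, p=[0.7, 0.3])
    weight = np.clip(rng.normal(80, 15, n), 45, 160)
    height = np.clip(rng.normal(1.70, 0.10, n), 1.45, 2.05)

    C = np.column_stack(
        [rng.random(n) < spec.comorbidity_prevalence.get(c, 0.05) for c in com_names]
    )
    M = np.column_stack(
        [rng.random(n) < spec.medication_prevalence.get(a, 0.1) for a in atc_names]
    )
    z_scr = rng.standard_normal(n)
    z_urine = rng.standard_normal(n)
    gamma = np.array([spec.comorbidity_logodds.get(c, 0.0) for c in com_names])
    delta = np.array([spec.medication_logodds.get(a, 0.0) for a in atc_names])
    risk = (
        spec.creatinine_effect * z_scr
        + spec.urine_effect * z_urine
        + C @ gamma
        + M @ delta
    )
    b0 = _calibrate_intercept(risk, spec.prevalence)
    p = 1.0 / (1.0 + np.exp(-(b0 + risk)))
    destined = rng.random(n) < p

    onset_lo = scheme.observation_hours + 1.0
    onset_hi = horizon - max(8.0, spec.rise_hours * 0.5)
    if onset_hi <= onset_lo:
        raise ValueError("infeasible spec: no room for onset inside the horizon")
    onset = rng.uniform(onset_lo, onset_hi, n)
    tier = rng.choice(len(spec.stage_tier_probs), size=n, p=spec.stage_tier_probs)

    base_scr = np.clip(0.85 + 0.18 * z_scr, 0.4, 2.2)
    base_urine = np.clip(1.15 - 0.22 * z_urine, 0.65, 2.4)

    lab_times = np.arange(1.0, horizon + 1e-9, _LAB_PERIOD)
    vital_times = np.arange(0.5, horizon + 1e-9, _VITAL_PERIOD)
    urine_times = np.arange(1.0, horizon + 1e-9, _URINE_PERIOD)
    obs_end = scheme.observation_hours

    def excursion(times: np.ndarray, j: int) -> np.ndarray:
        """Creatinine rise above baseline for destined stay j at `times`."""
        peak = base_scr[j] * (spec.stage_tier_ratios[tier[j]] - 1.0) * spec.drift_scale
        out = np.zeros_like(times)
        t0 = onset[j]
        ramp = np.clip((times - t0) / spec.rise_hours, 0.0, 1.0)
        out += peak * ramp
        if spec.leak_fraction > 0 and spec.leak_hours > 0:
            leak_amp = spec.leak_fraction * 0.2
            pre = np.clip((times - (obs_end - spec.leak_hours)) / spec.leak_hours, 0.0, 1.0)
            out += leak_amp * pre * (times < t0)
        return out

    def urine_factor(times: np.ndarray, j: int) -> np.ndarray:
        """Multiplier and floor for urine rate of destined stay j."""
        rate = np.full_like(times, base_urine[j])
        if spec.leak_fraction > 0:
            pre = (times >= obs_end - spec.leak_hours) & (times < onset[j])
            rate[pre] = base_urine[j] * (1.0 - 0.25 * spec.leak_fraction)
        low = spec.urine_depressed[tier[j]]
        rate[times >= onset[j]] = low
        return rate

    # null channels generated cohort-wide (vectorized), then per-stay slices
    other_channels = [c for c in TEMPORAL_CHANNELS if c not in ("creatinine", "urine_rate")]
    channel_data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ch in other_channels:
        lo, hi, normal = TEMPORAL_CHANNELS[ch]
        times = vital_times if ch in _VITALS else lab_times
        spread = spec.channel_spread_frac * (hi - lo)
        noise = spec.channel_noise_frac * (hi - lo)
        base = np.clip(rng.normal(normal, spread, n), lo, hi)
        vals = np.clip(
            base[:, None] + rng.normal(0, noise, (n, len(times))), lo, hi
        )
        channel_data[ch] = (times, vals)
    channel_missing = {
        ch: rng.random(n) < spec.channel_missing_rate for ch in other_channels
    }
    obs_keep = {
        ch: rng.random((n, len(channel_data[ch][0]))) >= spec.obs_dropout
        for ch in other_channels
    }

    scr_noise = rng.normal(0, spec.scr_noise_sd, (n, len(lab_times)))
    urine_noise = rng.normal(0, spec.urine_noise_sd, (n, len(urine_times)))
    scr_keep = rng.random((n, len(lab_times))) >= spec.obs_dropout
    note_roll = rng.random(n)
    stays: list[GeneratedStay] = []
    for j in range(n):
        scr_vals = base_scr[j] + scr_noise[j]
        if destined[j]:
            scr_vals = scr_vals + excursion(lab_times, j)
        scr_vals = np.clip(scr_vals, 0.15, 25.0)
        keep = scr_keep[j].copy()
        if not keep.any():
            keep[0] = True  # keep at least the baseline draw
        channels = {"creatinine": (lab_times[keep], scr_vals[keep])}

        rate = (
            urine_factor(urine_times, j)
            if destined[j]
            else np.full_like(urine_times, base_urine[j])
        )
        rate = np.clip(rate + urine_noise[j], 0.0, None)
        volumes = rate * weight[j] * _URINE_PERIOD
        channels["urine_rate"] = (urine_times, rate)

        for ch in other_channels:
            if channel_missing[ch][j]:
                continue
            times, vals = channel_data[ch]
            keep_ch = obs_keep[ch][j]
            if keep_ch.any():
                channels[ch] = (times[keep_ch], vals[j][keep_ch])

        flags = {c: bool(C[j, i]) for i, c in enumerate(com_names)}
        if note_roll[j] < spec.empty_note_rate:
            note = ""
        else:
            note = _note_text(flags, rng)
            if note_roll[j] > 1.0 - spec.aki_note_rate:
                note += " Transferred with suspected acute kidney injury."
        atc = {a for i, a in enumerate(atc_names) if M[j, i]}
        stay = PatientStay(
            stay_id=j + 1,
            age=float(age[j]),
            gender="M" if male[j] else "F",
            ethnicity=str(ethnicity[j]),
            weight_kg=float(weight[j]),
            height_m=float(height[j]),
            channels=channels,
            atc_codes=atc,
            note_text=note,
        )
        stays.append(
            GeneratedStay(
                stay=stay,
                destined=bool(destined[j]),
                latent_risk=float(b0 + risk[j]),
                onset_time=float(onset[j]) if destined[j] else None,
                tier=int(tier[j]) if destined[j] else None,
                urine_times=urine_times.copy(),
                urine_volumes=volumes,
            )
        )
    return stays


def label_generated(cohort: list[GeneratedStay], scheme: IntervalScheme) -> pd.DataFrame:
    """Apply the KDIGO labeler to every generated stay's trajectories."""
    rows = []
    for g in cohort:
        scr, urine = g.kdigo_inputs()
        assessment, excluded = label_stay(scr, urine, scheme)
        rows.append(
            {
                "stay_id": g.stay.stay_id,
                "is_aki": assessment.is_aki,
                "stage": assessment.stage,
                "onset_time_hours": assessment.onset_time,
                "onset_interval_index": assessment.onset_interval_index,
                "fired_criteria": ";".join(sorted(assessment.fired_criteria)),
                "excluded": excluded or "",
            }
        )
    return pd.DataFrame(rows)


def write_mimic_shaped(
    cohort: list[GeneratedStay],
    out_dir: str | Path,
    ndc_map: NdcAtcMap | None = None,
    scr_unit: str = "mg/dl",
) -> dict[str, Path]:
    """Emit the MIMIC-shaped CSV tables the cohort pipeline reads.

    Prescriptions carry NDC codes drawn from the bundled synthetic mapping
    for each exposed ATC class; the creatinine unit flag exercises
    umol/l -> mg/dl conversion in the readers.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ndc_map = ndc_map or NdcAtcMap()
    from .kdigo import UMOL_PER_MGDL

    patients, admissions, icustays, lab_rows, chart_rows, rx_rows, note_rows = (
        [], [], [], [], [], [], []
    )
    for g in cohort:
        s = g.stay
        sid = s.stay_id
        patients.append({"SUBJECT_ID": sid, "GENDER": s.gender, "AGE_YEARS": round(s.age, 1)})
        admissions.append({"SUBJECT_ID": sid, "HADM_ID": sid, "ETHNICITY": s.ethnicity})
        icustays.append(
            {
                "ICUSTAY_ID": sid, "HADM_ID": sid, "SUBJECT_ID": sid,
                "WEIGHT_KG": round(s.weight_kg, 1), "HEIGHT_M": round(s.height_m, 2),
                "RRT": int(s.rrt),
            }
        )
        for ch, (t, v) in sorted(s.channels.items()):
            rows = lab_rows if ch not in _VITALS else chart_rows
            unit = ""
            vals = v
            if ch == "creatinine":
                if scr_unit == "umol/l":
                    vals = v * UMOL_PER_MGDL
                    unit = "umol/l"
                else:
                    unit = "mg/dl"
            for ti, vi in zip(t, vals):
                rows.append(
                    {
                        "ICUSTAY_ID": sid, "CHANNEL": ch,
                        "CHARTTIME_HOURS": round(float(ti), 3),
                        "VALUENUM": round(float(vi), 4), "VALUEUOM": unit,
                    }
                )
        for ti, vi in zip(g.urine_times, g.urine_volumes):
            lab_rows.append(
                {
                    "ICUSTAY_ID": sid, "CHANNEL": "urine",
                    "CHARTTIME_HOURS": round(float(ti), 3),
                    "VALUENUM": round(float(vi), 2), "VALUEUOM": "ml",
                }
            )
        for atc in sorted(s.atc_codes):
            codes = ndc_map.ndc_codes_for(atc, exclusive=True) or ndc_map.ndc_codes_for(atc)
            if codes:
                rx_rows.append({"ICUSTAY_ID": sid, "NDC": codes[sid % len(codes)]})
        note_rows.append({"ICUSTAY_ID": sid, "CATEGORY": "Admission note", "TEXT": s.note_text})

    paths = {}
    for name, rows in (
        ("PATIENTS", patients), ("ADMISSIONS", admissions), ("ICUSTAYS", icustays),
        ("LABEVENTS", lab_rows), ("CHARTEVENTS", chart_rows),
        ("PRESCRIPTIONS", rx_rows), ("NOTEEVENTS", note_rows),
    ):
        path = out_dir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        paths[name] = path
    return paths
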