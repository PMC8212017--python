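"""KDIGO labeling of acute kidney injury from serum creatinine and urine output.

The KDIGO consensus criteria define an AKI *case* by any of

* a serum-creatinine (SCr) rise >= 0.3 mg/dl within 48 h,
* SCr >= 1.5x the baseline (the first in-hospital measurement) within 7 days, or
* urine output < 0.5 ml/kg/h sustained for >= 6 h,

and grade *stages* 1-3 from ratio bands versus baseline, absolute 48-h rises,
sustained low urine-output runs, anuria, initiation of renal replacement
therapy, and (for patients under 18) an eGFR drop below 35 ml/min/1.73 m^2.

This module evaluates those rules on per-stay time series and additionally
bins each AKI onset time into equal-length *onset intervals* that partition a
prediction window following a fixed observation window, the multi-class
target for onset-timing prediction.

Times are hours since hospital/ICU admission throughout.  SCr values are
mg/dl; urine volumes are ml charted over the preceding interval; weights kg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CreatinineSeries",
    "UrineSeries",
    "AkiAssessment",
    "IntervalScheme",
    "EXPERIMENTAL_SCHEMES",
    "baseline_scr",
    "detect_aki_case",
    "stage_aki",
    "assign_onset_interval",
    "label_stay",
    "label_cohort",
    "UMOL_PER_MGDL",
]

#: conversion factor between creatinine in umol/l and mg/dl
UMOL_PER_MGDL = 88.4

# rule identifiers recorded in AkiAssessment.fired_criteria
SCR_RISE_48H = "scr_rise_0.3_48h"
SCR_RATIO_7D = "scr_ratio_1.5_7d"
URINE_LOW_6H = "urine_lt_0.5_6h"
SCR_RISE_4_48H = "scr_rise_4.0_48h"
URINE_LOW_12H = "urine_lt_0.5_12h"
URINE_LOW03_24H = "urine_lt_0.3_24h"
ANURIA_12H = "anuria_12h"
RRT = "rrt_initiated"
PEDIATRIC_EGFR = "egfr_lt_35_under18"

_EPS = 1e-9
_HOURS_48 = 48.0
_HOURS_7D = 168.0
#: charting gaps longer than this break a sustained low-urine-output run
MAX_URINE_GAP_HOURS = 6.0


class LabelingError(ValueError):
    """Raised when a stay cannot be labeled (e.g. no usable measurements)."""


@dataclass
class CreatinineSeries:
    """Serum-creatinine measurements of one stay, sorted by time.

    Parameters
    ----------
    times : array-like
        Hours since admission, strictly increasing after construction.
    values : array-like
        SCr in mg/dl, all positive.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-d and equally long")
        order = np.argsort(t, kind="stable")
        self.times = t[order]
        self.values = v[order]
        if len(t) and np.any(np.diff(self.times) < 0):
            raise ValueError("times must be sortable to increasing order")
        if np.any(self.values <= 0):
            raise ValueError("SCr values must be positive")

    def __len__(self) -> int:
        return len(self.times)

    def truncated(self, t_max: float) -> "CreatinineSeries":
        keep = self.times <= t_max + _EPS
        return CreatinineSeries(self.times[keep], self.values[keep])


@dataclass
class UrineSeries:
    """Charted urine volumes of one stay.

    ``volumes[i]`` is the output (ml) over the interval ending at
    ``times[i]``; the first interval is anchored at ``interval_start``.
    """

    times: np.ndarray
    volumes: np.ndarray
    weight_kg: float
    interval_start: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and volumes must be 1-d and equally long")
        order = np.argsort(t, kind="stable")
        self.times = t[order]
        self.volumes = v[order]
        if np.any(self.volumes < 0):
            raise ValueError("urine volumes must be non-negative")
        if len(t) and not (self.weight_kg > 0):
            raise ValueError("patient weight must be positive to assess urine output")

    def __len__(self) -> int:
        return len(self.times)

    def truncated(self, t_max: float) -> "UrineSeries":
        keep = self.times <= t_max + _EPS
        return UrineSeries(self.times[keep], self.volumes[keep], self.weight_kg, self.interval_start)

    def rates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-interval output rates.

        Returns ``(start_times, durations, rates)`` with rates in ml/kg/h.
        Zero-length intervals (duplicate chart times) are dropped.
        """
        starts = np.concatenate(([self.interval_start], self.times[:-1]))
        durations = self.times - starts
        keep = durations > _EPS
        starts, durations = starts[keep], durations[keep]
        rates = self.volumes[keep] / durations / self.weight_kg
        return starts, durations, rates


@dataclass
class IntervalScheme:
    """Observation / prediction / onset-interval durations (hours)."""

    observation_hours: float
    prediction_hours: float
    onset_interval_hours: float

    def __post_init__(self) -> None:
        if min(self.observation_hours, self.prediction_hours, self.onset_interval_hours) <= 0:
            raise ValueError("all durations must be positive")
        n = self.prediction_hours / self.onset_interval_hours
        if abs(n - round(n)) > 1e-9:
            raise ValueError("prediction_hours must be divisible by onset_interval_hours")

    @property
    def n_onset_intervals(self) -> int:
        return int(round(self.prediction_hours / self.onset_interval_hours))

    @property
    def prediction_end(self) -> float:
        return self.observation_hours + self.prediction_hours


#: the three experimental interval settings: 24h/24h/12h, 24h/6d/24h, 48h/5d/24h
EXPERIMENTAL_SCHEMES: dict[str, IntervalScheme] = {
    "case1": IntervalScheme(24.0, 24.0, 12.0),
    "case2": IntervalScheme(24.0, 144.0, 24.0),
    "case3": IntervalScheme(48.0, 120.0, 24.0),
}


@dataclass
class AkiAssessment:
    """Outcome of KDIGO evaluation for one stay."""

    is_aki: bool
    stage: int = 0  # 0 = none, else 1..3
    onset_time: float | None = None
    fired_criteria: set[str] = field(default_factory=set)
    onset_interval_index: int | None = None

    def __post_init__(self) -> None:
        if self.is_aki != (self.stage in (1, 2, 3)) and self.stage != 0:
            raise ValueError("stage must be 1-3 iff is_aki")
        if self.is_aki and self.onset_time is None:
            raise ValueError("AKI assessment requires an onset time")


def baseline_scr(scr: CreatinineSeries) -> float:
    """The baseline: the first SCr value measured during hospitalization."""
    if scr is None or len(scr) == 0:
        raise LabelingError("cannot take baseline SCr of an empty series")
    return float(scr.values[0])


def _scr_rise_onset(scr: CreatinineSeries, delta: float, window: float = _HOURS_48) -> float | None:
    """Earliest time at which some earlier measurement within `window` hours
    is exceeded by >= `delta` mg/dl; None if never."""
    if len(scr) < 2:
        return None
    t, v = scr.times, scr.values
    dt = t[None, :] - t[:, None]  # dt[i, j] = t_j - t_i
    dv = v[None, :] - v[:, None]
    ok = (dt > _EPS) & (dt <= window + _EPS) & (dv >= delta - _EPS)
    if not ok.any():
        return None
    return float(t[np.nonzero(ok.any(axis=0))[0][0]])


def _scr_ratio_onset(scr: CreatinineSeries, ratio: float) -> float | None:
    """Earliest time within 7 days of the baseline measurement at which SCr
    reaches `ratio` x baseline; None if never."""
    if len(scr) == 0:
        return None
    base = baseline_scr(scr)
    t0 = scr.times[0]
    ok = (scr.times - t0 <= _HOURS_7D + _EPS) & (scr.values >= ratio * base - _EPS)
    if not ok.any():
        return None
    return float(scr.times[np.nonzero(ok)[0][0]])


def _urine_run_onset(
    urine: UrineSeries, threshold: float, min_hours: float, max_gap: float = MAX_URINE_GAP_HOURS
) -> float | None:
    """Earliest time at which urine rate has been < `threshold` ml/kg/h for a
    sustained run of >= `min_hours`.

    Runs are maximal stretches of consecutive charting intervals whose rate is
    sub-threshold; an interval longer than `max_gap` hours breaks a run (too
    sparse to assert a sustained rate).  The run "fires" once its cumulative
    duration reaches `min_hours`, at run start + `min_hours`.
    """
    if urine is None or len(urine) == 0:
        return None
    starts, durations, rates = urine.rates()
    run_start = None
    acc = 0.0
    prev_end = None
    for s, d, r in zip(starts, durations, rates):
        is_low = (r < threshold - _EPS) and (d <= max_gap + _EPS)
        contiguous = prev_end is not None and abs(s - prev_end) <= 1e-6
        if is_low:
            if run_start is None or not contiguous:
                run_start, acc = s, 0.0
            acc += d
            if acc >= min_hours - _EPS:
                return float(run_start + min_hours)
        else:
            run_start = None
        prev_end = s + d
    return None


def detect_aki_case(
    scr: CreatinineSeries | None = None,
    urine: UrineSeries | None = None,
) -> AkiAssessment:
    """Evaluate the three KDIGO case criteria.

    Returns an assessment with ``is_aki``, the earliest ``onset_time`` over
    the fired criteria, and the set of fired criterion identifiers.  Stage is
    left at 0; use :func:`stage_aki` for grading.
    """
    if (scr is None or len(scr) == 0) and (urine is None or len(urine) == 0):
        raise LabelingError("need at least one of SCr / urine series to assess AKI")
    onsets: dict[str, float] = {}
    if scr is not None and len(scr):
        t = _scr_rise_onset(scr, 0.3)
        if t is not None:
            onsets[SCR_RISE_48H] = t
        t = _scr_ratio_onset(scr, 1.5)
        if t is not None:
            onsets[SCR_RATIO_7D] = t
    if urine is not None and len(urine):
        t = _urine_run_onset(urine, 0.5, 6.0)
        if t is not None:
            onsets[URINE_LOW_6H] = t
    if not onsets:
        return AkiAssessment(is_aki=False)
    onset = min(onsets.values())
    return AkiAssessment(
        is_aki=True, stage=0, onset_time=onset, fired_criteria=set(onsets)
    )


def stage_aki(
    scr: CreatinineSeries | None = None,
    urine: UrineSeries | None = None,
    rrt_initiated: bool = False,
    age_years: float | None = None,
    egfr: float | None = None,
) -> AkiAssessment:
    """Grade AKI stage as the maximum over all satisfied KDIGO stage rules.

    Rules: SCr ratio vs 7-day baseline >=1.5 -> 1, >=2.0 -> 2, >=3.0 -> 3;
    rise >=0.3 mg/dl in 48 h -> 1; rise >=4.0 mg/dl in 48 h -> 3; urine
    < 0.5 ml/kg/h for >=6 h -> 1, >=12 h -> 2; < 0.3 for >=24 h -> 3;
    anuria >=12 h -> 3; renal replacement therapy -> 3; age < 18 with
    eGFR < 35 -> 3.  If the pediatric rule is requested without eGFR it is
    skipped with a warning.
    """
    stage = 0
    fired: set[str] = set()
    onsets: dict[str, float] = {}

    def hit(rule: str, s: int, onset: float | None) -> None:
        nonlocal stage
        fired.add(rule)
        stage = max(stage, s)
        if onset is not None:
            onsets[rule] = onset

    if scr is not None and len(scr):
        base = baseline_scr(scr)
        t0 = scr.times[0]
        in_window = scr.times - t0 <= _HOURS_7D + _EPS
        if in_window.any():
            max_ratio = float(np.max(scr.values[in_window]) / base)
            if max_ratio >= 3.0 - _EPS:
                hit("scr_ratio_3.0", 3, _scr_ratio_onset(scr, 3.0))
            elif max_ratio >= 2.0 - _EPS:
                hit("scr_ratio_2.0", 2, _scr_ratio_onset(scr, 2.0))
            elif max_ratio >= 1.5 - _EPS:
                hit(SCR_RATIO_7D, 1, _scr_ratio_onset(scr, 1.5))
        t = _scr_rise_onset(scr, 0.3)
        if t is not None:
            hit(SCR_RISE_48H, 1, t)
        t = _scr_rise_onset(scr, 4.0)
        if t is not None:
            hit(SCR_RISE_4_48H, 3, t)
    if urine is not None and len(urine):
        t = _urine_run_onset(urine, 0.5, 6.0)
        if t is not None:
            hit(URINE_LOW_6H, 1, t)
        t = _urine_run_onset(urine, 0.5, 12.0)
        if t is not None:
            hit(URINE_LOW_12H, 2, t)
        t = _urine_run_onset(urine, 0.3, 24.0)
        if t is not None:
            hit(URINE_LOW03_24H, 3, t)
        # anuria: rate of (numerically) zero sustained >= 12 h
        t = _urine_run_onset(urine, 1e-6, 12.0)
        if t is not None:
            hit(ANURIA_12H, 3, t)
    if rrt_initiated:
        hit(RRT, 3, None)
    if age_years is not None and age_years < 18:
        if egfr is None:
            warnings.warn(
                "patient under 18 but eGFR not supplied; pediatric stage-3 rule skipped",
                stacklevel=2,
            )
        elif egfr < 35:
            hit(PEDIATRIC_EGFR, 3, None)

    if stage == 0:
        return AkiAssessment(is_aki=False)
    onset = min(onsets.values()) if onsets else None
    if onset is None:
        # only non-temporal rules fired (RRT / eGFR); anchor at first evidence
        onset = float(scr.times[0]) if scr is not None and len(scr) else 0.0
    return AkiAssessment(True, stage, onset, fired, None)


def assign_onset_interval(onset_time: float, scheme: IntervalScheme) -> int | None:
    """Map an onset time to its onset-interval index under half-open bins.

    Bins partition ``(observation_end, prediction_end]`` into equal
    ``onset_interval_hours`` pieces, ``[start, end)`` on the shifted axis, so
    a boundary time belongs to the later bin.  Returns None when the onset
    lies beyond the prediction horizon (out-of-horizon marker).
    """
    if onset_time <= scheme.observation_hours:
        raise ValueError("onset inside the observation interval is excluded upstream")
    if onset_time > scheme.prediction_end + _EPS:
        return None
    idx = int(np.floor((onset_time - scheme.observation_hours) / scheme.onset_interval_hours))
    return min(idx, scheme.n_onset_intervals - 1)


# exclusion marker used by the cohort pipeline
AKI_IN_OBSERVATION = "aki_in_observation"


def label_stay(
    scr: CreatinineSeries | None,
    urine: UrineSeries | None,
    scheme: IntervalScheme,
    rrt_initiated: bool = False,
    age_years: float | None = None,
    egfr: float | None = None,
) -> tuple[AkiAssessment, str | None]:
    """Full per-stay labeling for one interval scheme.

    Returns ``(assessment, exclusion_reason)``.  A stay that is already an
    AKI case within the observation interval is excluded
    (``exclusion_reason = 'aki_in_observation'``).  Otherwise the criteria
    are evaluated on all data up to the prediction end; onsets beyond the
    horizon yield a not-AKI assessment for this scheme.
    """
    obs_scr = scr.truncated(scheme.observation_hours) if scr is not None else None
    obs_urine = urine.truncated(scheme.observation_hours) if urine is not None else None
    if (obs_scr is not None and len(obs_scr)) or (obs_urine is not None and len(obs_urine)):
        obs = detect_aki_case(obs_scr, obs_urine)
        if obs.is_aki:
            return obs, AKI_IN_OBSERVATION

    full_scr = scr.truncated(scheme.prediction_end) if scr is not None else None
    full_urine = urine.truncated(scheme.prediction_end) if urine is not None else None
    case = detect_aki_case(full_scr, full_urine)
    staged = stage_aki(full_scr, full_urine, rrt_initiated, age_years, egfr)
    if not case.is_aki and not staged.is_aki:
        return AkiAssessment(is_aki=False), None
    onset_candidates = [a.onset_time for a in (case, staged) if a.onset_time is not None]
    onset = min(onset_candidates)
    if onset <= scheme.observation_hours:
        # criterion window straddles the boundary yet never fired on
        # observation data alone; clamp onset just after the boundary
        onset = np.nextafter(scheme.observation_hours, np.inf)
    idx = assign_onset_interval(onset, scheme)
    if idx is None:
        return AkiAssessment(is_aki=False), None
    stage = staged.stage if staged.is_aki else 1
    return (
        AkiAssessment(True, stage, onset, case.fired_criteria | staged.fired_criteria, idx),
        None,
    )


def label_cohort(
    events: pd.DataFrame,
    stays: pd.DataFrame,
    scheme: IntervalScheme,
) -> pd.DataFrame:
    """Label every stay in long-format event data.

    Parameters
    ----------
    events : DataFrame
        Columns ``stay_id, channel, time_hours, value, unit``; channels
        ``"scr"`` (mg/dl or umol/l, converted via the unit column) and
        ``"urine"`` (ml per charting interval) are used.
    stays : DataFrame
        Columns ``stay_id, weight_kg`` and optionally ``age_years, rrt,
        egfr``.
    """
    out = []
    stays = stays.set_index("stay_id") if "stay_id" in stays.columns else stays
    for stay_id, grp in events.groupby("stay_id", sort=True):
        row = stays.loc[stay_id] if stay_id in stays.index else pd.Series(dtype=object)
        scr_rows = grp[grp["channel"] == "scr"]
        scr = None
        if len(scr_rows):
            vals = scr_rows["value"].to_numpy(dtype=float).copy()
            if "unit" in scr_rows:
                umol = scr_rows["unit"].astype(str).str.lower().str.contains("mol").to_numpy()
                vals[umol] = vals[umol] / UMOL_PER_MGDL
            scr = CreatinineSeries(scr_rows["time_hours"].to_numpy(dtype=float), vals)
        urine_rows = grp[grp["channel"] == "urine"]
        urine = None
        if len(urine_rows):
            weight = float(row.get("weight_kg", np.nan))
            if not np.isfinite(weight) or weight <= 0:
                raise LabelingError(f"stay {stay_id}: urine charted but weight unusable")
            urine = UrineSeries(
                urine_rows["time_hours"].to_numpy(dtype=float),
                urine_rows["value"].to_numpy(dtype=float),
                weight,
            )
        if scr is None and urine is None:
            raise LabelingError(f"stay {stay_id}: no SCr or urine events")
        assessment, excluded = label_stay(
            scr,
            urine,
            scheme,
            rrt_initiated=bool(row.get("rrt", False)),
            age_years=row.get("age_years", None),
            egfr=row.get("egfr", None),
        )
        out.append(
            {
                "stay_id": stay_id,
                "is_aki": assessment.is_aki,
                "stage": assessment.stage,
                "onset_time_hours": assessment.onset_time,
                "onset_interval_index": assessment.onset_interval_index,
                "fired_criteria": ";".join(sorted(assessment.fired_criteria)),
                "excluded": excluded or "",
            }
        )
    return pd.DataFrame(out)
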