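"""KDIGO labeling: rule-by-rule examples and brute-force equivalence."""

import numpy as np
import pytest

from akiattn.kdigo import (
    AKI_IN_OBSERVATION,
    AkiAssessment,
    CreatinineSeries,
    EXPERIMENTAL_SCHEMES,
    IntervalScheme,
    LabelingError,
    UrineSeries,
    assign_onset_interval,
    baseline_scr,
    detect_aki_case,
    label_cohort,
    label_stay,
    stage_aki,
)
from conftest import make_scr, make_urine


# --------------------------------------------------------------------- oracle

def brute_force_case(scr: CreatinineSeries | None, urine: UrineSeries | None):
    """Independent O(n^2) scan over all measurement pairs and all contiguous
    sub-threshold urine runs."""
    fired = set()
    onsets = []
    if scr is not None and len(scr):
        t, v = scr.times, scr.values
        for i in range(len(t)):
            for j in range(i + 1, len(t)):
                if t[j] - t[i] <= 48 + 1e-9 and v[j] - v[i] >= 0.3 - 1e-9:
                    fired.add("scr_rise_0.3_48h")
                    onsets.append(t[j])
        base = v[0]
        for j in range(len(t)):
            if t[j] - t[0] <= 168 + 1e-9 and v[j] >= 1.5 * base - 1e-9:
                fired.add("scr_ratio_1.5_7d")
                onsets.append(t[j])
    if urine is not None and len(urine):
        starts, durations, rates = urine.rates()
        for i in range(len(starts)):
            acc = 0.0
            for j in range(i, len(starts)):
                if rates[j] >= 0.5 - 1e-9 or durations[j] > 6 + 1e-9:
                    break
                if j > i and abs(starts[j] - (starts[j - 1] + durations[j - 1])) > 1e-6:
                    break
                acc += durations[j]
                if acc >= 6 - 1e-9:
                    fired.add("urine_lt_0.5_6h")
                    onsets.append(starts[i] + 6.0)
                    break
    if not fired:
        return False, set(), None
    return True, fired, min(onsets)


# ------------------------------------------------------------------ baseline

def test_baseline_is_first_measurement():
    assert baseline_scr(make_scr([(0, 1.0), (24, 1.4)])) == 1.0
    assert baseline_scr(make_scr([(5, 0.6)])) == 0.6
    # unsorted input is time-sorted at construction
    assert baseline_scr(make_scr([(24, 1.4), (0, 1.0)])) == 1.0


def test_baseline_empty_series_raises():
    with pytest.raises(LabelingError):
        baseline_scr(CreatinineSeries(np.empty(0), np.empty(0)))


# ---------------------------------------------------------------- case rules

def test_case_absolute_rise_within_48h():
    a = detect_aki_case(make_scr([(0, 1.0), (24, 1.31)]))
    assert a.is_aki and a.onset_time == 24 and "scr_rise_0.3_48h" in a.fired_criteria


def test_case_no_criterion_fires(hourly_urine):
    scr = make_scr([(t, 1.0) for t in range(0, 73, 8)])
    a = detect_aki_case(scr, hourly_urine(72, rate=1.0))
    assert not a.is_aki and a.onset_time is None


def test_case_ratio_rule_beyond_48h():
    a = detect_aki_case(make_scr([(0, 0.6), (120, 0.92)]))
    assert a.is_aki and a.fired_criteria == {"scr_ratio_1.5_7d"}
    assert a.onset_time == 120


def test_case_urine_rate_sustained():
    # 35 ml/h at 80 kg = 0.4375 ml/kg/h for 7 consecutive hours
    urine = make_urine([(t, 35.0) for t in range(1, 8)], weight=80.0)
    a = detect_aki_case(urine=urine)
    assert a.is_aki and a.fired_criteria == {"urine_lt_0.5_6h"}
    assert a.onset_time == pytest.approx(6.0)


def test_case_needs_some_input():
    with pytest.raises(LabelingError):
        detect_aki_case(None, None)


# --------------------------------------------------------------- stage rules

@pytest.mark.parametrize(
    "ratio,expected",
    [(3.1, 3), (2.5, 2), (1.6, 1), (1.2, 0)],
    ids=["band3", "band2", "band1", "below"],
)
def test_stage_ratio_bands(ratio, expected):
    a = stage_aki(make_scr([(0, 1.0), (100, ratio)]))
    assert a.stage == expected


def test_stage_absolute_rise_is_stage1():
    a = stage_aki(make_scr([(0, 1.0), (24, 1.35)]))
    assert a.stage == 1


def test_stage_rise_4mgdl_is_stage3():
    a = stage_aki(make_scr([(0, 1.0), (40, 5.2)]))
    assert a.stage == 3 and "scr_rise_4.0_48h" in a.fired_criteria


def test_stage_rrt_forces_stage3():
    a = stage_aki(make_scr([(0, 1.0), (80, 1.6)]), rrt_initiated=True)
    assert a.stage == 3 and "rrt_initiated" in a.fired_criteria


@pytest.mark.parametrize(
    "hours,rate,expected",
    [(7, 0.4, 1), (13, 0.4, 2), (25, 0.25, 3), (13, 0.0, 3)],
    ids=["6-12h", ">=12h", "lt03-24h", "anuria"],
)
def test_stage_urine_rules(hourly_urine, hours, rate, expected):
    urine = hourly_urine(hours, rate=rate)
    a = stage_aki(urine=urine)
    assert a.stage == expected


def test_pediatric_rule_and_warning():
    scr = make_scr([(0, 1.0), (24, 1.0)])
    a = stage_aki(scr, age_years=16, egfr=30)
    assert a.stage == 3 and "egfr_lt_35_under18" in a.fired_criteria
    with pytest.warns(UserWarning, match="eGFR"):
        a = stage_aki(scr, age_years=16, egfr=None)
    assert a.stage == 0


def test_stage_invariant_to_late_normal_values():
    base = [(0, 1.0), (24, 2.5)]
    late = base + [(150, 1.0), (160, 1.05)]
    assert stage_aki(make_scr(base)).stage == stage_aki(make_scr(late)).stage


# ------------------------------------------------------------- onset binning

def test_onset_interval_examples():
    scheme = IntervalScheme(24, 24, 12)
    assert assign_onset_interval(30, scheme) == 0
    assert assign_onset_interval(40, scheme) == 1
    # half-open bins: the boundary belongs to the later bin
    assert assign_onset_interval(36.0, scheme) == 1
    assert assign_onset_interval(60, scheme) is None  # out of horizon
    with pytest.raises(ValueError):
        assign_onset_interval(20, scheme)


def test_onset_bins_partition_horizon(rng):
    scheme = EXPERIMENTAL_SCHEMES["case2"]
    times = rng.uniform(scheme.observation_hours + 1e-6, scheme.prediction_end, 500)
    idx = np.array([assign_onset_interval(t, scheme) for t in times])
    assert set(np.unique(idx)) <= set(range(scheme.n_onset_intervals))
    # bin index agrees with direct arithmetic
    expect = np.minimum(
        ((times - scheme.observation_hours) // scheme.onset_interval_hours).astype(int),
        scheme.n_onset_intervals - 1,
    )
    assert (idx == expect).all()


def test_scheme_validation():
    with pytest.raises(ValueError):
        IntervalScheme(24, 25, 12)  # not divisible
    with pytest.raises(ValueError):
        IntervalScheme(-1, 24, 12)
    assert EXPERIMENTAL_SCHEMES["case2"].n_onset_intervals == 6
    assert EXPERIMENTAL_SCHEMES["case3"].n_onset_intervals == 5


# ------------------------------------------------------- randomized properties

def _random_inputs(rng):
    n = rng.integers(2, 12)
    t = np.sort(rng.uniform(0, 150, n))
    t += np.arange(n) * 1e-3  # enforce strictly increasing
    v = np.clip(rng.normal(1.0, 0.45, n), 0.2, None)
    scr = CreatinineSeries(t, v)
    m = rng.integers(2, 14)
    ut = np.sort(rng.uniform(0, 60, m)) + np.arange(m) * 1e-3
    rates = np.clip(rng.normal(0.7, 0.5, m), 0.0, None)
    weight = 80.0
    starts = np.concatenate(([0.0], ut[:-1]))
    vols = rates * (ut - starts) * weight
    urine = UrineSeries(ut, vols, weight)
    return scr, urine


def test_detect_matches_brute_force_oracle(rng):
    """Engine equals an exhaustive pairwise/window scan on random series."""
    for _ in range(250):
        scr, urine = _random_inputs(rng)
        want_aki, want_fired, want_onset = brute_force_case(scr, urine)
        if want_aki:
            got = detect_aki_case(scr, urine)
            assert got.is_aki
            assert got.fired_criteria == want_fired
            assert got.onset_time == pytest.approx(want_onset, abs=1e-6)
        else:
            assert not detect_aki_case(scr, urine).is_aki


def test_stage2_ratio_implies_case(rng):
    """Monotone severity: a stage-2 ratio band always satisfies the case
    definition."""
    for _ in range(100):
        base = rng.uniform(0.5, 1.5)
        ratio = rng.uniform(2.0, 2.9)
        t2 = rng.uniform(1, 160)
        scr = make_scr([(0.0, base), (t2, base * ratio)])
        assert stage_aki(scr).stage >= 2
        assert detect_aki_case(scr).is_aki


# ------------------------------------------------------------------ labeling

def test_label_stay_excludes_observation_aki():
    scheme = EXPERIMENTAL_SCHEMES["case1"]
    scr = make_scr([(0, 1.0), (10, 1.5), (30, 1.6)])
    a, excl = label_stay(scr, None, scheme)
    assert excl == AKI_IN_OBSERVATION


def test_label_stay_out_of_horizon_is_not_aki():
    scheme = EXPERIMENTAL_SCHEMES["case1"]  # horizon 48 h
    scr = make_scr([(0, 1.0), (40, 1.05), (100, 2.5)])
    a, excl = label_stay(scr, None, scheme)
    assert excl is None and not a.is_aki


def test_label_stay_assigns_bin_and_stage():
    scheme = EXPERIMENTAL_SCHEMES["case1"]
    scr = make_scr([(0, 1.0), (20, 1.05), (40, 2.6)])
    a, excl = label_stay(scr, None, scheme)
    assert excl is None and a.is_aki and a.stage == 2
    assert a.onset_interval_index == 1  # onset at 40 h -> second 12-h bin


def test_label_cohort_converts_umol_units():
    import pandas as pd

    events = pd.DataFrame(
        {
            "stay_id": [1, 1],
            "channel": ["scr", "scr"],
            "time_hours": [0.0, 24.0],
            "value": [88.4, 132.6],  # 1.0 and 1.5 mg/dl
            "unit": ["umol/l", "umol/l"],
        }
    )
    stays = pd.DataFrame({"stay_id": [1], "weight_kg": [80.0]})
    out = label_cohort(events, stays, EXPERIMENTAL_SCHEMES["case2"])
    assert bool(out.loc[0, "is_aki"])  # 1.5x baseline fired after conversion
    assert out.loc[0, "onset_time_hours"] == 24.0


def test_assessment_invariants():
    with pytest.raises(ValueError):
        AkiAssessment(is_aki=True, stage=2, onset_time=None)
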