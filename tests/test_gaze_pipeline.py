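"""Tests for fixation detection, AOI assignment, metrics and exclusions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intergaze.gaze_pipeline import (
    AOI,
    Fixation,
    apply_exclusions,
    assign_fixations,
    detect_fixations,
    diagnostic_attention_contrast,
    trial_metrics,
    validate_layout,
)

FRAME = 1000.0 / 120.0


def oracle_fixations(t, x, y, disp=30.0, min_dur=50.0, frame=None):
    """Independent brute-force maximal-window detector.

    For each start index, exhaustively scans every candidate end index,
    recomputing the summed dispersion from scratch over the slice, keeps
    the longest admissible window and emits it when its duration (span
    plus one nominal frame) reaches the minimum.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(t)
    if n == 0:
        return []
    if frame is None:
        frame = float(np.median(np.diff(t))) if n > 1 else FRAME
    out = []
    i = 0
    while i < n:
        best = i
        for j in range(i, n):
            xs, ys = x[i : j + 1], y[i : j + 1]
            if (xs.max() - xs.min()) + (ys.max() - ys.min()) <= disp:
                best = j
            else:
                break
        if t[best] - t[i] + frame >= min_dur:
            out.append((i, best))
            i = best + 1
        else:
            i += 1
    return out


def as_tuples(fixations):
    return [(f.onset_ms, f.sample_count) for f in fixations]


def test_zero_dispersion_single_fixation():
    t = np.arange(12) * FRAME
    fx = detect_fixations(t, np.full(12, 100.0), np.full(12, 100.0))
    assert len(fx) == 1
    assert (fx[0].x, fx[0].y) == (100.0, 100.0)
    assert fx[0].duration_ms == pytest.approx(12 * FRAME)
    assert fx[0].sample_count == 12


def test_alternating_saccade_no_fixations():
    t = np.arange(40) * FRAME
    x = np.where(np.arange(40) % 2 == 0, 100.0, 400.0)
    assert detect_fixations(t, x, x) == []


def test_minimum_duration_boundary_inclusive():
    # six samples at 120 Hz span exactly 50 ms including the last frame
    t = np.arange(6) * FRAME
    assert len(detect_fixations(t, np.zeros(6), np.zeros(6))) == 1
    t5 = np.arange(5) * FRAME
    assert detect_fixations(t5, np.zeros(5), np.zeros(5)) == []


def test_two_cluster_fixture_matches_oracle(rng):
    pieces = []
    for cx, cy in ((200.0, 200.0), (600.0, 500.0)):
        pieces.append(np.column_stack([rng.normal(cx, 5, 20), rng.normal(cy, 5, 20)]))
    pieces.insert(1, np.array([[330.0, 300.0], [470.0, 400.0]]))  # saccade
    xy = np.vstack(pieces)
    t = np.arange(len(xy)) * FRAME
    got = detect_fixations(t, xy[:, 0], xy[:, 1])
    exp = oracle_fixations(t, xy[:, 0], xy[:, 1])
    assert len(got) == 2
    assert [(f.onset_ms, f.sample_count) for f in got] == [
        (t[i], j - i + 1) for i, j in exp
    ]


def test_error_on_nonmonotone_timestamps():
    with pytest.raises(ValueError):
        detect_fixations([0.0, 10.0, 10.0], [0, 0, 0], [0, 0, 0])
    assert detect_fixations([], [], []) == []


@settings(max_examples=300, derandomize=True, deadline=None)
@given(st.data())
def test_detector_equals_bruteforce_oracle(data):
    n = data.draw(st.integers(min_value=0, max_value=50))
    coords = st.integers(min_value=0, max_value=60)
    x = [data.draw(coords) for _ in range(n)]
    y = [data.draw(coords) for _ in range(n)]
    t = np.arange(n) * FRAME
    got = detect_fixations(t, x, y)
    exp = oracle_fixations(t, x, y)
    assert [(f.onset_ms, f.sample_count) for f in got] == [(t[i], j - i + 1) for i, j in exp]
    # no two consecutive fixations could be merged without breaking 30 px
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    for (i1, j1), (i2, j2) in zip(exp, exp[1:]):
        xs, ys = xa[i1 : j2 + 1], ya[i1 : j2 + 1]
        assert (xs.max() - xs.min()) + (ys.max() - ys.min()) > 30.0


def test_assignment_half_open_rectangles(study_layout):
    aoi = study_layout[1]  # a payoff cell
    inside = Fixation(aoi.x0, aoi.y0, 0, 100, 6)
    far_edge = Fixation(aoi.x0 + aoi.width, aoi.y0, 0, 100, 6)
    nowhere = Fixation(5.0, 1000.0, 0, 100, 6)
    labels = [lab for _, lab in assign_fixations([inside, far_edge, nowhere], study_layout)]
    assert labels[0] == aoi.label
    assert labels[1] != aoi.label
    assert labels[2] == "none"


def test_fixture_assignment_matches_hand_lookup(study_layout):
    by_label = {a.label: a for a in study_layout}
    picks = ["own_left", "other_right", "sum_left", "group_id", "code",
             "label_difference", "own_right", "coin", "difference_left", "label_own"]
    fx = [
        Fixation(by_label[p].x0 + 3, by_label[p].y0 + 3, k * 100.0, 100.0, 6)
        for k, p in enumerate(picks)
    ]
    assert [lab for _, lab in assign_fixations(fx, study_layout)] == picks


def test_overlapping_layout_rejected():
    bad = [AOI("a", "payoff_own", 0, 0, 100, 100), AOI("b", "payoff_other", 50, 50, 100, 100)]
    with pytest.raises(ValueError):
        validate_layout(bad)
    with pytest.raises(ValueError):
        validate_layout([AOI("c", "coin", 1250, 0, 100, 100)])


def _fx(label_aoi, dur):
    return Fixation(label_aoi.x0 + 1, label_aoi.y0 + 1, 0.0, dur, 6)


def test_trial_metrics_hand_computed(study_layout):
    by = {a.label: a for a in study_layout}
    assigned = assign_fixations(
        [
            _fx(by["own_left"], 200.0),
            _fx(by["own_right"], 100.0),
            _fx(by["other_left"], 100.0),
            _fx(by["group_id"], 50.0),
            _fx(by["coin"], 50.0),
            Fixation(5.0, 1000.0, 0.0, 100.0, 6),  # off-AOI
        ],
        study_layout,
    )
    m = trial_metrics(assigned, study_layout, response_time_ms=1500.0)
    assert m["n_fixations"] == 6
    assert m["n_inspected"] == 5
    assert m["prop_inspected"] == pytest.approx(5 / 15)
    assert m["attention_own_pct"] == pytest.approx(100 * 300 / 400)
    assert m["on_info_fixation_share"] == pytest.approx(5 / 6)
    assert m["share_group_id"] == pytest.approx(0.5)
    assert m["share_coin"] == pytest.approx(0.5)
    assert m["share_code"] == 0.0
    assert m["group_info_attended"] is True
    # dwell bookkeeping: AOI dwell cannot exceed the trial response time
    assert m["dwell_payoff_own_ms"] + m["dwell_payoff_other_ms"] + m["dwell_identity_ms"] <= 1500.0


def test_trial_metrics_degenerate_attention(study_layout):
    by = {a.label: a for a in study_layout}
    m = trial_metrics(
        assign_fixations([_fx(by["own_left"], 300.0)], study_layout), study_layout, 500.0
    )
    assert m["attention_own_pct"] == 100.0
    m2 = trial_metrics(
        assign_fixations([_fx(by["label_sum"], 300.0)], study_layout), study_layout, 500.0
    )
    assert np.isnan(m2["attention_own_pct"])  # zero payoff dwell is flagged as NaN


def test_binocular_averaging():
    from intergaze.gaze_pipeline import average_eyes

    df = pd.DataFrame(
        {
            "t_ms": [0.0, 8.3, 16.7],
            "x_left": [100.0, 102.0, np.nan],
            "y_left": [200.0, 202.0, np.nan],
            "x_right": [104.0, np.nan, 110.0],
            "y_right": [204.0, np.nan, 210.0],
            "valid_left": [True, True, False],
            "valid_right": [True, False, True],
        }
    )
    out = average_eyes(df)
    assert out.loc[0, "x"] == pytest.approx(102.0)  # both eyes averaged
    assert out.loc[1, "x"] == pytest.approx(102.0)  # left-eye fallback
    assert out.loc[2, "x"] == pytest.approx(110.0)  # right-eye fallback
    assert out["valid"].all()
    # monocular tables pass through untouched
    mono = pd.DataFrame({"t_ms": [0.0], "x": [1.0], "y": [2.0]})
    assert average_eyes(mono) is mono


def _toy_metrics():
    rows = []
    for k in range(1, 21):
        rows.append(
            {
                "participant": "p1",
                "trial": k,
                "response_time_ms": 1000.0,
                "on_info_fixation_share": 0.9,
                "group_info_attended": True,
            }
        )
    df = pd.DataFrame(rows)
    df.loc[df["trial"] == 1, "response_time_ms"] = 150.0  # below 200 ms
    df.loc[df["trial"] == 2, "on_info_fixation_share"] = 0.4  # fixation-share violator
    df.loc[df["trial"] == 3, "response_time_ms"] = 50000.0  # beyond mean + 3 SD
    df.loc[df["trial"].isin([4, 5]), "group_info_attended"] = False
    return df


def test_exclusions_remove_exactly_planted_violators():
    df = _toy_metrics()
    kept, report = apply_exclusions(df, require_group_attended=True)
    assert report["n_fixation_share"] == 1
    assert report["n_rt"] == 2
    assert report["n_group_unattended"] == 2
    assert sorted(kept["trial"]) == sorted(set(range(1, 21)) - {1, 2, 3, 4, 5})
    # process-stage filter off: group-unattended trials retained
    kept2, report2 = apply_exclusions(df)
    assert sorted(kept2["trial"]) == sorted(set(range(1, 21)) - {1, 2, 3})
    assert "n_group_unattended" not in report2


def test_exclusions_noop_and_idempotent():
    df = _toy_metrics()
    clean = df[~df["trial"].isin([1, 2, 3, 4, 5])]
    kept, report = apply_exclusions(clean, require_group_attended=True)
    assert len(kept) == len(clean)
    assert report["n_fixation_share"] == report["n_rt"] == report["n_group_unattended"] == 0
    # idempotence with frozen RT stats
    kept_all, _ = apply_exclusions(df, require_group_attended=True)
    mean = kept_all["response_time_ms"].mean()
    sd = kept_all["response_time_ms"].std(ddof=1)
    again, rep2 = apply_exclusions(kept_all, require_group_attended=True, rt_stats=(mean, sd))
    assert len(again) == len(kept_all)
    assert rep2["n_rt"] == 0


def test_participant_level_flags():
    df = _toy_metrics()
    df2 = df.copy()
    df2["participant"] = "p2"
    both = pd.concat([df, df2], ignore_index=True)
    participants = pd.DataFrame(
        {"participant": ["p1", "p2"], "wrong_outgroup": [False, True],
         "outgroup_preferred": [False, False], "demand_check_failed": [False, False]}
    )
    kept, report = apply_exclusions(both, participants=participants)
    assert report["participants_excluded"] == ["p2"]
    assert set(kept["participant"]) == {"p1"}


def test_diagnostic_attention_contrast_degenerate():
    df = pd.DataFrame(
        [
            {"participant": "p1", "group_info_attended": True,
             "share_group_id": 0.0, "share_coin": 1.0, "share_code": 0.0},
        ]
    )
    out = diagnostic_attention_contrast(df)
    assert out["mean_share_coin"] == 1.0
    assert out["mean_share_group_id"] == 0.0
    assert out["n_participants"] == 1


def test_diagnostic_attention_contrast_biased_simulation(rng):
    from intergaze.addm_simulator import ADDMParams, simulate_cohort
    from intergaze.synthetic_data import ExperimentSpec, generate_participants, generate_trials

    spec = ExperimentSpec(n_participants=8)
    parts = generate_participants(spec, rng)
    trials = generate_trials(spec, rng, parts)
    m = simulate_cohort(trials, parts, ADDMParams(), rng)  # default 3x group bias
    out = diagnostic_attention_contrast(m)
    assert out["mean_share_group_id"] == pytest.approx(0.6, abs=0.05)
    assert out["mean_share_coin"] == pytest.approx(0.2, abs=0.05)
    assert out["mean_share_code"] == pytest.approx(0.2, abs=0.05)
    assert out["t_statistic"] > 2.0
    # unbiased simulator: unconditional shares are symmetric at 1/3 each
    # (the group-attended conditioning of the contrast would inflate the
    # group share, so symmetry is checked on the raw per-trial shares)
    m2 = simulate_cohort(trials, parts, ADDMParams(), rng, identity_bias=(1.0, 1.0, 1.0))
    raw = m2[["share_group_id", "share_coin", "share_code"]].dropna().mean()
    assert raw["share_group_id"] == pytest.approx(1 / 3, abs=0.05)
    assert raw["share_coin"] == pytest.approx(1 / 3, abs=0.05)
    # shares sum to one whenever identity dwell is positive
    s = m[["share_group_id", "share_coin", "share_code"]].dropna().sum(axis=1)
    assert np.allclose(s, 1.0)
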