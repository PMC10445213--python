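import math

import numpy as np
import pandas as pd
import pytest

from trailgaze import (
    Trial,
    aggregate_condition,
    assign_fixations,
    click_accuracy,
    completion_time,
    count_fixation_types,
    eye_hand_span,
    scanpath_length,
    score_trial,
    speed_accuracy_slope,
    summary_stats,
)
from trailgaze.scores import resolve_clicks


def _clicks(rows):
    return pd.DataFrame(rows, columns=["t_ms", "x", "y"])


def _fix(rows, extra=None):
    df = pd.DataFrame(rows, columns=["onset_ms", "offset_ms", "cx", "cy"])
    df["duration_ms"] = df["offset_ms"] - df["onset_ms"]
    for k, v in (extra or {}).items():
        df[k] = v
    return df


def perfect_clicks(layout, start_ms=1000.0, step_ms=1400.0):
    """One dead-center click per target in sequence order."""
    pos = layout.positions()
    rows = [(start_ms + (i + 1) * step_ms, pos[i, 0], pos[i, 1]) for i in range(25)]
    return _clicks(rows)


# ---------------------------------------------------------------------------
# clicks and completion time


@pytest.mark.parametrize("d,expected", [(0.0, 1.0), (0.675, 0.0), (1.0, 0.0), (0.3375, 0.5)])
def test_click_accuracy_linear_ramp(d, expected):
    assert click_accuracy(d, 0.675) == pytest.approx(expected)


def test_completion_time_is_first_correct_click_on_last_target(layout_a):
    clicks = perfect_clicks(layout_a, start_ms=0.0, step_ms=1400.0)
    trial = Trial(layout=layout_a, clicks=clicks, fixations=_fix([]), saccades=pd.DataFrame(), start_ms=1000.0)
    # last click at 25 * 1400 = 35000; start click at 1000
    assert completion_time(trial) == pytest.approx((35000 - 1000) / 1000.0)


def test_miss_on_last_target_does_not_stop_the_clock(layout_a):
    clicks = perfect_clicks(layout_a, start_ms=0.0, step_ms=1400.0)
    last = layout_a.target(25)
    miss = pd.DataFrame([[34000.0, last.x + 2.0, last.y]], columns=["t_ms", "x", "y"])
    clicks = pd.concat([clicks.iloc[:-1], miss, clicks.iloc[[-1]]], ignore_index=True)
    trial = Trial(layout=layout_a, clicks=clicks, fixations=_fix([]), saccades=pd.DataFrame(), start_ms=0.0)
    assert completion_time(trial) == pytest.approx(35.0)


def test_unfinished_trial_has_undefined_completion_time(layout_a):
    clicks = perfect_clicks(layout_a).iloc[:-1]  # target 25 never hit
    trial = Trial(layout=layout_a, clicks=clicks, fixations=_fix([]), saccades=pd.DataFrame())
    assert math.isnan(completion_time(trial))


def test_resolve_clicks_tracks_current_target(layout_a):
    pos = layout_a.positions()
    rows = [
        (100.0, pos[0, 0], pos[0, 1]),  # hit 1
        (200.0, pos[4, 0], pos[4, 1]),  # miss (current is 2)
        (300.0, pos[1, 0], pos[1, 1]),  # hit 2
    ]
    res = resolve_clicks(_clicks(rows), layout_a)
    assert res["correct"].tolist() == [True, False, True]
    assert res["target"].tolist() == [1, 2, 2]


# ---------------------------------------------------------------------------
# speed-accuracy slope


def _clicks_with_accuracy(layout, accuracies, step_ms=1000.0, rts=None):
    """Clicks in sequence order whose relative accuracy is prescribed."""
    pos = layout.positions()
    rows = []
    t = 0.0
    for i, a in enumerate(accuracies):
        t = t + (rts[i] if rts is not None else step_ms)
        d = (1 - a) * layout.targets[0].radius
        rows.append((t, pos[i, 0] + d, pos[i, 1]))
    return _clicks(rows)


def test_noiseless_linear_relation_recovers_slope(layout_a):
    # construct log-odds(accuracy) = 0.001 * RT exactly
    rts = np.linspace(800, 2000, 25)
    logodds = 0.001 * rts
    accs = 1 / (1 + np.exp(-logodds))
    clicks = _clicks_with_accuracy(layout_a, accs, rts=rts)
    trial = Trial(layout=layout_a, clicks=clicks, fixations=_fix([]), saccades=pd.DataFrame())
    assert speed_accuracy_slope(trial, eps=1e-9) == pytest.approx(0.001, rel=1e-6)


def test_constant_accuracy_gives_zero_slope(layout_a):
    clicks = _clicks_with_accuracy(layout_a, np.full(25, 0.5), rts=np.linspace(500, 3000, 25))
    trial = Trial(layout=layout_a, clicks=clicks, fixations=_fix([]), saccades=pd.DataFrame())
    assert speed_accuracy_slope(trial) == 0.0


def test_slope_matches_closed_form_ols(layout_a):
    rng = np.random.default_rng(8)
    accs = rng.uniform(0.1, 0.9, 25)
    rts = rng.uniform(600, 2500, 25)
    clicks = _clicks_with_accuracy(layout_a, accs, rts=rts)
    trial = Trial(layout=layout_a, clicks=clicks, fixations=_fix([]), saccades=pd.DataFrame())
    got = speed_accuracy_slope(trial)
    # independent closed form on the same per-target data
    res = resolve_clicks(clicks, layout_a)
    a = np.clip(res["accuracy"].to_numpy(), 0.01, 0.99)
    y = np.log(a / (1 - a))
    x = np.diff(np.concatenate([[0.0], res["t_ms"].to_numpy()]))
    expected = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    assert got == pytest.approx(expected, abs=1e-12)


def test_too_few_targets_undefined(layout_a):
    clicks = _clicks_with_accuracy(layout_a, [0.5, 0.6])
    trial = Trial(layout=layout_a, clicks=clicks, fixations=_fix([]), saccades=pd.DataFrame())
    assert math.isnan(speed_accuracy_slope(trial))


# ---------------------------------------------------------------------------
# fixation labeling


def test_fixation_labels_follow_current_target_timeline(layout_a):
    pos = layout_a.positions()
    clicks = perfect_clicks(layout_a, start_ms=0.0, step_ms=1000.0)  # target i clicked at (i)*1000
    fixes = _fix(
        [
            (500.0, 700.0, pos[0, 0] + 1.0, pos[0, 1]),  # near target 1 before its click: guiding
            (1500.0, 1700.0, pos[3, 0] + 1.0, pos[3, 1]),  # near target 4 while current is 2: searching
            (1800.0, 1900.0, 15.0, 15.0),  # far from everything: unassigned
        ]
    )
    labeled = assign_fixations(fixes, layout_a, clicks)
    assert labeled["label"].tolist() == ["guiding", "searching", "unassigned"]
    assert labeled["object"].tolist()[:2] == [1, 4]
    assert count_fixation_types(labeled) == (3, 1, 1)


def test_counts_include_unassigned_in_total():
    labeled = pd.DataFrame({"label": ["guiding"] * 10 + ["searching"] * 90 + ["unassigned"] * 5})
    assert count_fixation_types(labeled) == (105, 10, 90)
    assert count_fixation_types(labeled.iloc[:0]) == (0, 0, 0)


# ---------------------------------------------------------------------------
# summary stats, scanpath, eye-hand span


def test_median_conventions():
    fix = _fix([(0, 100, 0, 0), (200, 400, 0, 0), (500, 800, 0, 0)])
    sacc = pd.DataFrame({"amplitude_deg": [1.0, 3.0]})
    mfd, msa = summary_stats(fix, sacc)
    assert mfd == 200.0
    assert msa == 2.0  # even count: midpoint
    assert summary_stats(fix.iloc[:0], sacc) == (pytest.approx(math.nan, nan_ok=True), 2.0)


def test_scanpath_simple_cases():
    assert scanpath_length(_fix([(0, 100, 0.0, 0.0)])) == 0.0
    assert scanpath_length(_fix([(0, 100, 0.0, 0.0), (200, 300, 3.0, 4.0)])) == pytest.approx(5.0)


def test_scanpath_matches_brute_force():
    rng = np.random.default_rng(0)
    pts = rng.uniform(-10, 10, size=(40, 2))
    fix = _fix([(i * 100.0, i * 100.0 + 50, p[0], p[1]) for i, p in enumerate(pts)])
    expected = sum(float(np.hypot(*(pts[i + 1] - pts[i]))) for i in range(39))
    assert scanpath_length(fix) == pytest.approx(expected, abs=1e-9)


def test_eye_hand_span_sign_convention(layout_a):
    pos = layout_a.positions()
    clicks = _clicks([(1300.0, pos[0, 0], pos[0, 1])])
    fix = _fix([(500.0, 900.0, pos[0, 0], pos[0, 1])])
    labeled = assign_fixations(fix, layout_a, clicks)
    assert eye_hand_span(labeled, clicks, layout_a) == pytest.approx(800.0)
    # hand leads eye: click before the guiding fixation onset
    clicks2 = _clicks([(400.0, pos[0, 0], pos[0, 1])])
    fix2 = _fix([(500.0, 900.0, pos[0, 0], pos[0, 1])])
    labeled2 = assign_fixations(fix2, layout_a, clicks2)
    assert eye_hand_span(labeled2, clicks2, layout_a) == pytest.approx(-100.0)


def test_eye_hand_span_undefined_without_guiding(layout_a):
    clicks = perfect_clicks(layout_a)
    fix = _fix([(100.0, 200.0, 20.0, 20.0)])  # unassigned only
    labeled = assign_fixations(fix, layout_a, clicks)
    assert math.isnan(eye_hand_span(labeled, clicks, layout_a))


# ---------------------------------------------------------------------------
# trial composition and aggregation


def test_partial_scoring_with_no_saccades(layout_a, flat_traits, noise_free_config):
    from trailgaze.synth import generate_trial_events

    ev = generate_trial_events(flat_traits, layout_a, "speed", seed=0, config=noise_free_config)
    trial = Trial(layout=layout_a, clicks=ev.clicks, fixations=ev.fixations, saccades=ev.saccades.iloc[:0])
    s = score_trial(trial)
    assert math.isnan(s.median_saccade_amplitude)
    assert s.n_fixations > 0 and not math.isnan(s.completion_time)
    # identical trial scored twice gives identical results
    assert score_trial(trial) == s


def test_guiding_plus_searching_bounded_by_total(layout_a, flat_traits, noise_free_config):
    from trailgaze.synth import generate_trial_events

    for seed in range(3):
        ev = generate_trial_events(flat_traits, layout_a, "speed", seed=seed, config=noise_free_config)
        trial = Trial(layout=layout_a, clicks=ev.clicks, fixations=ev.fixations, saccades=ev.saccades)
        s = score_trial(trial)
        assert s.n_guiding + s.n_searching <= s.n_fixations


def _long_scores(rows):
    return pd.DataFrame(rows, columns=["subject", "session", "trial", "completion_time"])


def test_aggregate_condition_averages_trials():
    scores = _long_scores(
        [("s1", 1, 1, 40.0), ("s1", 1, 2, 44.0), ("s1", 2, 1, 41.0), ("s1", 2, 2, 43.0),
         ("s2", 1, 1, 50.0), ("s2", 1, 2, 52.0), ("s2", 2, 1, 48.0), ("s2", 2, 2, 54.0)]
    )
    table = aggregate_condition(scores, "completion_time")
    assert table.loc["s1", "session1"] == pytest.approx(42.0)
    assert table.loc["s2", "session2"] == pytest.approx(51.0)


def test_aggregate_condition_keeps_single_trial_cells_and_drops_missing_sessions():
    scores = _long_scores(
        [("s1", 1, 1, 40.0), ("s1", 1, 2, math.nan), ("s1", 2, 1, 43.0),
         ("s2", 1, 1, 50.0)]  # s2 has no session 2
    )
    table = aggregate_condition(scores, "completion_time")
    assert list(table.index) == ["s1"]
    assert table.loc["s1", "session1"] == pytest.approx(40.0)


def test_aggregate_condition_rejects_unusable_input():
    with pytest.raises(ValueError):
        aggregate_condition(_long_scores([("s1", 1, 1, 40.0)]), "completion_time")
    scores = _long_scores([("s1", 1, 1, math.nan), ("s1", 2, 1, 40.0)])
    with pytest.raises(ValueError, match="no analyzable data"):
        aggregate_condition(scores, "completion_time")
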