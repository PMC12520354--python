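"""Per-repetition metrics, cost scores, and cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from r2play import (
    HRSample,
    Participant,
    RepetitionRecord,
    SessionRecord,
    TapEvent,
    best_of,
    compute_cost_scores,
    cost_score,
    seconds_per_tablet,
    summarize_cohort,
)
from r2play.scoring import avg_hr_over, round2

# frozen worked examples: (baseline, challenge) seconds/tablet -> printed cost
WORKED_EXAMPLES = {
    "exertion": (1.75, 1.94, 10.86),
    "cognitive_moderate": (1.65, 1.74, 5.45),
    "cognitive_high": (1.68, 2.06, 22.62),
    "auditory": (1.66, 1.81, 9.04),
    "scramble": (1.18, 1.44, 22.03),
    "fatigue": (0.83, 0.93, 12.05),
}


def _rep(level="number_letter", cond="standard", n=1, start=0.0, end=21.0,
         n_correct=12, n_errors=0, pauses=()):
    taps = []
    dt = (end - start) / (n_correct + n_errors + 1)
    t = start
    for _ in range(n_errors):
        t += dt
        taps.append(TapEvent(t, "T1", "1", False))
    for _ in range(n_correct):
        t += dt
        taps.append(TapEvent(t, "T2", "A", True))
    return RepetitionRecord(level, cond, n, start, end, tuple(taps), tuple(pauses))


class TestSecondsPerTablet:
    def test_plain_division(self):
        assert seconds_per_tablet(_rep(end=21.0, n_correct=12)) == pytest.approx(1.75)

    def test_exercise_pause_excluded_by_default(self):
        rep = _rep(level="exercise", end=30.0, n_correct=12, pauses=((10.0, 16.0),))
        assert seconds_per_tablet(rep) == pytest.approx(2.0)
        assert seconds_per_tablet(rep, pause_exclusion=False) == pytest.approx(2.5)

    def test_reduced_selection_count(self):
        rep = _rep(level="stroop", end=16.48, n_correct=8)
        assert seconds_per_tablet(rep) == pytest.approx(2.06)

    def test_zero_correct_taps_undefined(self):
        rep = RepetitionRecord("number_letter", "standard", 1, 0.0, 10.0)
        assert seconds_per_tablet(rep) is None


class TestBestOf:
    def test_minimum_for_each_metric(self):
        assert best_of([1.8, 1.7]) == 1.7
        assert best_of([0, 2]) == 0
        assert best_of([None, 142.0]) == 142.0

    def test_all_undefined(self):
        assert best_of([None, None]) is None


class TestCostScore:
    @pytest.mark.parametrize("name", sorted(WORKED_EXAMPLES))
    def test_worked_examples(self, name):
        base, chal, printed = WORKED_EXAMPLES[name]
        assert round2(cost_score(base, chal).value) == printed

    def test_no_change_is_zero(self):
        assert cost_score(1.5, 1.5).value == 0.0

    def test_zero_baseline_undefined(self):
        cv = cost_score(0, 3)
        assert not cv.defined
        assert cv.reason == "zero_baseline"

    def test_missing_input_undefined(self):
        assert not cost_score(None, 1.0).defined
        assert not cost_score(1.0, None).defined

    @given(st.floats(0.1, 10), st.floats(0.1, 10))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_scaling_property(self, b, c):
        # cost(b, c) == -cost(c, b) * (c / b), re-derived from the definition
        forward = cost_score(b, c).value
        backward = cost_score(c, b).value
        assert forward == pytest.approx(-backward * (c / b), rel=1e-9)


def _full_session(spt_by_level, hr_stream=(), errors=0):
    """Build a session with controlled seconds/tablet per (level, condition)."""
    levels = []
    t = 400.0
    for kind in ("motor_pre", "number_letter", "exercise", "go_no_go", "stroop", "motor_post"):
        conds = (["standard", "standard"] if kind.startswith("motor")
                 else ["standard", "standard", "auditory", "scramble"])
        n_correct = 8 if kind in ("go_no_go", "stroop") else 12
        reps = []
        for i, cond in enumerate(conds, start=1):
            spt = spt_by_level[(kind, cond)]
            spt = spt[i - 1] if isinstance(spt, (list, tuple)) else spt
            end = t + spt * n_correct
            reps.append(_rep(kind, cond, i, t, end, n_correct, errors))
            t = end + 30.0
        levels.append((kind, tuple(reps)))
    return SessionRecord(
        participant=Participant("X", 14.0),
        configuration_interval=(0.0, 360.0),
        levels=tuple(levels),
        hr_stream=tuple(hr_stream),
    )


class TestComputeCostScores:
    def test_fatigue_cost_matches_worked_example(self):
        spt = {(k, c): 1.5 for k in
               ("motor_pre", "number_letter", "exercise", "go_no_go", "stroop", "motor_post")
               for c in ("standard", "auditory", "scramble")}
        spt[("motor_pre", "standard")] = [0.83, 0.90]   # best of two -> 0.83
        spt[("motor_post", "standard")] = [0.93, 0.95]  # best -> 0.93
        scores = compute_cost_scores(_full_session(spt))
        assert round2(scores.get("fatigue", "time").value) == 12.05

    def test_scramble_cost_matches_worked_example(self):
        spt = {}
        for k in ("motor_pre", "number_letter", "exercise", "go_no_go", "stroop", "motor_post"):
            for c in ("standard", "auditory", "scramble"):
                spt[(k, c)] = 1.18 if c != "scramble" else 1.44
        scores = compute_cost_scores(_full_session(spt))
        assert round2(scores.get("scramble", "time").value) == 22.03

    def test_level_costs_use_best_of_two_standards(self):
        spt = {(k, c): 1.0 for k in
               ("motor_pre", "number_letter", "exercise", "go_no_go", "stroop", "motor_post")
               for c in ("standard", "auditory", "scramble")}
        spt[("number_letter", "standard")] = [1.80, 1.75]  # best 1.75
        spt[("exercise", "standard")] = [1.94, 2.10]       # best 1.94
        scores = compute_cost_scores(_full_session(spt))
        assert round2(scores.get("exertion", "time").value) == 10.86

    def test_identical_metrics_give_zero_costs(self):
        spt = {(k, c): 1.6 for k in
               ("motor_pre", "number_letter", "exercise", "go_no_go", "stroop", "motor_post")
               for c in ("standard", "auditory", "scramble")}
        scores = compute_cost_scores(_full_session(spt))
        for cost in ("exertion", "cognitive_moderate", "cognitive_high",
                     "auditory", "scramble", "fatigue"):
            assert scores.get(cost, "time").value == pytest.approx(0.0)

    def test_error_cost_undefined_on_zero_baseline(self):
        spt = {(k, c): 1.6 for k in
               ("motor_pre", "number_letter", "exercise", "go_no_go", "stroop", "motor_post")
               for c in ("standard", "auditory", "scramble")}
        scores = compute_cost_scores(_full_session(spt, errors=0))
        cv = scores.get("exertion", "errors")
        assert not cv.defined
        assert cv.reason == "zero_baseline"

    def test_missing_level_marks_cost_undefined(self):
        spt = {(k, c): 1.6 for k in
               ("motor_pre", "number_letter", "exercise", "go_no_go", "stroop", "motor_post")
               for c in ("standard", "auditory", "scramble")}
        session = _full_session(spt)
        trimmed = SessionRecord(
            participant=session.participant,
            configuration_interval=session.configuration_interval,
            levels=tuple((k, reps) for k, reps in session.levels if k != "stroop"),
        )
        scores = compute_cost_scores(trimmed)
        assert scores.get("cognitive_high", "time").reason == "missing_level"
        assert scores.get("auditory", "time").reason == "missing_level"

    def test_no_hr_stream_marks_hr_costs_undefined(self):
        spt = {(k, c): 1.6 for k in
               ("motor_pre", "number_letter", "exercise", "go_no_go", "stroop", "motor_post")
               for c in ("standard", "auditory", "scramble")}
        scores = compute_cost_scores(_full_session(spt))
        assert scores.get("exertion", "hr").reason == "missing_hr"


class TestAvgHR:
    def test_constant_stream(self):
        stream = [HRSample(float(t), 150.0) for t in range(0, 100, 5)]
        assert avg_hr_over(stream, 10.0, 50.0) == pytest.approx(150.0)

    def test_linear_ramp_time_weighted(self):
        stream = [HRSample(float(t), 100.0 + t) for t in range(0, 61, 1)]
        assert avg_hr_over(stream, 0.0, 60.0) == pytest.approx(130.0)

    def test_no_samples_in_interval(self):
        stream = [HRSample(0.0, 100.0), HRSample(10.0, 110.0)]
        assert avg_hr_over(stream, 500.0, 600.0) is None


class TestSummarizeCohort:
    # per-participant peak HRs from the pilot cohort
    PEAKS = [184, 155, 196, 156, 155, 152, 184, 132, 158, 163]

    def test_pilot_peak_hr_row(self):
        s = summarize_cohort(self.PEAKS)
        assert s.n == 10
        assert s.mean == pytest.approx(163.5)
        assert round(s.sd_sample, 1) == 19.0
        assert round(s.ci95[0], 1) == 151.7
        assert round(s.ci95[1], 1) == 175.3

    def test_pilot_configuration_time_median(self):
        times = [5.38, 6.05, 4.42, 7.53, 3.46, 5.97, 6.34, 5.76, 6.16, 6.93]
        assert round(summarize_cohort(times).median, 2) == 6.01

    def test_single_value_has_no_sd_or_ci(self):
        s = summarize_cohort([5])
        assert s.mean == s.median == 5
        assert s.sd_sample is None and s.ci95 is None

    def test_none_values_are_skipped(self):
        s = summarize_cohort([1.0, None, 3.0])
        assert s.n == 2
        assert s.mean == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])

    def test_quartile_conventions_differ_on_small_n(self):
        vals = [1, 2, 3, 4, 5, 6, 7, 8]
        lin = summarize_cohort(vals, quartile="linear")
        tuk = summarize_cohort(vals, quartile="tukey")
        assert lin.median == tuk.median == 4.5
        assert lin.iqr == pytest.approx(3.5)
        assert tuk.iqr == pytest.approx(4.0)
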