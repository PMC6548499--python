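import numpy as np
import pandas as pd
import pytest

from opseq.assays import (
    average_repeated_tests,
    cno_suppression,
    collapse_pre_periods,
    devaluation_table,
    extract_cs_windows,
    feedback_summary,
    pavlovian_conditioning_score,
    period_response_table,
    pit_score,
)
from opseq.events_io import ValidationError
from opseq.microstructure import classify_presses
from opseq.simulator import SimConfig, simulate_pit_session
from conftest import make_log


def _pit_windows(first_onset=480.0, order=("CS+", "CS-") * 4):
    return [(cue, first_onset + i * 300.0, first_onset + i * 300.0 + 120.0)
            for i, cue in enumerate(order)]


class TestCsWindows:
    def test_canonical_pit_log(self):
        log = simulate_pit_session(SimConfig(press_rate_per_min=0.0,
                                             background_approach_rate_per_min=0.0,
                                             seed=0))
        windows = extract_cs_windows(log)
        assert len(windows) == 8
        assert sum(w.cs_type == "CS+" for w in windows) == 4

    def test_pre_window_arithmetic(self):
        log = make_log(cs_windows=[("CS+", 480.0, 600.0)], duration=900.0,
                       session_type="extinction")
        (w,) = extract_cs_windows(log)
        assert w.pre_onset_s == 360.0
        assert w.pre_contains(361.0) and not w.pre_contains(480.0)
        assert w.contains(480.0)  # press exactly at onset counts as CS

    def test_malformed_seven_cs_events_rejected(self):
        log = make_log(cs_windows=_pit_windows()[:4], duration=3000.0,
                       session_type="pit_test")
        log.events = [e for e in log.events if not
                      (e.event_type == "cs_offset" and e.time_s > 1400)]
        with pytest.raises(ValidationError):
            extract_cs_windows(log)

    def test_pre_window_overlap_rejected(self):
        log = make_log(cs_windows=[("CS+", 200.0, 320.0), ("CS-", 400.0, 520.0)],
                       duration=900.0, session_type="extinction")
        with pytest.raises(ValidationError, match="overlaps"):
            extract_cs_windows(log)


class TestPeriodTable:
    def _hand_log(self):
        # 3 presses inside CS+ windows (2 with approach), 1 press in pre-CS+
        return make_log(
            press_times=[400.0, 500.0, 520.0, 1100.0],
            entry_times=[500.5, 521.0],
            cs_windows=_pit_windows(order=("CS+", "CS-", "CS+", "CS-")),
            duration=2000.0,
            session_type="extinction",
        )

    def test_hand_built_counts(self):
        log = self._hand_log()
        windows = extract_cs_windows(log)
        table = period_response_table(log, windows, classify_presses(log))
        row = table.set_index(["cs_type", "period"])
        assert row.loc[("CS+", "CS"), "press_count"] == 3
        assert row.loc[("CS+", "CS"), "proportion_with_approach"] == pytest.approx(2 / 3)
        assert row.loc[("CS+", "preCS"), "press_count"] == 1
        assert row.loc[("CS-", "CS"), "press_count"] == 0
        assert np.isnan(row.loc[("CS-", "CS"), "proportion_with_approach"])

    def test_zero_press_log_undefined_proportions(self):
        log = make_log(cs_windows=_pit_windows(), duration=3000.0,
                       session_type="extinction")
        table = period_response_table(log, extract_cs_windows(log),
                                      classify_presses(log))
        assert (table["press_count"] == 0).all()
        assert table["proportion_with_approach"].isna().all()

    def test_press_count_conservation(self):
        log = simulate_pit_session(SimConfig(seed=3))
        windows = extract_cs_windows(log)
        cl = classify_presses(log)
        table = period_response_table(log, windows, cl)
        in_windows = table["press_count"].sum()
        out = sum(
            not any(w.contains(c.press_time_s) or w.pre_contains(c.press_time_s)
                    for w in windows)
            for c in cl
        )
        assert in_windows + out == len(cl)

    def test_collapse_pre_periods_conserves_counts(self):
        log = simulate_pit_session(SimConfig(seed=4))
        table = period_response_table(log, extract_cs_windows(log),
                                      classify_presses(log))
        collapsed = collapse_pre_periods(table)
        assert collapsed["press_count"].sum() == table["press_count"].sum()
        assert set(collapsed["cs_period"]) == {"CS+", "CS-", "Pre-CS"}


class TestScores:
    def _table(self, cs_all=30, pre_all=12, cs_with=10, pre_with=2):
        return pd.DataFrame(
            [
                {"cs_type": "CS+", "period": "CS", "press_count": cs_all,
                 "presses_with_approach": cs_with,
                 "presses_without_approach": cs_all - cs_with},
                {"cs_type": "CS+", "period": "preCS", "press_count": pre_all,
                 "presses_with_approach": pre_with,
                 "presses_without_approach": pre_all - pre_with},
            ]
        )

    def test_score_arithmetic(self):
        assert pit_score(self._table()) == 18
        assert pit_score(self._table(cs_all=12, pre_all=12)) == 0

    def test_additivity_across_press_types(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cs_all, pre_all = rng.integers(0, 60, 2)
            cs_w = rng.integers(0, cs_all + 1)
            pre_w = rng.integers(0, pre_all + 1)
            t = self._table(int(cs_all), int(pre_all), int(cs_w), int(pre_w))
            assert pit_score(t, "all") == (
                pit_score(t, "with_approach") + pit_score(t, "without_approach")
            )

    def test_cno_suppression_antisymmetric(self):
        assert cno_suppression(10, 10) == 0
        assert cno_suppression(5, 18) == -13
        assert cno_suppression(3, 8) == -cno_suppression(8, 3)

    def test_average_repeated_tests(self):
        scores = pd.DataFrame(
            {"subject_id": ["r1", "r1", "r1", "r1"],
             "drug": ["vehicle", "vehicle", "cno", "cno"],
             "score": [10.0, 14.0, 2.0, 6.0]}
        )
        avg = average_repeated_tests(scores).set_index("drug")["score"]
        assert avg["vehicle"] == 12.0 and avg["cno"] == 4.0


class TestDevaluationTable:
    def test_construction_and_phase_boundary(self):
        log = make_log(
            press_times=[10.0, 20.0, 30.0, 40.0, 350.0],
            entry_times=[10.5, 30.5],
            press_args={0: "devalued", 1: "valued", 2: "devalued", 3: "valued",
                        4: "valued"},
            session_type="devaluation_test",
            duration=1200.0,
        )
        table = devaluation_table(log, classify_presses(log))
        t = table.set_index(["lever", "press_type"])
        assert t.loc[("devalued", "all"), "press_count"] == 2
        assert t.loc[("valued", "all"), "press_count"] == 2  # press at 350 excluded
        # both entries follow devalued presses
        assert t.loc[("devalued", "all"), "proportion_with_approach"] == 1.0
        assert t.loc[("valued", "all"), "proportion_with_approach"] == 0.0

    def test_wrong_session_type_rejected(self):
        with pytest.raises(ValidationError):
            devaluation_table(make_log(), [])


class TestPavlovianScore:
    def test_hand_traced_rates(self):
        """CS onset 100, first pellet 130, three entries before it: rate is
        3 entries / 0.5 min = 6 per min."""
        log = make_log(
            entry_times=[105.0, 110.0, 120.0],
            pellet_times=[130.0, 160.0],
            cs_windows=[("CS+", 100.0, 220.0)],
            session_type="pavlovian",
            duration=500.0,
        )
        (row,) = pavlovian_conditioning_score(log).to_dict("records")
        assert row["cs_rate_per_min"] == pytest.approx(6.0)
        assert row["pre_cs_rate_per_min"] == 0.0

    def test_entries_after_first_pellet_excluded(self):
        log = make_log(
            entry_times=[135.0, 140.0],
            pellet_times=[130.0],
            cs_windows=[("CS+", 100.0, 220.0)],
            session_type="pavlovian",
            duration=500.0,
        )
        (row,) = pavlovian_conditioning_score(log).to_dict("records")
        assert row["cs_rate_per_min"] == 0.0

    def test_no_entries_zero_rates(self):
        log = make_log(cs_windows=[("CS+", 200.0, 320.0)],
                       session_type="pavlovian", duration=600.0)
        (row,) = pavlovian_conditioning_score(log).to_dict("records")
        assert row["cs_rate_per_min"] == 0.0
        assert row["pre_cs_rate_per_min"] == 0.0


class TestFeedbackSummary:
    def test_hand_built_counts(self):
        log = make_log(
            press_times=[10.0, 20.0, 30.0],
            entry_times=[20.5],
            dispenser_times=[20.0],
            session_type="feedback_test",
        )
        log.condition_tags["feedback_mode"] = "cues_only"
        table = feedback_summary([log], {"s1": classify_presses(log)})
        t = table.set_index("reinforced")
        assert t.loc[True, "press_count"] == 1
        assert t.loc[True, "proportion_with_approach"] == 1.0
        assert t.loc[False, "press_count"] == 2
        assert t.loc[False, "presses_with_approach"] == 0

    def test_dispenser_cue_alone_drives_reinforced_status(self):
        """Removing pellet rows while keeping dispenser cues leaves the
        classification unchanged (cues-only equivalence)."""
        with_food = make_log(press_times=[10.0, 20.0], entry_times=[10.4],
                             pellet_times=[10.0], dispenser_times=[10.0])
        cues_only = make_log(press_times=[10.0, 20.0], entry_times=[10.4],
                             dispenser_times=[10.0])
        a = classify_presses(with_food)
        b = classify_presses(cues_only)
        assert [(c.reinforced, c.with_approach) for c in a] == [
            (c.reinforced, c.with_approach) for c in b
        ]

    def test_no_feedback_session_has_zero_reinforced(self):
        log = make_log(press_times=[1.0, 2.0], session_type="feedback_test")
        log.condition_tags["feedback_mode"] = "no_food_or_cues"
        table = feedback_summary([log], {"s1": classify_presses(log)})
        assert table.set_index("reinforced").loc[True, "press_count"] == 0
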