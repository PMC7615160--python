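"""Temporal event-history categories on the QoL and cost clocks."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvburden.events import (
    EVENT_TYPES,
    GT3,
    NO_EVENT,
    Y0,
    Y1_2,
    Y2_3,
    YEAR_DAYS,
    AdverseEvent,
    classify_fatal,
    cost_categories_frame,
    cost_category,
    label_members,
    merged_label,
    qol_categories_frame,
    qol_category,
)


class TestQolClock:
    @pytest.mark.parametrize(
        "days, qol_day, expected",
        [
            ([], 1460, NO_EVENT),
            ([100, 600], 1460, Y2_3),        # last occurrence governs: gap 2.35y
            ([1440], 1460, Y0),
            ([1460], 1460, Y0),              # event on the measurement day
            ([1460 - 365.25], 1460, Y0),     # boundary gap exactly 1y is "<=1 year"
            ([1460 - 366], 1460, Y1_2),
            ([10], 1460, GT3),
        ],
    )
    def test_examples(self, days, qol_day, expected):
        assert qol_category(days, qol_day) == expected

    def test_all_events_after_measurement_warn_and_ignore(self, caplog):
        with caplog.at_level(logging.WARNING, logger="cvburden.events"):
            assert qol_category([1500], 1460) == NO_EVENT
        assert any("after the QoL measurement" in r.message for r in caplog.records)

    def test_negative_qol_day_rejected(self):
        with pytest.raises(ValueError):
            qol_category([10], -1)


class TestCostClock:
    @pytest.mark.parametrize(
        "first_day, k, expected",
        [
            (400, 1, Y0),
            (400, 2, Y1_2),
            (400, 3, Y2_3),
            (400, 5, GT3),
            (400, 0, NO_EVENT),       # pre-event periods are unexposed
            (None, 3, NO_EVENT),
            (np.nan, 3, NO_EVENT),
        ],
    )
    def test_examples(self, first_day, k, expected):
        assert cost_category(first_day, k) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cost_category(-1.0, 0)
        with pytest.raises(ValueError):
            cost_category(10.0, -1)

    @settings(max_examples=200, deadline=None)
    @given(first_day=st.floats(0, 4000), horizon=st.integers(1, 12))
    def test_monotone_progression_and_exhaustiveness(self, first_day, horizon):
        """Across successive periods the category follows
        NO_EVENT* -> Y0 -> Y1_2 -> Y2_3 -> GT3* with no other pattern."""
        seq = [cost_category(first_day, k) for k in range(horizon)]
        allowed = [NO_EVENT, Y0, Y1_2, Y2_3, GT3]
        assert all(c in allowed for c in seq)  # exhaustive labels
        order = [allowed.index(c) for c in seq]
        diffs = np.diff(order)
        # strictly stepping one category at a time once exposed,
        # except the jump NO_EVENT -> Y0, and GT3 absorbs
        for prev, nxt in zip(seq, seq[1:]):
            if prev == NO_EVENT:
                assert nxt in (NO_EVENT, Y0)
            elif prev == GT3:
                assert nxt == GT3
            else:
                assert allowed.index(nxt) == allowed.index(prev) + 1


class TestFatalClassification:
    @pytest.mark.parametrize(
        "event_day, death_day, fatal",
        [(100, 200, True), (100, 500, False), (100, None, False), (400, 420, True)],
    )
    def test_same_annual_period_rule(self, event_day, death_day, fatal):
        assert classify_fatal(event_day, death_day) is fatal


class TestClockDifference:
    def test_recurrence_moves_qol_clock_only(self):
        """A repeat event pulls the QoL category toward the event year
        but leaves the (first-occurrence) cost clock unchanged."""
        qol_day = 4 * YEAR_DAYS
        single = qol_category([100.0], qol_day)
        repeated = qol_category([100.0, qol_day - 30], qol_day)
        assert single == GT3 and repeated == Y0
        for k in range(4):
            assert cost_category(100.0, k) == cost_category(100.0, k)
            # first occurrence governs regardless of later events
            assert cost_category(min(100.0, qol_day - 30), k) == cost_category(100.0, k)


class TestFrames:
    def _events(self):
        return pd.DataFrame(
            {
                "participant_id": [0, 0, 1, 2],
                "event_type": ["mi", "mi", "stroke", "vascular_death"],
                "day": [100.0, 900.0, 1400.0, 600.0],
            }
        )

    def test_qol_frame_matches_scalar_rule(self):
        qol_days = pd.Series({0: 1461.0, 1: 1461.0})
        out = qol_categories_frame(self._events(), qol_days)
        assert out.loc[0, "qcat_mi"] == qol_category([100, 900], 1461)
        assert out.loc[1, "qcat_stroke"] == qol_category([1400], 1461)
        assert out.loc[1, "qcat_mi"] == NO_EVENT

    def test_cost_frame_matches_scalar_rule(self):
        py = pd.DataFrame({"participant_id": [0, 0, 0, 0, 2], "period": [0, 1, 2, 3, 1]})
        out = cost_categories_frame(self._events(), py)
        for row in out.itertuples():
            assert row.ccat_mi == cost_category(100.0 if row.participant_id == 0 else None, row.period)
        vd = out[out.participant_id == 2].iloc[0]
        assert vd.ccat_vascular_death == Y0

    def test_exactly_one_category_per_cell(self, small_cohort):
        """Exhaustiveness on generated data: every (participant, period,
        type) cell carries exactly one valid label."""
        py = small_cohort.person_years
        for etype in EVENT_TYPES:
            assert py[f"ccat_{etype}"].isin([NO_EVENT, Y0, Y1_2, Y2_3, GT3]).all()

    def test_certain_admission_flag(self, small_cohort):
        py = small_cohort.person_years
        expect = np.zeros(len(py), dtype=bool)
        for etype in ("crv_urgent", "crv_nonurgent", "hf_admission"):
            expect |= (py[f"ccat_{etype}"] == Y0).to_numpy()
        assert (py["certain_admission"].to_numpy() == expect).all()


def test_merged_label_round_trip():
    assert merged_label((Y2_3, GT3)) == "y2_3+gt3"
    assert label_members("y1_2+y2_3+gt3") == (Y1_2, Y2_3, GT3)
    with pytest.raises(ValueError):
        merged_label((Y0, Y2_3))  # not consecutive


def test_adverse_event_validation():
    with pytest.raises(ValueError):
        AdverseEvent(1, "unknown_type", 10.0)
    with pytest.raises(ValueError):
        AdverseEvent(1, "mi", -1.0)
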