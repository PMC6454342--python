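"""Event pairing, proactive classification, day assembly and sleep exclusion."""

from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screenuse import (
    FixedWindow,
    LongestOvernightGap,
    NoSleepExclusion,
    StudyConfig,
    apply_sleep_exclusion,
    build_day_sequences,
    classify_proactive,
    pair_screen_events,
)
from screenuse.episodes import DAY_S, extract_user_days

from conftest import BASE_DAY_S, make_day

H = 3600.0


def _pair(seq):
    """seq: list of (seconds, 'on'|'off'|'notif')."""
    names = {"on": "screen_on", "off": "screen_off", "notif": "notification"}
    times = np.array([s for s, _ in seq], dtype=float)
    types = np.array([names[k] for _, k in seq])
    return pair_screen_events(types, times)


class TestPairing:
    def test_single_pair(self):
        on, off, qc = _pair([(36000, "on"), (36300, "off")])
        assert list(on) == [36000] and list(off) == [36300]
        assert qc.total_anomalies() == 0

    def test_second_on_supersedes_first(self):
        on, off, qc = _pair([(36000, "on"), (36120, "on"), (36300, "off")])
        assert list(on) == [36120] and list(off) == [36300]
        assert qc.superseded_screen_on == 1

    def test_orphan_off_dropped(self):
        on, off, qc = _pair([(32400, "off")])
        assert len(on) == 0
        assert qc.orphan_screen_off == 1

    def test_zero_length_dropped(self):
        on, off, qc = _pair([(100, "on"), (100, "off"), (200, "on"), (300, "off")])
        assert list(on) == [200]
        assert qc.zero_length_interval == 1

    def test_touching_intervals_merged(self):
        on, off, qc = _pair([(100, "on"), (200, "off"), (200, "on"), (400, "off")])
        assert list(on) == [100] and list(off) == [400]
        assert qc.merged_zero_gap == 1

    def test_trailing_on_counted(self):
        on, off, qc = _pair([(100, "on"), (200, "off"), (300, "on")])
        assert list(off) == [200]
        assert qc.unterminated_screen_on == 1

    def test_notifications_ignored_for_pairing(self):
        on, off, qc = _pair([(50, "notif"), (100, "on"), (90, "notif"), (200, "off")])
        assert list(on) == [100]
        assert qc.total_anomalies() == 0


class TestClassifyProactive:
    def test_notification_30s_before_is_reactive(self):
        assert classify_proactive(1000.0, np.array([970.0])) is False

    def test_notification_61s_before_is_proactive(self):
        assert classify_proactive(1000.0, np.array([939.0])) is True

    def test_no_notifications_is_proactive(self):
        assert classify_proactive(1000.0, np.array([])) is True

    def test_window_boundaries_half_open(self):
        # exactly 60 s before: inside the window; exactly at screen-on: outside
        assert classify_proactive(1000.0, np.array([940.0])) is False
        assert classify_proactive(1000.0, np.array([1000.0])) is True

    @given(
        start=st.floats(1000, 1e6),
        offsets=st.lists(st.floats(0.0, 500.0), max_size=5),
        w1=st.floats(1.0, 300.0),
        w2=st.floats(1.0, 300.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_enlarging_window_only_flips_toward_reactive(self, start, offsets, w1, w2):
        notifs = np.sort(start - np.array(offsets))
        small, large = min(w1, w2), max(w1, w2)
        if not classify_proactive(start, notifs, small):
            assert not classify_proactive(start, notifs, large)


class TestDayAssembly:
    def test_midnight_crossing_use_split(self):
        # use 23:50 -> 00:10 next day: 600 s to each side of midnight
        on = np.array([BASE_DAY_S + 23 * H + 50 * 60])
        off = np.array([BASE_DAY_S + DAY_S + 10 * 60])
        cfg = StudyConfig(exclude_first_last_day=False, sleep_policy="none")
        days = build_day_sequences("u", on, off, np.array([True]), cfg)
        assert len(days) == 2
        first_use = days[0].duration[days[0].is_use]
        second_use = days[1].duration[days[1].is_use]
        assert first_use.sum() == pytest.approx(600)
        assert second_use.sum() == pytest.approx(600)
        for d in days:
            d.validate()

    def test_within_day_sequence_and_edge_nonuse(self):
        # uses 09:00-09:10 and 10:00-10:05 -> use 600, nonuse 3000, use 300,
        # plus midnight-bounded nonuse on both edges
        on = BASE_DAY_S + np.array([9 * H, 10 * H])
        off = BASE_DAY_S + np.array([9 * H + 600, 10 * H + 300])
        cfg = StudyConfig(exclude_first_last_day=False, sleep_policy="none")
        (day,) = build_day_sequences("u", on, off, np.array([True, True]), cfg)
        day.validate()
        assert list(day.duration) == pytest.approx(
            [9 * H, 600, 3000, 300, DAY_S - (10 * H + 300)]
        )
        assert list(day.is_use) == [False, True, False, True, False]
        assert day.duration.sum() == pytest.approx(DAY_S)  # conservation

    def test_first_last_day_excluded(self):
        on = np.array([BASE_DAY_S + 10 * H, BASE_DAY_S + DAY_S + 10 * H,
                       BASE_DAY_S + 2 * DAY_S + 10 * H])
        off = on + 300
        cfg = StudyConfig(sleep_policy="none")  # exclusion on by default
        days = build_day_sequences("u", on, off, np.ones(3, bool), cfg)
        assert [d.date for d in days] == [date(2017, 3, 9)]

    def test_no_exclusion_keeps_all_days(self):
        on = np.array([BASE_DAY_S + 10 * H, BASE_DAY_S + 2 * DAY_S + 10 * H])
        off = on + 300
        cfg = StudyConfig(exclude_first_last_day=False, sleep_policy="none")
        days = build_day_sequences("u", on, off, np.ones(2, bool), cfg)
        # middle day has no uses: a single all-day nonuse episode
        assert len(days) == 3
        assert not days[1].is_use.any()
        assert days[1].duration.sum() == pytest.approx(DAY_S)


class TestSleepExclusion:
    def test_none_policy_is_identity(self):
        day = make_day([10 * H, 600, 3000, 300], first_kind="nonuse")
        out = apply_sleep_exclusion(day, NoSleepExclusion())
        assert not out.sleep_excluded.any()

    def test_fixed_window_full_overlap(self):
        # nonuse 01:10-06:00 inside window 00:00-07:00 -> fully flagged,
        # plus the leading gap [0,1h) and the 06:05-07:00 part of the trailer
        day = make_day([1 * H, 600, 5 * H - 600, 300], first_kind="nonuse")
        out = apply_sleep_exclusion(day, FixedWindow(0.0, 7.0))
        flagged = out.duration[out.sleep_excluded & ~out.is_use]
        assert flagged.sum() == pytest.approx(1 * H + (5 * H - 600) + 55 * 60)
        assert out.duration.sum() == pytest.approx(day.duration.sum())

    def test_fixed_window_partial_overlap_is_split(self):
        # nonuse 06:00-09:00 against window 00:00-07:00: only 06-07 flagged
        day = make_day([6 * H, 60, 3 * H - 60, 120], first_kind="nonuse")
        out = apply_sleep_exclusion(day, FixedWindow(0.0, 7.0))
        ex = out.duration[out.sleep_excluded].sum()
        assert ex == pytest.approx(6 * H + (7 * H - (6 * H + 60)))
        assert out.duration.sum() == pytest.approx(day.duration.sum())
        assert not out.sleep_excluded[out.is_use].any()

    def test_longest_overnight_gap_flags_exactly_that_gap(self):
        # nonuse 00:00-06:00 (6 h, overlaps night 21-11), use 600 s,
        # nonuse 06:10-08:10 (2 h, too short), use until midnight exactly
        durs = [6 * H, 600, 2 * H, DAY_S - (6 * H + 600 + 2 * H)]
        day = make_day(durs, first_kind="nonuse")
        out = apply_sleep_exclusion(day, LongestOvernightGap(min_hours=4))
        assert list(out.sleep_excluded) == [True, False, False, False]

    def test_longest_overnight_gap_respects_min_hours(self):
        # trailing gap 05:20-24:00 (~18.7 h) is the longest night overlap
        day = make_day([3 * H, 600, 2 * H, 600], first_kind="nonuse")
        out = apply_sleep_exclusion(day, LongestOvernightGap(min_hours=4))
        assert list(out.sleep_excluded) == [False, False, False, False, True]
        # with a 22 h minimum nothing qualifies
        short = apply_sleep_exclusion(day, LongestOvernightGap(min_hours=22))
        assert not short.sleep_excluded.any()

    def test_use_episodes_never_flagged(self, small_cohort, config):
        grp = small_cohort.events[small_cohort.events.user_id == "u1"]
        days, _ = extract_user_days(grp, config)
        for d in days:
            assert not d.sleep_excluded[d.is_use].any()
            d.validate()


class TestConservation:
    def test_generated_days_tile_86400_seconds(self, small_cohort, config):
        grp = small_cohort.events[small_cohort.events.user_id == "u2"]
        days, qc = extract_user_days(grp, config)
        assert qc.total_anomalies() == 0
        assert len(days) == 2 * 7 - 2  # first/last day excluded
        for d in days:
            assert d.duration.sum() == pytest.approx(DAY_S, abs=1e-6)
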