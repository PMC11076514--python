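"""Event scoring: percept extraction, switch rates, real-switch matching."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cylsfm import (
    KeypressEvent,
    ObserverParams,
    block_switch_rate,
    count_switches,
    extract_percepts,
    score_real_switch,
    simulate_bistable_block,
    subject_metrics,
)
from cylsfm.records import BlockRecord, SessionRecord
from cylsfm.scoring import MIN_CORRECT, block_metrics, metrics_from_counts
from cylsfm.stimulus import CylinderParams, SwitchSchedule, make_real_switch_schedule


def ev(*pairs):
    return [KeypressEvent(t=float(t), key=k) for t, k in pairs]


class TestExtractPercepts:
    def test_basic_intervals(self):
        events = ev((2, "left"), (10, "right"), (25, "left"))
        out = extract_percepts(events, 120.0)
        completed = [iv for iv in out if not iv.censored]
        assert [(iv.start, iv.end) for iv in completed] == [(2.0, 10.0), (10.0, 25.0)]
        assert [iv.duration for iv in completed] == [8.0, 15.0]
        tail = out[-1]
        assert tail.censored and (tail.start, tail.end) == (25.0, 120.0)

    def test_same_direction_repeats_ignored(self):
        out = extract_percepts(ev((2, "left"), (10, "left")), 120.0)
        assert [iv for iv in out if not iv.censored] == []
        assert out[-1].start == 2.0

    def test_empty_and_unsorted(self):
        assert extract_percepts([], 120.0) == []
        with pytest.raises(ValueError):
            extract_percepts(ev((10, "left"), (2, "right")), 120.0)

    @given(
        st.lists(
            st.tuples(st.floats(0.0, 120.0), st.sampled_from(["left", "right"])),
            max_size=40,
        )
    )
    def test_conservation_identity(self, pairs):
        """pre-response time + completed durations + censored tail == duration."""
        pairs.sort(key=lambda p: p[0])
        events = ev(*pairs)
        out = extract_percepts(events, 120.0)
        if not events:
            assert out == []
            return
        pre = events[0].t
        completed = sum(iv.duration for iv in out if not iv.censored)
        tail = out[-1].duration
        assert pre + completed + tail == pytest.approx(120.0, abs=1e-9)

    def test_switch_count_equals_completed_intervals(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = np.sort(rng.uniform(0, 120, rng.integers(0, 25)))
            keys = rng.choice(["left", "right"], size=t.size)
            events = ev(*zip(t, keys))
            out = extract_percepts(events, 120.0)
            assert count_switches(events) == sum(1 for iv in out if not iv.censored)


class TestCountAndRate:
    def test_direction_changes_only(self):
        assert count_switches(ev((2, "left"), (10, "right"), (25, "left"))) == 2
        assert count_switches(ev((2, "left"))) == 0
        assert count_switches(ev((2, "left"), (5, "left"), (9, "right"))) == 1

    def test_ideal_observer_counts_eleven(self, canonical_schedule):
        events = [KeypressEvent(t=0.5, key=canonical_schedule.directions[0])] + [
            KeypressEvent(t=t + 1.0, key=d)
            for t, d in zip(canonical_schedule.switch_times, canonical_schedule.directions[1:])
        ]
        assert count_switches(events) == 11

    def test_rate_arithmetic(self):
        rate, log10 = block_switch_rate(24, 120.0)
        assert rate == pytest.approx(0.2)
        assert log10 == pytest.approx(-0.69897, abs=1e-5)

    def test_zero_replacement(self):
        rate, log10 = block_switch_rate(0, 120.0)
        assert rate == 0.0
        assert log10 == pytest.approx(np.log10(0.5 / 120.0))

    def test_physical_rate(self):
        rate, _ = block_switch_rate(11, 120.0)
        assert rate == pytest.approx(0.0917, abs=5e-4)
        assert round(rate, 2) == 0.09

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            block_switch_rate(-1, 120.0)


def brute_force_credits(events, schedule, window):
    """Maximum bipartite matching between physical switches and responses
    (augmenting-path search); the independent oracle for the greedy scorer."""
    switches = list(zip(schedule.switch_times, schedule.directions[1:]))
    eligible = [
        [j for j, e in enumerate(events) if e.key == d and 0 <= e.t - t < window]
        for t, d in switches
    ]
    match_of_response: dict[int, int] = {}

    def augment(i, seen):
        for j in eligible[i]:
            if j in seen:
                continue
            seen.add(j)
            if j not in match_of_response or augment(match_of_response[j], seen):
                match_of_response[j] = i
                return True
        return False

    return sum(augment(i, set()) for i in range(len(switches)))


class TestRealSwitchScorer:
    def test_ideal_observer_included(self, canonical_schedule):
        events = [
            KeypressEvent(t=t + 1.0, key=d)
            for t, d in zip(canonical_schedule.switch_times, canonical_schedule.directions[1:])
        ]
        score = score_real_switch(events, canonical_schedule)
        assert score.n_correct == 11
        assert score.accuracy == pytest.approx(1.0)
        assert score.included
        assert score.mean_rt_correct == pytest.approx(1.0)

    def test_inclusion_boundary(self, canonical_schedule):
        def events_with_n_correct(n):
            return [
                KeypressEvent(t=t + 1.0, key=d)
                for t, d in list(
                    zip(canonical_schedule.switch_times, canonical_schedule.directions[1:])
                )[:n]
            ]

        assert not score_real_switch(events_with_n_correct(6), canonical_schedule).included
        assert score_real_switch(events_with_n_correct(7), canonical_schedule).included

    def test_boundary_accuracy_is_636_percent(self, canonical_schedule):
        assert round(100 * MIN_CORRECT / canonical_schedule.n_switches, 1) == 63.6

    def test_anticipation_never_credited(self, canonical_schedule):
        t0, d0 = canonical_schedule.switch_times[0], canonical_schedule.directions[1]
        score = score_real_switch([KeypressEvent(t=t0 - 0.5, key=d0)], canonical_schedule)
        assert score.n_correct == 0

    def test_late_response_uncredited_but_latency_recorded(self, canonical_schedule):
        t0, d0 = canonical_schedule.switch_times[0], canonical_schedule.directions[1]
        score = score_real_switch([KeypressEvent(t=t0 + 5.0, key=d0)], canonical_schedule)
        assert score.n_correct == 0
        assert score.mean_rt_all == pytest.approx(5.0)
        assert np.isnan(score.mean_rt_correct)

    def test_window_monotonicity(self, canonical_schedule):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 120, 15))
        events = ev(*zip(t, rng.choice(["left", "right"], 15)))
        prev = -1
        for w in (1.0, 2.0, 4.0, 8.0):
            n = score_real_switch(events, canonical_schedule, window=w).n_correct
            assert n >= prev
            prev = n

    def test_spontaneous_reversals_outside_windows_harmless(self, canonical_schedule):
        base = [
            KeypressEvent(t=t + 1.0, key=d)
            for t, d in zip(canonical_schedule.switch_times, canonical_schedule.directions[1:])
        ]
        # inject extra reports > 4 s after every switch (outside all windows)
        extra = [
            KeypressEvent(t=t + 6.0, key="left")
            for t in canonical_schedule.switch_times[:-1]
        ]
        events = sorted(base + extra, key=lambda e: e.t)
        assert score_real_switch(events, canonical_schedule).n_correct == 11

    def test_greedy_equals_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n_sw = int(rng.integers(2, 7))
            times = np.sort(rng.uniform(1, 110, n_sw))
            while np.any(np.diff(times) < 0.5):
                times = np.sort(rng.uniform(1, 110, n_sw))
            first = "left" if rng.random() < 0.5 else "right"
            dirs = [first]
            for _ in range(n_sw):
                dirs.append("right" if dirs[-1] == "left" else "left")
            schedule = SwitchSchedule(120.0, tuple(times), tuple(dirs))
            n_ev = int(rng.integers(0, 12))
            events = ev(*zip(
                np.sort(rng.uniform(0, 120, n_ev)), rng.choice(["left", "right"], n_ev)
            ))
            window = float(rng.choice([2.0, 4.0, 8.0]))
            greedy = score_real_switch(events, schedule, window=window).n_correct
            assert greedy == brute_force_credits(events, schedule, window)


class TestSubjectMetrics:
    def _session(self, blocks):
        return SessionRecord(subject_id="s1", group="control", session_index=1, blocks=blocks)

    def test_identical_blocks_mean_equals_block_value(self):
        events = ev((2, "left"), (10, "right"), (25, "left"))
        blocks = [
            BlockRecord(block_index=k, block_type="bistable", duration=120.0, events=list(events))
            for k in range(5)
        ]
        m = subject_metrics(self._session(blocks))
        bm = block_metrics(blocks[0])
        assert m.mean_log10_rate == pytest.approx(bm.log10_rate)
        assert m.block_log10_rates == (bm.log10_rate,) * 5

    def test_equal_durations_zero_cv(self):
        events = ev((0, "left"), (10, "right"), (20, "left"), (30, "right"))
        blocks = [BlockRecord(0, "bistable", 120.0, events)]
        m = subject_metrics(self._session(blocks))
        assert m.cv == pytest.approx(0.0)
        assert m.mean_duration == pytest.approx(10.0)

    def test_no_bistable_blocks_rejected(self, canonical_schedule):
        rs = BlockRecord(0, "real_switch", 120.0, [], schedule=canonical_schedule)
        with pytest.raises(ValueError):
            subject_metrics(self._session([rs]))

    def test_exponential_cv_converges_to_one(self):
        obs = ObserverParams(gamma_shape=1.0, gamma_scale=4.0)
        durations = []
        for s in range(40):
            block = simulate_bistable_block(obs, 1200.0, seed=s)
            durations += [
                iv.duration for iv in extract_percepts(block.events, 1200.0) if not iv.censored
            ]
        cv = np.std(durations, ddof=1) / np.mean(durations)
        assert abs(cv - 1.0) < 3 / np.sqrt(len(durations))

    def test_metrics_from_counts_matches_per_block_rule(self):
        import pandas as pd

        counts = pd.DataFrame(
            {
                "subject_id": ["a"] * 5,
                "group": ["control"] * 5,
                "session": [1] * 5,
                "block": range(1, 6),
                "n_switches": [24, 0, 11, 3, 50],
            }
        )
        per = metrics_from_counts(counts)
        expected = np.mean([block_switch_rate(n, 120.0)[1] for n in (24, 0, 11, 3, 50)])
        assert per.loc[0, "mean_log10_rate"] == pytest.approx(expected)
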