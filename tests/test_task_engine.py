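"""Controller unit and property tests: detection, classification, staircase,
entry rewards, and session orchestration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    brute_force_phase2,
    pull_hold_release,
    random_segment,
    staircase_from_counts,
    trace,
)
from levercage import (
    DEFAULT_CONFIG,
    LeverTrace,
    SessionEvent,
    TaskConfig,
    classify_trial_phase1,
    classify_trial_phase2,
    detect_trials,
    evaluate_block,
    process_entry,
    run_session,
)
from levercage.errors import (
    AngleRangeError,
    AttributionError,
    ConfigError,
    MalformedTraceError,
    ValidationError,
)
from levercage.task_engine import EntryRewardLedger, day_index


# ---------------------------------------------------------------------------
# config invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "bad",
    [
        dict(pull_threshold=30.0),
        dict(goal_low=13.0),
        dict(goal_high=25.0),
        dict(hold_init=900),
        dict(hold_step=0),
        dict(hold_step=300),  # does not divide 700
        dict(up_threshold=0.05),  # below down_threshold
        dict(block_size=0),
        dict(sample_period=30),  # does not divide hold_init
    ],
)
def test_config_invariants_rejected(bad):
    with pytest.raises(ConfigError):
        TaskConfig(**bad)


# ---------------------------------------------------------------------------
# trial detection
# ---------------------------------------------------------------------------


class TestDetectTrials:
    def test_flat_trace_yields_no_trials(self, config):
        assert detect_trials(trace(np.zeros(1000)), config) == []

    def test_two_pulls_two_trials(self, config):
        a = np.concatenate(
            [np.linspace(0, 14, 15), np.linspace(14, 0, 15),
             np.linspace(0, 13, 14), np.linspace(13, 0, 14)]
        )
        dets = detect_trials(trace(a), config)
        assert len(dets) == 2
        for t_init, seg in dets:
            assert seg.angles[0] >= config.pull_threshold

    def test_oscillation_without_rearm_is_one_trial(self, config):
        # lever dithers around the threshold but never returns below 1 deg
        a = np.array([0.0, 5.0] + [11.9, 12.1] * 50)
        dets = detect_trials(trace(a), config)
        assert len(dets) == 1

    def test_segment_runs_to_rearm_sample(self, config):
        a = np.array([0, 6, 13, 14, 10, 5, 0.5, 0, 12.5, 9, 0.2, 0])
        dets = detect_trials(trace(a), config)
        assert len(dets) == 2
        first = dets[0][1]
        # starts at the 13-deg crossing, ends at the first sample below 1 deg
        np.testing.assert_allclose(first.angles, [13, 14, 10, 5, 0.5])
        assert dets[0][0] == pytest.approx(0.02)  # 2 samples * 10 ms

    def test_open_segment_at_stream_end(self, config):
        a = np.concatenate([np.zeros(5), np.linspace(0, 14, 10)])
        dets = detect_trials(trace(a), config)
        assert len(dets) == 1  # never re-arms; runs to stream end

    def test_out_of_range_angles_rejected(self, config):
        with pytest.raises(AngleRangeError):
            detect_trials(trace([0, 25.0, 0]), config)

    def test_nonuniform_sampling_rejected(self):
        with pytest.raises(MalformedTraceError):
            LeverTrace.from_times([0, 10, 25], [0, 1, 2])

    def test_too_short_trace_rejected(self):
        with pytest.raises(MalformedTraceError):
            LeverTrace(0.0, np.array([1.0]))


# ---------------------------------------------------------------------------
# phase-1 classification
# ---------------------------------------------------------------------------


class TestPhase1:
    def test_detected_pull_is_rewarded_success(self, config):
        tr = pull_hold_release(peak=14, level=13, hold_ms=100)
        (t_init, seg), = detect_trials(tr, config)
        rec = classify_trial_phase1(seg, config, "m1")
        assert rec.outcome == "success"
        assert rec.reward_volume == config.trial_reward_volume == 10.0
        assert rec.t_outcome == rec.t_init == t_init

    def test_peak_exactly_at_threshold_triggers(self, config):
        tr = pull_hold_release(peak=12.0, level=11, hold_ms=50)
        dets = detect_trials(tr, config)
        assert len(dets) == 1


# ---------------------------------------------------------------------------
# phase-2 classification
# ---------------------------------------------------------------------------


class TestPhase2:
    def test_steady_hold_succeeds(self, config):
        seg = trace(np.full(91, 12.0))
        rec = classify_trial_phase2(seg, 800, config)
        assert rec.outcome == "success"
        assert rec.reward_volume == 10.0
        assert rec.t_outcome == pytest.approx(0.8)  # reward when hold elapses

    def test_range_exit_fails_at_first_bad_sample(self, config):
        a = np.concatenate([np.full(40, 12.0), [20.1], np.full(50, 12.0)])
        rec = classify_trial_phase2(trace(a), 800, config)
        assert rec.outcome == "failure"
        assert rec.reward_volume == 0.0
        assert rec.t_outcome == pytest.approx(0.40)

    @pytest.mark.parametrize("angle", [4.5, 19.5])
    def test_goal_range_boundaries_inclusive(self, config, angle):
        seg = trace(np.full(91, angle))
        assert classify_trial_phase2(seg, 800, config).outcome == "success"

    def test_truncated_segment_is_discarded(self, config):
        seg = trace(np.full(40, 12.0))  # ends before 800 ms, never exits
        assert classify_trial_phase2(seg, 800, config) is None

    def test_unrepresentable_hold_rejected(self, config):
        with pytest.raises(ConfigError):
            classify_trial_phase2(trace(np.full(91, 12.0)), 805, config)

    def test_matches_brute_force_oracle(self, config):
        rng = np.random.default_rng(7)
        for _ in range(300):
            seg = random_segment(rng, config)
            hold = int(rng.choice(config.hold_levels))
            rec = classify_trial_phase2(seg, hold, config)
            expected, idx = brute_force_phase2(seg, hold, config)
            if expected is None:
                assert rec is None
            else:
                assert rec.outcome == expected
                assert rec.t_outcome == pytest.approx(
                    seg.t0 + idx * config.sample_period / 1000.0)


# ---------------------------------------------------------------------------
# staircase rule
# ---------------------------------------------------------------------------


class TestEvaluateBlock:
    @pytest.mark.parametrize(
        "successes, hold, expected",
        [
            (19, 300, 400),   # 76% > 75% steps up
            (18, 300, 300),   # 72% in the dead zone
            (2, 300, 200),    # 8% < 10% steps down
            (3, 300, 300),    # 12% in the dead zone
            (25, 800, 800),   # ceiling clamp
            (0, 100, 100),    # floor clamp
            (13, 500, 500),   # 52% dead zone, mid-range
        ],
    )
    def test_block_rule(self, config, successes, hold, expected):
        assert evaluate_block(successes, 25, hold, config) == expected

    def test_exact_threshold_ties_do_not_move(self):
        cfg = TaskConfig(block_size=20)
        assert evaluate_block(15, 20, 300, cfg) == 300  # exactly 75%
        assert evaluate_block(2, 20, 300, cfg) == 300   # exactly 10%
        # 1/10 == 0.10 exactly must not step down despite float 0.1
        cfg10 = TaskConfig(block_size=10)
        assert evaluate_block(1, 10, 300, cfg10) == 300

    def test_invalid_counts_rejected(self, config):
        with pytest.raises(ValidationError):
            evaluate_block(26, 25, 300, config)
        with pytest.raises(ValidationError):
            evaluate_block(-1, 25, 300, config)

    @given(counts=st.lists(st.integers(0, 25), min_size=0, max_size=40))
    @settings(deadline=None)
    def test_staircase_bounded_and_on_lattice(self, counts):
        config = DEFAULT_CONFIG
        for hold in staircase_from_counts(counts, config):
            assert config.hold_init <= hold <= config.hold_max
            assert (hold - config.hold_init) % config.hold_step == 0

    def test_monotonicity_exhaustive_short_sequences(self, config):
        # elementwise-larger success sequences never yield a lower staircase
        levels = [0, 2, 3, 13, 19, 25]
        for a in itertools.product(levels, repeat=3):
            for b in itertools.product(levels, repeat=3):
                if not all(x >= y for x, y in zip(a, b)):
                    continue
                sa = staircase_from_counts(a, config)
                sb = staircase_from_counts(b, config)
                assert all(x >= y for x, y in zip(sa, sb)), (a, b)


# ---------------------------------------------------------------------------
# entry rewards
# ---------------------------------------------------------------------------


class TestEntryRewards:
    def test_first_entry_rewarded(self, config):
        ev = SessionEvent(30000.0, "m1", "entry")
        assert process_entry(ev, 0, config) == 5.0

    def test_cap_blocks_reward(self, config):
        ev = SessionEvent(30000.0, "m1", "entry")
        assert process_entry(ev, 200, config) == 0.0
        assert process_entry(ev, 199, config) == 5.0

    def test_wrong_event_kind_rejected(self, config):
        with pytest.raises(ValidationError):
            process_entry(SessionEvent(0.0, "m1", "exit"), 0, config)

    def test_ledger_caps_and_resets_at_lights_on(self, config):
        ledger = EntryRewardLedger(config)
        day0 = config.lights_on_hour * 3600.0
        rewarded = sum(
            ledger.on_entry(SessionEvent(day0 + i, "m1", "entry")) > 0
            for i in range(300)
        )
        assert rewarded == 200
        # first entry immediately after the next lights-on is rewarded again
        nxt = SessionEvent(day0 + 86400.0, "m1", "entry")
        assert ledger.on_entry(nxt) == 5.0

    def test_day_boundary_is_lights_on(self, config):
        on = config.lights_on_hour * 3600.0
        assert day_index(on - 1, config) == -1
        assert day_index(on, config) == 0
        assert day_index(on + 86399, config) == 0
        assert day_index(on + 86400, config) == 1


# ---------------------------------------------------------------------------
# session orchestration
# ---------------------------------------------------------------------------


def _visit_events(animal, t_in, t_out):
    return [SessionEvent(t_in, animal, "entry"), SessionEvent(t_out, animal, "exit")]


def _success_trace(t0):
    """One pull that holds 900 ms inside the goal range."""
    return pull_hold_release(peak=14, level=12, hold_ms=900, t0=t0)


class TestRunSession:
    def test_perfect_animal_reaches_max_after_175_trials(self, config):
        traces = [_success_trace(1000.0 + 3 * i) for i in range(200)]
        events = _visit_events("m1", 999.0, 1000.0 + 3 * 200)
        trials, out_events, states = run_session(events, traces, None, 2, config)
        assert len(trials) == 200
        st = states["m1"]
        assert st.required_hold == config.hold_max
        # history: hold after block k = min(100 + 100k, 800); first reaches
        # 800 at trial 175 and never before
        reached = [i for i, h in st.history if h == config.hold_max]
        assert min(reached) == 175

    def test_interleaved_animals_isolated(self, config):
        events, traces = [], []
        t = 1000.0
        for k in range(60):
            animal = "a" if k % 2 == 0 else "b"
            events += _visit_events(animal, t, t + 40.0)
            for j in range(5):
                traces.append(_success_trace(t + 1 + 5 * j))
            t += 50.0
        trials, _, states = run_session(events, traces, None, 2, config)
        solo_counts = {a: sum(1 for r in trials if r.animal_id == a) for a in "ab"}
        assert solo_counts == {"a": 150, "b": 150}
        # each animal's staircase equals a solo run of 150 successes
        for animal in "ab":
            assert states[animal].required_hold == 700  # 6 full blocks
            assert [h for _, h in states[animal].history] == [
                100, 200, 300, 400, 500, 600, 700]

    def test_phase1_volume_accounting(self, config):
        traces = [_success_trace(1000.0 + 3 * i) for i in range(200)]
        events = _visit_events("m1", 999.0, 1000.0 + 3 * 200)
        trials, out_events, _ = run_session(events, traces, None, 1, config)
        assert len(trials) == 200
        assert sum(r.reward_volume for r in trials) == 2000.0
        # conservation: 1 rewarded entry + 200 rewarded trials
        entry_volume = sum(e.payload["volume_ul"] for e in out_events
                           if e.kind == "entry_reward")
        assert entry_volume == 5.0

    def test_unattributed_trial_raises(self, config):
        events = _visit_events("m1", 0.0, 10.0)
        with pytest.raises(AttributionError):
            run_session(events, [_success_trace(50.0)], None, 1, config)

    def test_entry_exit_alternation_enforced(self, config):
        events = [SessionEvent(0.0, "m1", "entry"), SessionEvent(1.0, "m1", "entry")]
        with pytest.raises(ValidationError):
            run_session(events, [], None, 1, config)

    def test_deterministic_given_inputs(self, config):
        traces = [_success_trace(1000.0 + 3 * i) for i in range(60)]
        events = _visit_events("m1", 999.0, 1200.0)
        out1 = run_session(events, traces, None, 2, config)
        out2 = run_session(events, traces, None, 2, config)
        assert [(r.trial_id, r.outcome, r.t_init) for r in out1[0]] == [
            (r.trial_id, r.outcome, r.t_init) for r in out2[0]]
        assert [(e.t, e.kind, e.animal_id) for e in out1[1]] == [
            (e.t, e.kind, e.animal_id) for e in out2[1]]
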