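"""Closed-loop controller for the home-cage lever-positioning task.

The controller watches a stream of lever angles sampled at a fixed rate,
detects trials (a pull past the initiation threshold while armed), classifies
each trial against phase-specific rules, dispenses virtual water rewards, and
advances a per-animal adaptive staircase on the required hold duration.

Phase 1 (operant acquisition): any pull past ``pull_threshold`` is a rewarded
trial on a continuous reinforcement schedule.

Phase 2 (hold): after initiation the lever must remain inside the goal range
``[goal_low, goal_high]`` for the animal's current required hold duration.
The hold timer starts at the initiation sample; a sample outside the range
before the hold elapses fails the trial immediately. Every ``block_size``
trials the staircase steps the required duration up, down, or not at all
depending on the block success rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, TaskConfig
from .errors import (
    AngleRangeError,
    AttributionError,
    ConfigError,
    MalformedTraceError,
    ValidationError,
)

__all__ = [
    "LeverTrace",
    "StaircaseState",
    "TrialRecord",
    "SessionEvent",
    "EntryRewardLedger",
    "day_index",
    "hour_of_day",
    "detect_trials",
    "classify_trial_phase1",
    "classify_trial_phase2",
    "evaluate_block",
    "process_entry",
    "run_session",
]

SUCCESS = "success"
FAILURE = "failure"

# deterministic within-timestamp ordering of emitted events
_KIND_ORDER = {"entry": 0, "entry_reward": 1, "trial": 2, "staircase_change": 3, "exit": 4}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class LeverTrace:
    """Uniformly sampled lever angle (degrees from rest) versus time.

    Parameters
    ----------
    t0
        Absolute timestamp of the first sample, seconds since experiment start.
    angles
        Sampled lever angles, degrees from the counterweighted rest position.
    sample_period
        Sampling period in milliseconds.
    """

    t0: float
    angles: np.ndarray
    sample_period: int = 10

    def __post_init__(self) -> None:
        arr = np.asarray(self.angles, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise MalformedTraceError("a lever trace needs at least 2 samples")
        if self.sample_period <= 0:
            raise MalformedTraceError("sample_period must be positive")
        object.__setattr__(self, "angles", arr)

    @classmethod
    def from_times(
        cls, times_ms: Sequence[float], angles: Sequence[float], t0: float = 0.0
    ) -> "LeverTrace":
        """Build a trace from explicit sample times, enforcing uniform spacing."""
        t = np.asarray(times_ms, dtype=float)
        if t.size < 2:
            raise MalformedTraceError("a lever trace needs at least 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-6) or dt[0] <= 0:
            raise MalformedTraceError("non-uniform sample spacing")
        return cls(t0=t0 + t[0] / 1000.0, angles=np.asarray(angles, float),
                   sample_period=int(round(dt[0])))

    def __len__(self) -> int:
        return int(self.angles.size)

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the first sample."""
        return np.arange(len(self)) * float(self.sample_period)

    @property
    def times_s(self) -> np.ndarray:
        """Absolute sample times, seconds."""
        return self.t0 + self.times_ms / 1000.0

    @property
    def duration_ms(self) -> float:
        return (len(self) - 1) * float(self.sample_period)

    def slice(self, start: int, stop: int) -> "LeverTrace":
        """Sub-trace [start, stop) with an adjusted absolute start time."""
        return LeverTrace(
            t0=self.t0 + start * self.sample_period / 1000.0,
            angles=self.angles[start:stop],
            sample_period=self.sample_period,
        )


@dataclass
class StaircaseState:
    """Per-animal adaptive staircase: required hold plus within-block counters.

    ``history`` records ``(trial_index, required_hold)`` at creation and after
    every block evaluation, where ``trial_index`` is the cumulative number of
    scored phase-2 trials for this animal.
    """

    animal_id: str
    required_hold: int
    block_successes: int = 0
    block_trials: int = 0
    trial_count: int = 0
    history: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def new(cls, animal_id: str, config: TaskConfig = DEFAULT_CONFIG) -> "StaircaseState":
        st = cls(animal_id=animal_id, required_hold=config.hold_init)
        st.history.append((0, config.hold_init))
        return st

    def record(self, success: bool, config: TaskConfig = DEFAULT_CONFIG) -> Optional[int]:
        """Account one scored trial; evaluate the block when it completes.

        Returns the (possibly unchanged) required hold after a block
        evaluation, or ``None`` if the block is still open.
        """
        self.trial_count += 1
        self.block_trials += 1
        if success:
            self.block_successes += 1
        if self.block_trials < config.block_size:
            return None
        new_hold = evaluate_block(
            self.block_successes, config.block_size, self.required_hold, config
        )
        self.required_hold = new_hold
        self.block_successes = 0
        self.block_trials = 0
        self.history.append((self.trial_count, new_hold))
        return new_hold


@dataclass
class TrialRecord:
    """One classified trial."""

    animal_id: str
    phase: int
    t_init: float
    outcome: str
    reward_volume: float
    required_hold: Optional[int] = None
    t_outcome: Optional[float] = None
    trace: Optional[LeverTrace] = None
    trial_id: Optional[str] = None


@dataclass
class SessionEvent:
    """Timestamped, animal-tagged event (entry, exit, reward, trial, staircase)."""

    t: float
    animal_id: str
    kind: str
    payload: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# trial detection and classification
# ---------------------------------------------------------------------------


def detect_trials(
    trace_stream: LeverTrace, config: TaskConfig = DEFAULT_CONFIG
) -> list[tuple[float, LeverTrace]]:
    """Split a lever-angle stream into trial segments.

    The controller starts armed. A trial initiates at the first sample with
    angle >= ``pull_threshold`` while armed; the controller then disarms until
    the first subsequent sample with angle < ``rearm_threshold`` (hysteresis
    against re-triggering mid-pull). Segments run from the initiation sample
    to the re-arm sample inclusive, or to stream end.

    Returns a list of ``(t_init, segment)`` pairs in time order.
    """
    a = trace_stream.angles
    if np.any(a < 0) or np.any(a > config.lever_range_max):
        raise AngleRangeError(
            f"angles outside [0, {config.lever_range_max}] degrees"
        )
    segments: list[LeverTrace] = []
    armed = True
    start = 0
    # vectorised scan: alternate between "next crossing >= pull" and
    # "next sample < rearm"
    i = 0
    n = a.size
    while i < n:
        if armed:
            idx = np.nonzero(a[i:] >= config.pull_threshold)[0]
            if idx.size == 0:
                break
            start = i + int(idx[0])
            armed = False
            i = start + 1
        else:
            idx = np.nonzero(a[i:] < config.rearm_threshold)[0]
            if idx.size == 0:
                segments.append(trace_stream.slice(start, n))
                start = -1
                break
            end = i + int(idx[0])
            segments.append(trace_stream.slice(start, end + 1))
            armed = True
            i = end + 1
    return [(seg.t0, seg) for seg in segments]


def classify_trial_phase1(
    segment: LeverTrace, config: TaskConfig = DEFAULT_CONFIG, animal_id: str = ""
) -> TrialRecord:
    """Classify a detected segment under phase-1 rules.

    Every detected pull is a rewarded success on a continuous reinforcement
    schedule; the drop is dispensed at initiation.
    """
    return TrialRecord(
        animal_id=animal_id,
        phase=1,
        t_init=segment.t0,
        outcome=SUCCESS,
        reward_volume=config.trial_reward_volume,
        t_outcome=segment.t0,
        trace=segment,
    )


def classify_trial_phase2(
    segment: LeverTrace,
    required_hold: int,
    config: TaskConfig = DEFAULT_CONFIG,
    animal_id: str = "",
) -> Optional[TrialRecord]:
    """Classify a detected segment under phase-2 hold rules.

    Success iff every sample from initiation through ``required_hold`` ms later
    (inclusive on the sample lattice) lies within ``[goal_low, goal_high]``.
    The reward is dispensed when the hold elapses; a failure is recorded at the
    first out-of-range sample. A segment that ends (stream end / re-arm)
    before the hold elapses without ever leaving the range is not scored and
    returns ``None``.
    """
    if required_hold % config.sample_period != 0:
        raise ConfigError(
            f"required_hold {required_hold} ms not representable at "
            f"{config.sample_period} ms sampling"
        )
    if required_hold not in config.hold_levels:
        raise ConfigError(f"required_hold {required_hold} ms is not a staircase level")
    n_hold = required_hold // config.sample_period
    a = segment.angles
    window = a[: n_hold + 1]
    bad = np.nonzero((window < config.goal_low) | (window > config.goal_high))[0]
    if bad.size:
        i_fail = int(bad[0])
        return TrialRecord(
            animal_id=animal_id,
            phase=2,
            t_init=segment.t0,
            outcome=FAILURE,
            reward_volume=0.0,
            required_hold=required_hold,
            t_outcome=segment.t0 + i_fail * config.sample_period / 1000.0,
            trace=segment,
        )
    if a.size >= n_hold + 1:
        return TrialRecord(
            animal_id=animal_id,
            phase=2,
            t_init=segment.t0,
            outcome=SUCCESS,
            reward_volume=config.trial_reward_volume,
            required_hold=required_hold,
            t_outcome=segment.t0 + required_hold / 1000.0,
            trace=segment,
        )
    return None  # truncated before the hold elapsed; discard unscored


def evaluate_block(
    block_successes: int,
    block_size: int,
    required_hold: int,
    config: TaskConfig = DEFAULT_CONFIG,
) -> int:
    """Apply the block-wise up/down staircase rule.

    Step up by ``hold_step`` (to at most ``hold_max``) when the block success
    fraction strictly exceeds ``up_threshold``; step down (to at least
    ``hold_init``) when strictly below ``down_threshold``; otherwise leave the
    duration unchanged. Comparisons are exact (rational arithmetic), so a
    block landing exactly on a threshold does not move the staircase.
    """
    if block_size < 1 or not (0 <= block_successes <= block_size):
        raise ValidationError(
            f"invalid block counts: {block_successes}/{block_size}"
        )
    rate = Fraction(block_successes, block_size)
    if rate > Fraction(str(config.up_threshold)):
        return min(required_hold + config.hold_step, config.hold_max)
    if rate < Fraction(str(config.down_threshold)):
        return max(required_hold - config.hold_step, config.hold_init)
    return required_hold


# ---------------------------------------------------------------------------
# entry rewards and the day boundary
# ---------------------------------------------------------------------------


def day_index(t_s: float, config: TaskConfig = DEFAULT_CONFIG) -> int:
    """Experiment day containing ``t_s``, with days starting at lights-on."""
    return math.floor((t_s - config.lights_on_hour * 3600.0) / 86400.0)


def hour_of_day(t_s: float) -> float:
    """Wall-clock hour of day for a timestamp (experiment starts at midnight)."""
    return (t_s / 3600.0) % 24.0


def process_entry(
    event: SessionEvent,
    daily_entry_reward_count: int,
    config: TaskConfig = DEFAULT_CONFIG,
) -> float:
    """Volume dispensed for a chamber entry given today's reward count so far."""
    if event.kind != "entry":
        raise ValidationError(f"process_entry got a {event.kind!r} event")
    if daily_entry_reward_count < config.entry_reward_daily_cap:
        return config.entry_reward_volume
    return 0.0


class EntryRewardLedger:
    """Tracks per-animal daily entry-reward counts, resetting at lights-on."""

    def __init__(self, config: TaskConfig = DEFAULT_CONFIG):
        self.config = config
        self._counts: dict[tuple[str, int], int] = {}

    def count(self, animal_id: str, t_s: float) -> int:
        return self._counts.get((animal_id, day_index(t_s, self.config)), 0)

    def on_entry(self, event: SessionEvent) -> float:
        """Dispense (or withhold) the entry drop; increments only on dispense."""
        key = (event.animal_id, day_index(event.t, self.config))
        n = self._counts.get(key, 0)
        volume = process_entry(event, n, self.config)
        if volume > 0:
            self._counts[key] = n + 1
        return volume


# ---------------------------------------------------------------------------
# session orchestration
# ---------------------------------------------------------------------------


def _occupancy_intervals(
    events: Sequence[SessionEvent],
) -> list[tuple[float, float, str]]:
    """Per-animal entry/exit pairs -> sorted (t_entry, t_exit, animal) intervals.

    Validates alternation and strict per-animal time ordering. An entry that
    is never closed yields an interval open to +inf.
    """
    last_t: dict[str, float] = {}
    inside: dict[str, float] = {}
    intervals: list[tuple[float, float, str]] = []
    for ev in events:
        if ev.kind not in ("entry", "exit"):
            continue
        if ev.animal_id in last_t and ev.t <= last_t[ev.animal_id]:
            raise ValidationError(
                f"events for {ev.animal_id} not strictly time-ordered at t={ev.t}"
            )
        last_t[ev.animal_id] = ev.t
        if ev.kind == "entry":
            if ev.animal_id in inside:
                raise ValidationError(f"double entry for {ev.animal_id} at t={ev.t}")
            inside[ev.animal_id] = ev.t
        else:
            if ev.animal_id not in inside:
                raise ValidationError(f"exit without entry for {ev.animal_id} at t={ev.t}")
            intervals.append((inside.pop(ev.animal_id), ev.t, ev.animal_id))
    for animal, t_in in inside.items():
        intervals.append((t_in, math.inf, animal))
    intervals.sort(key=lambda iv: iv[0])
    return intervals


def run_session(
    events: Sequence[SessionEvent],
    traces: Iterable[LeverTrace],
    states: Optional[dict[str, StaircaseState]] = None,
    phase: int = 2,
    config: TaskConfig = DEFAULT_CONFIG,
) -> tuple[list[TrialRecord], list[SessionEvent], dict[str, StaircaseState]]:
    """Replay a cage session: attribute trials, classify, reward, staircase.

    Parameters
    ----------
    events
        Time-ordered entry/exit events for all animals in the cage.
    traces
        Lever-angle streams (continuous recordings or stored per-trial
        segments); trials are detected afresh with :func:`detect_trials`.
    states
        Per-animal staircase states, updated in place (phase 2). Missing
        animals start fresh at ``hold_init``.
    phase
        1 or 2; selects the trial classifier.

    Returns ``(trial_records, session_events, states)`` where
    ``session_events`` contains the input entry/exit events plus generated
    ``entry_reward``, ``trial`` and ``staircase_change`` events, time-sorted.
    Deterministic given identical inputs.
    """
    if phase not in (1, 2):
        raise ConfigError(f"phase must be 1 or 2, got {phase}")
    states = states if states is not None else {}
    intervals = _occupancy_intervals(events)

    detections: list[tuple[float, LeverTrace]] = []
    for stream in traces:
        detections.extend(detect_trials(stream, config))
    detections.sort(key=lambda p: p[0])

    ledger = EntryRewardLedger(config)
    out: list[SessionEvent] = []
    for ev in events:
        out.append(ev)
        if ev.kind == "entry":
            volume = ledger.on_entry(ev)
            if volume > 0:
                out.append(
                    SessionEvent(ev.t, ev.animal_id, "entry_reward",
                                 {"volume_ul": volume})
                )

    def occupant(t: float) -> str:
        for t_in, t_out, animal in intervals:
            if t_in <= t < t_out:
                return animal
            if t_in > t:
                break
        raise AttributionError(f"trial at t={t} with no animal in the chamber")

    trials: list[TrialRecord] = []
    per_animal_counter: dict[str, int] = {}
    for t_init, segment in detections:
        animal = occupant(t_init)
        if phase == 1:
            rec = classify_trial_phase1(segment, config, animal)
        else:
            state = states.get(animal)
            if state is None:
                state = states[animal] = StaircaseState.new(animal, config)
            rec = classify_trial_phase2(segment, state.required_hold, config, animal)
            if rec is None:
                continue
        n = per_animal_counter.get(animal, 0) + 1
        per_animal_counter[animal] = n
        rec.trial_id = f"{animal}-p{phase}-{n:05d}"
        trials.append(rec)
        out.append(
            SessionEvent(
                rec.t_init,
                animal,
                "trial",
                {
                    "trial_id": rec.trial_id,
                    "phase": phase,
                    "outcome": rec.outcome,
                    "required_hold_ms": rec.required_hold,
                    "reward_volume_ul": rec.reward_volume,
                },
            )
        )
        if phase == 2:
            state = states[animal]
            before = state.required_hold
            new_hold = state.record(rec.outcome == SUCCESS, config)
            if new_hold is not None and new_hold != before:
                out.append(
                    SessionEvent(
                        rec.t_outcome if rec.t_outcome is not None else rec.t_init,
                        animal,
                        "staircase_change",
                        {"required_hold_ms": new_hold, "previous_ms": before},
                    )
                )

    out.sort(key=lambda e: (e.t, _KIND_ORDER.get(e.kind, 9), e.animal_id))
    return trials, out, states
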