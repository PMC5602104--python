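"""Behavioral summary pipeline.

Acquisition criterion, circadian trial distributions, staircase progression
curves, and daily activity (trial counts, time in chamber). All outputs are
tidy tables or small dataclasses; inferential statistics are deliberately left
to downstream statistics environments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, TaskConfig
from .task_engine import (
    SUCCESS,
    SessionEvent,
    TrialRecord,
    day_index,
    evaluate_block,
)

__all__ = [
    "CircadianHistogram",
    "ProgressionCurve",
    "acquisition_flag",
    "circadian_histogram",
    "dark_hours",
    "progression_curve",
    "daily_activity",
    "reach_max_flag",
]

ACQUIRED = "acquired"
NOT_ACQUIRED = "not_acquired"
REACHED = "reached"
NOT_REACHED = "not_reached"


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------


def acquisition_flag(n_phase1_trials: int, criterion: int = 200) -> str:
    """Acquisition criterion: strictly more than ``criterion`` phase-1 trials."""
    if n_phase1_trials < 0:
        raise ValueError("trial count cannot be negative")
    return ACQUIRED if n_phase1_trials > criterion else NOT_ACQUIRED


# ---------------------------------------------------------------------------
# circadian distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircadianHistogram:
    """Percentage of trials per hour-of-day bin plus the dark-phase total.

    ``bin_percentages[h]`` is the percentage of trials whose timestamp falls in
    wall-clock hour ``[h, h+1)`` (after applying ``bin_origin_hour``). For an
    empty trial set ``bin_percentages`` is ``None`` (sentinel).
    """

    bin_percentages: Optional[np.ndarray]
    dark_phase_percentage: Optional[float]
    n_trials: int
    bin_origin_hour: int = 0


def dark_hours(config: TaskConfig = DEFAULT_CONFIG) -> list[int]:
    """Wall-clock hours belonging to the dark phase (lights-off onward)."""
    off = int(config.lights_off_hour)
    return [(off + k) % 24 for k in range(config.dark_phase_hours)]


def circadian_histogram(
    trial_times_s: Sequence[float],
    config: TaskConfig = DEFAULT_CONFIG,
    bin_origin_hour: int = 0,
) -> CircadianHistogram:
    """Bin trial timestamps into 24 one-hour bins of the wall clock.

    ``bin_origin_hour`` rotates the bin labels so that bin 0 starts at that
    hour (e.g. pass ``config.lights_on_hour`` for photoperiod-aligned bins);
    the default keeps bins aligned to clock midnight. The dark-phase
    percentage is the sum over the 12 h starting at lights-off regardless of
    bin origin.
    """
    t = np.asarray(list(trial_times_s), dtype=float)
    n = t.size
    if n == 0:
        return CircadianHistogram(None, None, 0, bin_origin_hour)
    hours = (t / 3600.0) % 24.0
    shifted = (hours - bin_origin_hour) % 24.0
    counts, _ = np.histogram(shifted, bins=np.arange(25))
    pct = 100.0 * counts / n
    dark = {(h - bin_origin_hour) % 24 for h in dark_hours(config)}
    dark_pct = float(sum(pct[h] for h in dark))
    return CircadianHistogram(pct, dark_pct, n, bin_origin_hour)


# ---------------------------------------------------------------------------
# staircase progression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProgressionCurve:
    """Required hold at the end of each 25-trial bin plus per-bin success rate."""

    required_hold_ms: tuple[int, ...]
    success_pct: tuple[float, ...]
    bin_end_times_s: Optional[tuple[float, ...]] = None
    t_start_s: Optional[float] = None

    def __len__(self) -> int:
        return len(self.required_hold_ms)


def progression_curve(
    outcomes: Sequence[bool] | Sequence[TrialRecord],
    config: TaskConfig = DEFAULT_CONFIG,
    times_s: Optional[Sequence[float]] = None,
    max_trials: Optional[int] = None,
) -> ProgressionCurve:
    """Replay the staircase over consecutive blocks of one animal's outcomes.

    ``outcomes`` may be booleans or :class:`TrialRecord` objects (their
    outcome and initiation time are used). Only complete blocks are reported;
    ``max_trials`` truncates the sequence first (e.g. 500 for a
    first-500-trials analysis).
    """
    if outcomes and isinstance(outcomes[0], TrialRecord):
        recs = list(outcomes)
        if times_s is None:
            times_s = [r.t_init for r in recs]
        outcomes = [r.outcome == SUCCESS for r in recs]
    flags = [bool(o) for o in outcomes]
    times = list(times_s) if times_s is not None else None
    if max_trials is not None:
        flags = flags[:max_trials]
        if times is not None:
            times = times[:max_trials]
    bs = config.block_size
    hold = config.hold_init
    holds: list[int] = []
    pcts: list[float] = []
    ends: list[float] = []
    for start in range(0, len(flags) - bs + 1, bs):
        block = flags[start : start + bs]
        successes = sum(block)
        hold = evaluate_block(successes, bs, hold, config)
        holds.append(hold)
        pcts.append(100.0 * successes / bs)
        if times is not None:
            ends.append(times[start + bs - 1])
    return ProgressionCurve(
        required_hold_ms=tuple(holds),
        success_pct=tuple(pcts),
        bin_end_times_s=tuple(ends) if times is not None else None,
        t_start_s=(times[0] if times else None),
    )


def reach_max_flag(
    progression: ProgressionCurve,
    horizon_days: float = 7,
    config: TaskConfig = DEFAULT_CONFIG,
) -> str:
    """Whether the staircase reached ``hold_max`` within the testing horizon.

    If the curve carries bin timestamps, only bins ending within
    ``horizon_days`` of the first trial count; otherwise attainment anywhere
    on the curve counts.
    """
    for i, hold in enumerate(progression.required_hold_ms):
        if hold != config.hold_max:
            continue
        if progression.bin_end_times_s is not None and progression.t_start_s is not None:
            if progression.bin_end_times_s[i] - progression.t_start_s > horizon_days * 86400.0:
                continue
        return REACHED
    return NOT_REACHED


# ---------------------------------------------------------------------------
# daily activity
# ---------------------------------------------------------------------------


def daily_activity(
    events: Sequence[SessionEvent],
    trials: Sequence[TrialRecord],
    config: TaskConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per animal per day: trial count, time in chamber, log trial count.

    Days start at lights-on. Visits spanning a day boundary contribute time to
    each day they overlap. The natural-log column is NaN for zero-count days.
    An entry left open at stream end is closed at the last event timestamp
    (with a warning).
    """
    last_t = max((ev.t for ev in events), default=0.0)
    visits: list[tuple[float, float, str]] = []
    open_entry: dict[str, float] = {}
    for ev in sorted(events, key=lambda e: e.t):
        if ev.kind == "entry":
            open_entry[ev.animal_id] = ev.t
        elif ev.kind == "exit" and ev.animal_id in open_entry:
            visits.append((open_entry.pop(ev.animal_id), ev.t, ev.animal_id))
    for animal, t_in in open_entry.items():
        warnings.warn(
            f"unmatched entry for {animal}; closing visit at stream end",
            stacklevel=2,
        )
        visits.append((t_in, last_t, animal))

    animals = sorted({ev.animal_id for ev in events} | {r.animal_id for r in trials})
    day_lo = min(
        [day_index(v[0], config) for v in visits]
        + [day_index(r.t_init, config) for r in trials],
        default=0,
    )
    day_hi = max(
        [day_index(v[1], config) for v in visits]
        + [day_index(r.t_init, config) for r in trials],
        default=0,
    )

    time_in: dict[tuple[str, int], float] = {}
    for t_in, t_out, animal in visits:
        d = day_index(t_in, config)
        while True:
            day_end = (d + 1) * 86400.0 + config.lights_on_hour * 3600.0
            seg_end = min(t_out, day_end)
            time_in[(animal, d)] = time_in.get((animal, d), 0.0) + (seg_end - t_in)
            if t_out <= day_end:
                break
            t_in, d = day_end, d + 1

    counts: dict[tuple[str, int], int] = {}
    for rec in trials:
        key = (rec.animal_id, day_index(rec.t_init, config))
        counts[key] = counts.get(key, 0) + 1

    rows = []
    for animal in animals:
        for d in range(day_lo, day_hi + 1):
            n = counts.get((animal, d), 0)
            rows.append(
                {
                    "animal_id": animal,
                    "day": d,
                    "trial_count": n,
                    "time_in_chamber_s": time_in.get((animal, d), 0.0),
                    "log_trial_count": math.log(n) if n > 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["animal_id", "day", "trial_count",
                                       "time_in_chamber_s", "log_trial_count"])
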