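"""Per-trial kinematic features of lever traces and per-animal aggregation.

Three features describe how an animal performs a hold trial:

``max_displacement``
    Largest lever angle reached during the trial, degrees. Animals that
    overshoot the goal range show larger values.
``hold_slope``
    Ordinary least-squares slope of angle versus time over a window 200-800 ms
    after trial initiation, degrees/s. A steady hold gives ~0; a progressive
    release of the lever (motor impersistence-like behaviour) gives a negative
    slope.
``mean_speed``
    Mean absolute instantaneous velocity |Δangle|/Δt over consecutive samples,
    degrees/s, computed over the full trial segment by default (optionally
    restricted to the hold window).

Per-animal summaries average features over successful trials at the maximum
required hold duration; animals with fewer than 200 such eligible trials are
flagged as excluded rather than summarised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, TaskConfig
from .errors import InsufficientTraceError, MalformedTraceError
from .task_engine import SUCCESS, LeverTrace, TrialRecord

__all__ = [
    "KinematicFeatures",
    "AnimalKinematicSummary",
    "max_displacement",
    "hold_slope",
    "mean_speed",
    "extract_features",
    "aggregate_animal",
    "summarize_animals",
]

#: analysis window for the hold slope, ms after trial initiation
SLOPE_WINDOW_MS = (200, 800)


@dataclass(frozen=True)
class KinematicFeatures:
    max_displacement: float
    hold_slope: float
    mean_speed: float


@dataclass(frozen=True)
class AnimalKinematicSummary:
    animal_id: str
    n_eligible_trials: int
    excluded: bool
    mean_max_displacement: Optional[float] = None
    sd_max_displacement: Optional[float] = None
    mean_hold_slope: Optional[float] = None
    sd_hold_slope: Optional[float] = None
    mean_speed: Optional[float] = None
    sd_speed: Optional[float] = None


def max_displacement(trace: LeverTrace) -> float:
    """Maximum sampled lever angle over the trial segment, degrees."""
    if len(trace) == 0:
        raise MalformedTraceError("empty trace")
    return float(trace.angles.max())


def hold_slope(
    trace: LeverTrace,
    window_start: int = SLOPE_WINDOW_MS[0],
    window_end: int = SLOPE_WINDOW_MS[1],
) -> float:
    """OLS slope of angle vs. time over [window_start, window_end] ms.

    Window endpoints are inclusive on the sample lattice and measured from the
    first sample of the segment (trial initiation). Raises
    :class:`InsufficientTraceError` if the trace does not cover the window.
    """
    sp = trace.sample_period
    i0 = int(np.ceil(window_start / sp))
    i1 = int(np.floor(window_end / sp))
    if i1 >= len(trace) or i0 > i1:
        raise InsufficientTraceError(
            f"trace of {trace.duration_ms:.0f} ms does not cover the "
            f"[{window_start}, {window_end}] ms window"
        )
    y = trace.angles[i0 : i1 + 1]
    t = np.arange(i0, i1 + 1) * (sp / 1000.0)
    t_centered = t - t.mean()
    denom = float(np.dot(t_centered, t_centered))
    if denom == 0.0:
        raise InsufficientTraceError("slope window contains a single sample")
    return float(np.dot(t_centered, y - y.mean()) / denom)


def mean_speed(trace: LeverTrace, window_ms: Optional[tuple[int, int]] = None) -> float:
    """Mean |Δangle|/Δt over consecutive sample pairs, degrees/s.

    By default the whole trial segment is used; pass ``window_ms`` to restrict
    to a time window (inclusive endpoints, ms from initiation).
    """
    a = trace.angles
    if window_ms is not None:
        sp = trace.sample_period
        i0 = int(np.ceil(window_ms[0] / sp))
        i1 = int(np.floor(window_ms[1] / sp))
        if i1 >= len(trace) or i1 - i0 < 1:
            raise InsufficientTraceError("speed window not covered by trace")
        a = a[i0 : i1 + 1]
    if a.size < 2:
        raise MalformedTraceError("mean_speed needs at least 2 samples")
    dt_s = trace.sample_period / 1000.0
    return float(np.mean(np.abs(np.diff(a))) / dt_s)


def extract_features(
    trace: LeverTrace,
    slope_window: tuple[int, int] = SLOPE_WINDOW_MS,
    speed_window: Optional[tuple[int, int]] = None,
) -> KinematicFeatures:
    """All three kinematic features for one trial segment."""
    return KinematicFeatures(
        max_displacement=max_displacement(trace),
        hold_slope=hold_slope(trace, *slope_window),
        mean_speed=mean_speed(trace, speed_window),
    )


def aggregate_animal(
    trials: Sequence[TrialRecord],
    config: TaskConfig = DEFAULT_CONFIG,
    min_eligible: int = 200,
    slope_window: tuple[int, int] = SLOPE_WINDOW_MS,
    speed_window: Optional[tuple[int, int]] = None,
    animal_id: Optional[str] = None,
) -> AnimalKinematicSummary:
    """Average kinematic features over one animal's eligible trials.

    Eligible trials are successful phase-2 trials at the maximum required hold
    duration (``config.hold_max``) that carry a trace covering the slope
    window. Per-trial features are computed first and then averaged without
    weighting. If fewer than ``min_eligible`` trials qualify, the animal is
    flagged excluded and no means are reported.
    """
    if animal_id is None:
        animal_id = trials[0].animal_id if trials else ""
    feats: list[KinematicFeatures] = []
    for rec in trials:
        if rec.outcome != SUCCESS or rec.required_hold != config.hold_max:
            continue
        if rec.trace is None:
            continue
        feats.append(extract_features(rec.trace, slope_window, speed_window))
    n = len(feats)
    if n < min_eligible:
        return AnimalKinematicSummary(animal_id=animal_id, n_eligible_trials=n,
                                      excluded=True)
    md = np.array([f.max_displacement for f in feats])
    sl = np.array([f.hold_slope for f in feats])
    sp = np.array([f.mean_speed for f in feats])
    return AnimalKinematicSummary(
        animal_id=animal_id,
        n_eligible_trials=n,
        excluded=False,
        mean_max_displacement=float(md.mean()),
        sd_max_displacement=float(md.std(ddof=1)),
        mean_hold_slope=float(sl.mean()),
        sd_hold_slope=float(sl.std(ddof=1)),
        mean_speed=float(sp.mean()),
        sd_speed=float(sp.std(ddof=1)),
    )


def summarize_animals(
    trials: Sequence[TrialRecord],
    config: TaskConfig = DEFAULT_CONFIG,
    min_eligible: int = 200,
    **kwargs,
) -> pd.DataFrame:
    """Per-animal kinematic summary table (one row per animal)."""
    by_animal: dict[str, list[TrialRecord]] = {}
    for rec in trials:
        by_animal.setdefault(rec.animal_id, []).append(rec)
    rows = [
        aggregate_animal(recs, config, min_eligible, animal_id=animal, **kwargs).__dict__
        for animal, recs in sorted(by_animal.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id", "n_eligible_trials", "excluded",
            "mean_max_displacement", "sd_max_displacement",
            "mean_hold_slope", "sd_hold_slope",
            "mean_speed", "sd_speed",
        ],
    )
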