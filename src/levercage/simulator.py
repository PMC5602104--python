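"""Virtual mice for desk-scale testing of the lever-cage pipeline.

The simulator generates everything the hardware would record — chamber
entry/exit events, per-trial lever traces, and (via the *real* task-engine
classifier, never by fiat) trial outcomes — from parameterised behavioural
agents. The generative model is deliberately simple:

* **Visits**: per-day visit counts are Poisson; visit start hours are drawn
  from a 24-bin categorical distribution (``circadian_weights``), emulating
  the dark-phase-dominant activity of mice under a 12/12 light/dark cycle.
* **Success/competence**: an agent can reliably hold for ``skill_ms``; the
  probability of *attempting* a long enough hold at required duration ``d``
  is logistic, ``p = 1/(1 + exp((d - skill_ms)/tau_ms))``, and ``skill_ms``
  grows linearly by ``learning_rate`` per trial up to ``skill_max``.
* **Trace morphology**: a linear rise to a Gaussian peak, a hold segment at a
  Gaussian level with Gaussian sample noise and a linear drift (release
  slope), then a linear return to rest. The WT-like preset holds steady just
  past the centre of the goal range; the HD-like preset pulls near (and
  sometimes through) the top of the goal range and progressively releases,
  mimicking an overshoot-and-release, motor-impersistence-like phenotype.

Reproducibility: one master seed; every animal gets an independent substream
derived from the seed and a stable hash of its id, so adding an animal never
perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, TaskConfig
from .errors import ConfigError
from .task_engine import (
    SUCCESS,
    EntryRewardLedger,
    LeverTrace,
    SessionEvent,
    StaircaseState,
    TrialRecord,
    classify_trial_phase1,
    classify_trial_phase2,
    detect_trials,
)

__all__ = [
    "AgentProfile",
    "SimOutput",
    "PRESETS",
    "make_profile",
    "success_probability",
    "step_skill",
    "generate_trace",
    "sample_visit_schedule",
    "simulate_cage",
]


# ---------------------------------------------------------------------------
# profiles and presets
# ---------------------------------------------------------------------------


def _default_weights() -> np.ndarray:
    return np.ones(24)


@dataclass
class AgentProfile:
    """Ground-truth parameters of one virtual mouse."""

    animal_id: str
    preset: str = "custom"
    #: relative entry intensity per wall-clock hour (24 nonnegative values)
    circadian_weights: np.ndarray = field(default_factory=_default_weights)
    visits_per_day: float = 20.0
    trials_per_visit: float = 18.0
    #: trials per visit after day 0 (defaults to trials_per_visit if None)
    trials_per_visit_late: Optional[float] = None
    #: hold duration the agent can reliably sustain, ms
    skill_ms: float = 300.0
    #: skill gain per trial, ms
    learning_rate: float = 2.0
    skill_max: float = 1500.0
    #: logistic width of the success-probability curve, ms
    tau_ms: float = 50.0
    pull_peak_mean: float = 14.5
    pull_peak_sd: float = 1.0
    hold_level_mean: float = 13.0
    hold_level_sd: float = 0.8
    hold_noise_sd: float = 0.3
    release_slope_mean: float = -0.5
    release_slope_sd: float = 0.4
    #: lever angular speed during rise/release ramps, degrees/s
    rise_speed: float = 80.0

    def __post_init__(self) -> None:
        w = np.asarray(self.circadian_weights, dtype=float)
        if w.shape != (24,) or np.any(w < 0) or not np.any(w > 0):
            raise ConfigError("circadian_weights must be 24 nonnegative values, not all zero")
        self.circadian_weights = w
        for name in ("visits_per_day", "trials_per_visit", "skill_ms",
                     "pull_peak_sd", "hold_level_sd", "hold_noise_sd",
                     "release_slope_sd", "tau_ms", "rise_speed"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


def _dark_heavy_weights() -> np.ndarray:
    """WT-like activity: strongest in the first 6 h of the dark phase."""
    w = np.full(24, 0.3)
    for h in range(19, 25):  # lights off at 19:00 under the default config
        w[h % 24] = 3.0
    for h in range(1, 7):  # late dark phase, moderate
        w[h] = 1.2
    return w


def _light_shifted_weights() -> np.ndarray:
    """HD-like activity: ramps up before lights-off, drops early in the dark."""
    w = np.full(24, 0.5)
    for h in range(16, 19):  # last 3 h of the light phase elevated
        w[h] = 2.0
    for h in range(19, 21):  # first 2 dark hours high, then the drop
        w[h] = 2.5
    for h in range(21, 25):
        w[h % 24] = 0.8
    return w


PRESETS: dict[str, dict] = {
    # steady holder: displaces just past the centre of the goal range
    "WT-like": dict(
        circadian_weights=_dark_heavy_weights(),
        pull_peak_mean=14.5, pull_peak_sd=1.0,
        hold_level_mean=13.0, hold_level_sd=0.8,
        hold_noise_sd=0.3,
        release_slope_mean=-0.5, release_slope_sd=0.4,
        skill_ms=300.0, learning_rate=2.0,
    ),
    # overshoot-and-release: pulls near the top of the goal range, sometimes
    # through it, then progressively lets the lever return
    "HD-like": dict(
        circadian_weights=_light_shifted_weights(),
        pull_peak_mean=18.5, pull_peak_sd=1.2,
        hold_level_mean=17.5, hold_level_sd=0.8,
        hold_noise_sd=0.4,
        release_slope_mean=-5.0, release_slope_sd=1.2,
        skill_ms=300.0, learning_rate=1.5,
    ),
    # noiseless deterministic holder that succeeds on every trial
    "perfect": dict(
        circadian_weights=_dark_heavy_weights(),
        pull_peak_mean=14.0, pull_peak_sd=0.0,
        hold_level_mean=12.0, hold_level_sd=0.0,
        hold_noise_sd=0.0,
        release_slope_mean=0.0, release_slope_sd=0.0,
        skill_ms=10000.0, learning_rate=0.0,
    ),
    # success rate pinned inside the (10%, 75%] dead zone: staircase stalls
    "deadzone": dict(
        circadian_weights=_dark_heavy_weights(),
        pull_peak_mean=14.0, pull_peak_sd=0.5,
        hold_level_mean=12.5, hold_level_sd=0.5,
        hold_noise_sd=0.2,
        release_slope_mean=-0.3, release_slope_sd=0.2,
        skill_ms=80.0, learning_rate=0.0,
    ),
    # explores on day 0 then stops: fails the >200-trial acquisition criterion
    "nonacquirer": dict(
        circadian_weights=_dark_heavy_weights(),
        visits_per_day=6.0, trials_per_visit=10.0, trials_per_visit_late=0.1,
        pull_peak_mean=14.0, pull_peak_sd=1.0,
        hold_level_mean=12.5, hold_level_sd=0.8,
        hold_noise_sd=0.3,
        release_slope_mean=-0.5, release_slope_sd=0.4,
        skill_ms=200.0, learning_rate=0.0,
    ),
}


def make_profile(preset: str, animal_id: str, **overrides) -> AgentProfile:
    """Instantiate a named preset profile (optionally overriding fields)."""
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[preset])
    params["circadian_weights"] = params["circadian_weights"].copy()
    params.update(overrides)
    return AgentProfile(animal_id=animal_id, preset=preset, **params)


@dataclass
class SimOutput:
    """Everything a simulated cage run produced, plus the ground truth."""

    events: list[SessionEvent]
    trials: list[TrialRecord]
    profiles: list[AgentProfile]
    config: TaskConfig
    seed: int


# ---------------------------------------------------------------------------
# competence model
# ---------------------------------------------------------------------------


def success_probability(skill_ms: float, required_hold: float, tau_ms: float = 50.0) -> float:
    """Logistic probability that the agent attempts a sufficient hold."""
    return float(1.0 / (1.0 + np.exp((required_hold - skill_ms) / tau_ms)))


def step_skill(skill_ms: float, profile: AgentProfile) -> float:
    """Linear per-trial skill increment, saturating at ``skill_max``."""
    return min(profile.skill_max, skill_ms + profile.learning_rate)


# ---------------------------------------------------------------------------
# trace generation
# ---------------------------------------------------------------------------


def generate_trace(
    profile: AgentProfile,
    required_hold: int,
    attempt_hold_ms: float,
    rng: np.random.Generator,
    config: TaskConfig = DEFAULT_CONFIG,
    t0: float = 0.0,
) -> LeverTrace:
    """One synthetic pull-and-hold lever trace.

    The trace rises linearly at ``rise_speed`` from rest to a Gaussian peak,
    holds at a Gaussian level with sample noise and a linear drift for
    ``attempt_hold_ms`` (the agent's intended hold horizon — shorter than
    ``required_hold`` for an intended failure), then returns linearly to rest.
    All samples are clipped to the lever's physical range. The actual outcome
    is whatever the task-engine classifier says about the trace.
    """
    sp = config.sample_period
    dt_s = sp / 1000.0
    peak = float(np.clip(rng.normal(profile.pull_peak_mean, profile.pull_peak_sd),
                         config.pull_threshold, config.lever_range_max))
    level = float(np.clip(rng.normal(profile.hold_level_mean, profile.hold_level_sd),
                          0.0, config.lever_range_max))
    slope = float(rng.normal(profile.release_slope_mean, profile.release_slope_sd))

    step = max(profile.rise_speed, 1e-6) * dt_s
    n_rise = int(np.ceil(peak / step))
    rise = np.minimum(np.arange(1, n_rise + 1) * step, peak)

    n_hold = max(1, int(round(attempt_hold_ms / sp)))
    hold = level + slope * np.arange(n_hold) * dt_s
    if profile.hold_noise_sd > 0:
        hold = hold + rng.normal(0.0, profile.hold_noise_sd, n_hold)

    last = hold[-1] if n_hold else peak
    n_rel = max(1, int(np.ceil(max(last, 0.0) / step)))
    release = np.maximum(last - np.arange(1, n_rel + 1) * step, 0.0)

    angles = np.concatenate([[0.0], rise, hold, release, [0.0, 0.0]])
    np.clip(angles, 0.0, config.lever_range_max, out=angles)
    return LeverTrace(t0=t0, angles=angles, sample_period=sp)


# ---------------------------------------------------------------------------
# visit scheduling
# ---------------------------------------------------------------------------


def _animal_rng(seed: int, animal_id: str) -> np.random.Generator:
    """Independent substream per animal: stable under cage-mate changes."""
    tag = zlib.crc32(animal_id.encode())
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def sample_visit_schedule(
    profile: AgentProfile,
    n_days: int,
    rng: np.random.Generator,
    mean_visit_s: float = 150.0,
) -> list[tuple[float, float]]:
    """Draw non-overlapping (entry, exit) times over ``n_days`` for one animal.

    Daily visit counts are Poisson(``visits_per_day``); start hours follow
    ``circadian_weights``; durations are clipped Gaussians around
    ``mean_visit_s``. Overlapping draws are pushed forward so visits never
    overlap within the animal.
    """
    p = profile.circadian_weights / profile.circadian_weights.sum()
    starts: list[float] = []
    durations: list[float] = []
    for day in range(n_days):
        n = rng.poisson(profile.visits_per_day)
        hours = rng.choice(24, size=n, p=p)
        frac = rng.uniform(0.0, 1.0, size=n)
        for h, f in zip(hours, frac):
            starts.append((day * 24.0 + h + f * 0.95) * 3600.0)
            durations.append(float(np.clip(rng.normal(mean_visit_s, mean_visit_s / 3),
                                           30.0, 4 * mean_visit_s)))
    order = np.argsort(starts, kind="stable")
    visits: list[tuple[float, float]] = []
    t_free = -np.inf
    for k in order:
        t_in = max(starts[k], t_free + 1.0)
        t_out = t_in + durations[k]
        visits.append((t_in, t_out))
        t_free = t_out
    return visits


# ---------------------------------------------------------------------------
# full cage simulation
# ---------------------------------------------------------------------------


def simulate_cage(
    profiles: Sequence[AgentProfile],
    phase_schedule: Sequence[tuple[int, int]] = ((1, 3), (2, 7)),
    config: TaskConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> SimOutput:
    """Simulate a multi-animal cage through the full testing protocol.

    ``phase_schedule`` is a sequence of ``(phase, n_days)`` segments, by
    default 3 days of phase-1 acquisition followed by 7 days of the phase-2
    hold task (the published protocol). One animal occupies the chamber at a
    time: overlapping visits across animals are resolved by queueing. Every
    trial's outcome is produced by the real task-engine classifier run on the
    generated trace, so engine and simulator can never disagree. Byte-for-byte
    reproducible given (profiles, config, seed).
    """
    if not profiles:
        raise ConfigError("need at least one profile")
    ids = [p.animal_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ConfigError("animal ids must be unique")

    total_days = sum(d for _, d in phase_schedule)
    phase_at: list[tuple[float, int]] = []  # (segment start time s, phase)
    t_acc = 0.0
    for phase, days in phase_schedule:
        if phase not in (1, 2):
            raise ConfigError("phases must be 1 or 2")
        phase_at.append((t_acc, phase))
        t_acc += days * 86400.0

    def phase_of(t: float) -> int:
        current = phase_at[0][1]
        for t_seg, ph in phase_at:
            if t >= t_seg:
                current = ph
        return current

    rngs = {p.animal_id: _animal_rng(seed, p.animal_id) for p in profiles}
    skills = {p.animal_id: p.skill_ms for p in profiles}
    states: dict[str, StaircaseState] = {}

    # ---- visits, queued so at most one animal is inside at a time --------
    raw: list[tuple[float, float, AgentProfile]] = []
    for p in profiles:
        for t_in, t_out in sample_visit_schedule(p, total_days, rngs[p.animal_id]):
            raw.append((t_in, t_out, p))
    raw.sort(key=lambda v: (v[0], v[2].animal_id))
    busy_until = -np.inf
    visits: list[tuple[float, float, AgentProfile]] = []
    for t_in, t_out, p in raw:
        dur = t_out - t_in
        t_in = max(t_in, busy_until + 1.0)
        t_out = t_in + dur
        visits.append((t_in, t_out, p))
        busy_until = t_out
    visits.sort(key=lambda v: v[0])

    ledger = EntryRewardLedger(config)
    events: list[SessionEvent] = []
    trials: list[TrialRecord] = []
    per_animal_counter: dict[str, int] = {}

    for t_in, t_out, p in visits:
        aid = p.animal_id
        rng = rngs[aid]
        entry = SessionEvent(t_in, aid, "entry")
        events.append(entry)
        volume = ledger.on_entry(entry)
        if volume > 0:
            events.append(SessionEvent(t_in, aid, "entry_reward", {"volume_ul": volume}))

        day = int(t_in // 86400.0)
        tpv = p.trials_per_visit if (day < 1 or p.trials_per_visit_late is None) \
            else p.trials_per_visit_late
        n_trials = int(rng.poisson(tpv))
        t_cursor = t_in + 2.0
        t_last_end = t_cursor
        for _ in range(n_trials):
            if t_cursor >= t_out - 8.0:
                break  # visit over; remaining trials are dropped
            phase = phase_of(t_cursor)
            if phase == 2:
                state = states.get(aid)
                if state is None:
                    state = states[aid] = StaircaseState.new(aid, config)
                required = state.required_hold
            else:
                required = config.hold_init
            p_succ = success_probability(skills[aid], required, p.tau_ms)
            intends_success = bool(rng.random() < p_succ)
            if intends_success:
                attempt = required + rng.uniform(100.0, 400.0)
                trace = generate_trace(p, required, attempt, rng, config,
                                       t0=t_cursor)
            else:
                # a non-adapted, phase-1-style vigorous pull straight through
                # the top of the goal range: fails the hold trial on the way up
                attempt = max(float(config.sample_period),
                              rng.uniform(0.2, 0.8) * required)
                vigorous = replace(
                    p,
                    circadian_weights=p.circadian_weights.copy(),
                    pull_peak_mean=21.5, pull_peak_sd=0.8,
                    hold_level_mean=20.5, hold_level_sd=0.5,
                )
                trace = generate_trace(vigorous, required, attempt, rng,
                                       config, t0=t_cursor)
            detected = detect_trials(trace, config)
            for t_init, segment in detected:
                if phase == 1:
                    rec = classify_trial_phase1(segment, config, aid)
                else:
                    rec = classify_trial_phase2(segment, required, config, aid)
                    if rec is None:
                        continue
                n = per_animal_counter.get(aid, 0) + 1
                per_animal_counter[aid] = n
                rec.trial_id = f"{aid}-{n:06d}"
                trials.append(rec)
                events.append(
                    SessionEvent(
                        rec.t_init, aid, "trial",
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
                    state = states[aid]
                    before = state.required_hold
                    new_hold = state.record(rec.outcome == SUCCESS, config)
                    if new_hold is not None and new_hold != before:
                        events.append(
                            SessionEvent(
                                rec.t_outcome, aid, "staircase_change",
                                {"required_hold_ms": new_hold, "previous_ms": before},
                            )
                        )
            skills[aid] = step_skill(skills[aid], p)
            t_last_end = t_cursor + trace.duration_ms / 1000.0 + 0.5
            t_cursor = t_last_end + 0.5 + rng.exponential(2.0)
        exit_t = max(t_out, t_last_end)
        events.append(SessionEvent(exit_t, aid, "exit"))

    events.sort(key=lambda e: (e.t, {"entry": 0, "entry_reward": 1, "trial": 2,
                                     "staircase_change": 3, "exit": 4}[e.kind],
                               e.animal_id))
    return SimOutput(events=events, trials=trials, profiles=list(profiles),
                     config=config, seed=seed)
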