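"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np

from levercage import DEFAULT_CONFIG, LeverTrace, evaluate_block
from levercage.kinematics import aggregate_animal
from levercage.simulator import generate_trace, make_profile
from levercage.task_engine import classify_trial_phase2, detect_trials


def trace(angles, t0: float = 0.0, sp: int = 10) -> LeverTrace:
    return LeverTrace(t0=t0, angles=np.asarray(angles, float), sample_period=sp)


def pull_hold_release(
    peak: float,
    level: float,
    hold_ms: float,
    rise_speed: float = 80.0,
    sp: int = 10,
    t0: float = 0.0,
) -> LeverTrace:
    """Deterministic pull trace: rest -> ramp to peak -> hold level -> rest."""
    step = rise_speed * sp / 1000.0
    rise = np.minimum(np.arange(1, int(np.ceil(peak / step)) + 1) * step, peak)
    hold = np.full(int(round(hold_ms / sp)), level, dtype=float)
    release = np.maximum(level - np.arange(1, int(np.ceil(level / step)) + 2) * step, 0.0)
    return trace(np.concatenate([[0.0], rise, hold, release, [0.0, 0.0]]), t0, sp)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_phase2(segment: LeverTrace, required_hold: int, config=DEFAULT_CONFIG):
    """Sample-by-sample scan of the hold window (independent of the engine).

    Returns ("success", reward sample index), ("failure", fail sample index),
    or (None, None) for a segment truncated before the hold elapsed.
    """
    n_hold = required_hold // config.sample_period
    for i, angle in enumerate(segment.angles):
        if i > n_hold:
            break
        if angle < config.goal_low or angle > config.goal_high:
            return "failure", i
    if len(segment.angles) >= n_hold + 1:
        return "success", n_hold
    return None, None


def staircase_from_counts(counts, config=DEFAULT_CONFIG):
    """Replay the staircase over per-block success counts."""
    hold = config.hold_init
    out = []
    for c in counts:
        hold = evaluate_block(c, config.block_size, hold, config)
        out.append(hold)
    return out


def random_segment(rng: np.random.Generator, config=DEFAULT_CONFIG) -> LeverTrace:
    """Random walk segment starting at/above the initiation threshold."""
    n = int(rng.integers(30, 120))
    start = rng.uniform(config.pull_threshold, config.lever_range_max)
    steps = rng.normal(0.0, 1.5, n - 1)
    angles = np.clip(start + np.cumsum(np.concatenate([[0.0], steps])),
                     0.0, config.lever_range_max)
    angles[0] = start
    return trace(angles)


# ---------------------------------------------------------------------------
# phenotype-contrast replicate (WT-like vs HD-like sign recovery)
# ---------------------------------------------------------------------------


def _agent_feature_means(preset: str, rng, n_trials: int, config=DEFAULT_CONFIG):
    profile = make_profile(preset, "agent")
    recs = []
    for _ in range(n_trials):
        tr = generate_trace(profile, config.hold_max,
                            config.hold_max + rng.uniform(100.0, 400.0),
                            rng, config)
        t_init, segment = detect_trials(tr, config)[0]
        rec = classify_trial_phase2(segment, config.hold_max, config, "agent")
        if rec is not None:
            recs.append(rec)
    summary = aggregate_animal(recs, config, min_eligible=50)
    return summary.mean_max_displacement, summary.mean_hold_slope


def phenotype_replicate(seed: int, n_agents: int = 20, n_trials: int = 250,
                        config=DEFAULT_CONFIG):
    """Group means of (max displacement, hold slope) for WT-like and HD-like.

    Returns (wt_md, wt_slope, hd_md, hd_slope) — means over agent means of
    successful trials at the maximum hold duration.
    """
    groups = {}
    for g, preset in enumerate(("WT-like", "HD-like")):
        md, sl = [], []
        for i in range(n_agents):
            rng = np.random.default_rng([seed, g, i])
            m, s = _agent_feature_means(preset, rng, n_trials, config)
            md.append(m)
            sl.append(s)
        groups[preset] = (float(np.mean(md)), float(np.mean(sl)))
    wt, hd = groups["WT-like"], groups["HD-like"]
    return wt[0], wt[1], hd[0], hd[1]
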