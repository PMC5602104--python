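"""Task configuration.

All geometric and timing constants of the lever-positioning task live here.
Angles are degrees of lever rotation away from the counterweighted rest
position; durations are milliseconds; timestamps elsewhere in the package are
seconds since experiment start (midnight of day 0).

The defaults encode the published task: a lever restricted to a 24° range,
trial initiation when the lever is pulled to the center of that range (12°),
a phase-2 goal range of 4.5°-19.5° within which the lever must be held, and
a block-wise staircase on the required hold duration (100 ms initial, 800 ms
ceiling, 100 ms steps, evaluated every 25 trials against >75% / <10% success
thresholds). Entry into the chamber dispenses a 5 µl drop (at most 200/day);
a rewarded trial dispenses 10 µl.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["TaskConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class TaskConfig:
    #: full angular travel of the lever between its two stop posts, degrees
    lever_range_max: float = 24.0
    #: angle that initiates a trial when crossed while the controller is armed
    pull_threshold: float = 12.0
    #: lower edge of the phase-2 goal range, degrees (inclusive)
    goal_low: float = 4.5
    #: upper edge of the phase-2 goal range, degrees (inclusive)
    goal_high: float = 19.5
    #: initial required hold duration, ms
    hold_init: int = 100
    #: ceiling of the required hold duration, ms
    hold_max: int = 800
    #: staircase step, ms
    hold_step: int = 100
    #: number of trials per staircase-evaluation block
    block_size: int = 25
    #: block success fraction that must be exceeded (strictly) to step up
    up_threshold: float = 0.75
    #: block success fraction below which (strictly) the staircase steps down
    down_threshold: float = 0.10
    #: volume of the drop dispensed on chamber entry, µl
    entry_reward_volume: float = 5.0
    #: maximum number of entry drops per animal per day
    entry_reward_daily_cap: int = 200
    #: volume of the drop dispensed for a successful trial, µl
    trial_reward_volume: float = 10.0
    #: angle below which the controller re-arms after a trial, degrees
    rearm_threshold: float = 1.0
    #: lever-position sampling period, ms (100 Hz default)
    sample_period: int = 10
    #: wall-clock hour at which lights turn on; also the "day" boundary
    lights_on_hour: int = 7
    #: length of the dark phase, hours
    dark_phase_hours: int = 12

    def __post_init__(self) -> None:
        c = self
        if not (0 < c.pull_threshold < c.lever_range_max):
            raise ConfigError("pull_threshold must lie strictly inside the lever range")
        if not (c.goal_low < c.pull_threshold < c.goal_high <= c.lever_range_max):
            raise ConfigError("goal range must bracket pull_threshold and fit the lever range")
        if c.hold_init > c.hold_max:
            raise ConfigError("hold_init must not exceed hold_max")
        if c.hold_step <= 0 or (c.hold_max - c.hold_init) % c.hold_step != 0:
            raise ConfigError("hold_step must be positive and divide hold_max - hold_init")
        if not (0 <= c.down_threshold < c.up_threshold <= 1):
            raise ConfigError("need 0 <= down_threshold < up_threshold <= 1")
        if c.block_size < 1:
            raise ConfigError("block_size must be >= 1")
        if c.sample_period <= 0 or c.hold_init % c.sample_period or c.hold_step % c.sample_period:
            raise ConfigError("sample_period must divide hold_init and hold_step")
        if not 0 <= c.lights_on_hour < 24:
            raise ConfigError("lights_on_hour must be an hour of day")

    # -- staircase lattice helpers -------------------------------------------------

    @property
    def hold_levels(self) -> tuple[int, ...]:
        """All representable required hold durations, ms."""
        return tuple(range(self.hold_init, self.hold_max + 1, self.hold_step))

    @property
    def lights_off_hour(self) -> float:
        return (self.lights_on_hour + 24 - self.dark_phase_hours) % 24

    # -- (de)serialisation ---------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TaskConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)


DEFAULT_CONFIG = TaskConfig()
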