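"""Readers and writers for the lever-cage file formats.

Formats (all plain text):

* **Event log** — JSON-lines, one event per line with keys ``t_s``,
  ``animal_id``, ``kind``, ``payload``; also exportable as CSV with a fixed
  column order (``t_s, animal_id, kind, payload``) where the payload is
  encoded ``key=value;key=value``.
* **Trace files** — per-trial CSV with header ``time_ms,angle_deg``;
  ``time_ms`` starts at 0 at trial initiation.
* **Trial table** — CSV, one row per trial, referencing the trace file.
* **Config / profiles** — YAML.
* **Run manifest** — JSON: config snapshot, file checksums, tool version,
  seed, wall-clock anchor for hour-of-day binning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import TaskConfig
from .errors import MalformedTraceError, ParseError, ValidationError
from .simulator import AgentProfile, SimOutput
from .task_engine import LeverTrace, SessionEvent, TrialRecord

__all__ = [
    "read_event_log",
    "write_event_log",
    "write_event_csv",
    "read_trace",
    "write_trace",
    "read_profiles",
    "write_profiles",
    "RunManifest",
    "save_run",
    "load_run",
]

TRIAL_COLUMNS = [
    "trial_id", "animal_id", "phase", "t_init_s", "required_hold_ms",
    "outcome", "reward_volume_ul", "t_outcome_s", "trace_file",
]


# ---------------------------------------------------------------------------
# event logs
# ---------------------------------------------------------------------------


def _validate_order(events: Sequence[SessionEvent]) -> None:
    last: dict[str, float] = {}
    for i, ev in enumerate(events):
        prev = last.get(ev.animal_id)
        if prev is not None and ev.t < prev:
            raise ValidationError(
                f"events for {ev.animal_id!r} out of order at index {i} "
                f"(t={ev.t} after t={prev})"
            )
        last[ev.animal_id] = ev.t


def write_event_log(events: Sequence[SessionEvent], path: str | Path) -> Path:
    """Write events as JSON-lines; returns the path."""
    path = Path(path)
    with path.open("w") as fh:
        for ev in events:
            fh.write(json.dumps(
                {"t_s": ev.t, "animal_id": ev.animal_id, "kind": ev.kind,
                 "payload": ev.payload},
                sort_keys=True,
            ))
            fh.write("\n")
    return path


def read_event_log(path: str | Path) -> list[SessionEvent]:
    """Read a JSON-lines event log; validates per-animal time ordering."""
    events: list[SessionEvent] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
                ev = SessionEvent(
                    t=float(d["t_s"]),
                    animal_id=str(d["animal_id"]),
                    kind=str(d["kind"]),
                    payload=dict(d.get("payload") or {}),
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"bad event ({exc})", line=lineno) from exc
            events.append(ev)
    _validate_order(events)
    return events


def write_event_csv(events: Sequence[SessionEvent], path: str | Path) -> Path:
    """Export events as CSV (t_s, animal_id, kind, payload as key=value;...)."""
    path = Path(path)
    rows = []
    for ev in events:
        payload = ";".join(f"{k}={v}" for k, v in sorted(ev.payload.items()))
        rows.append({"t_s": ev.t, "animal_id": ev.animal_id, "kind": ev.kind,
                     "payload": payload})
    pd.DataFrame(rows, columns=["t_s", "animal_id", "kind", "payload"]).to_csv(
        path, index=False)
    return path


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def write_trace(trace: LeverTrace, path: str | Path) -> Path:
    """Write one trace as CSV (time_ms from 0 at the first sample)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time_ms,angle_deg\n")
        for t, a in zip(trace.times_ms, trace.angles):
            fh.write(f"{t:g},{a:.10g}\n")
    return path


def read_trace(path: str | Path, t0: float = 0.0) -> LeverTrace:
    """Read a trace CSV; infers the sample period and checks uniformity."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error wrapping
        raise ParseError(f"cannot read trace file {path}: {exc}") from exc
    if list(df.columns) != ["time_ms", "angle_deg"]:
        raise ParseError(f"trace file {path} must have columns time_ms,angle_deg")
    times = df["time_ms"].to_numpy(dtype=float)
    angles = df["angle_deg"].to_numpy(dtype=float)
    if times.size < 2:
        raise MalformedTraceError(f"trace file {path} has fewer than 2 samples")
    return LeverTrace.from_times(times, angles, t0=t0)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def write_profiles(profiles: Sequence[AgentProfile], path: str | Path) -> Path:
    import yaml

    path = Path(path)
    out = []
    for p in profiles:
        d = dataclasses.asdict(p)
        d["circadian_weights"] = [float(w) for w in d["circadian_weights"]]
        out.append(d)
    path.write_text(yaml.safe_dump(out, sort_keys=False))
    return path


def read_profiles(path: str | Path) -> list[AgentProfile]:
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list):
        raise ParseError(f"profile file {path} must contain a list of profiles")
    profiles = []
    for d in data:
        d = dict(d)
        d["circadian_weights"] = np.asarray(d["circadian_weights"], dtype=float)
        profiles.append(AgentProfile(**d))
    return profiles


# ---------------------------------------------------------------------------
# run directories
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance record written alongside every run directory."""

    tool: str
    version: str
    seed: Optional[int]
    created_utc: str
    config: dict
    files: dict[str, str]  # relative path -> sha256
    experiment_start_utc: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_run(sim: SimOutput, outdir: str | Path) -> Path:
    """Persist a simulated (or replayed) run as a self-describing directory."""
    outdir = Path(outdir)
    (outdir / "traces").mkdir(parents=True, exist_ok=True)

    write_event_log(sim.events, outdir / "events.jsonl")
    sim.config.to_yaml(outdir / "config.yaml")
    if sim.profiles:
        write_profiles(sim.profiles, outdir / "profiles.yaml")

    rows = []
    for rec in sim.trials:
        trace_file = ""
        if rec.trace is not None:
            trace_file = f"traces/{rec.trial_id}.csv"
            write_trace(rec.trace, outdir / trace_file)
        rows.append({
            "trial_id": rec.trial_id,
            "animal_id": rec.animal_id,
            "phase": rec.phase,
            "t_init_s": rec.t_init,
            "required_hold_ms": rec.required_hold,
            "outcome": rec.outcome,
            "reward_volume_ul": rec.reward_volume,
            "t_outcome_s": rec.t_outcome,
            "trace_file": trace_file,
        })
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(outdir / "trials.csv",
                                                     index=False)

    files = {}
    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            files[str(f.relative_to(outdir))] = _sha256(f)
    manifest = RunManifest(
        tool="levercage",
        version=__version__,
        seed=sim.seed,
        created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        config=sim.config.to_dict(),
        files=files,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return outdir


def load_run(rundir: str | Path) -> SimOutput:
    """Load a run directory back into memory (traces included)."""
    rundir = Path(rundir)
    manifest_path = rundir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {rundir}")
    manifest = RunManifest.from_json(manifest_path.read_text())
    config = TaskConfig.from_dict(manifest.config)
    events = read_event_log(rundir / "events.jsonl")
    profiles: list[AgentProfile] = []
    if (rundir / "profiles.yaml").exists():
        profiles = read_profiles(rundir / "profiles.yaml")

    trials: list[TrialRecord] = []
    df = pd.read_csv(rundir / "trials.csv")
    for row in df.itertuples(index=False):
        trace = None
        if isinstance(row.trace_file, str) and row.trace_file:
            trace = read_trace(rundir / row.trace_file, t0=float(row.t_init_s))
        required = None if pd.isna(row.required_hold_ms) else int(row.required_hold_ms)
        t_outcome = None if pd.isna(row.t_outcome_s) else float(row.t_outcome_s)
        trials.append(TrialRecord(
            animal_id=str(row.animal_id),
            phase=int(row.phase),
            t_init=float(row.t_init_s),
            outcome=str(row.outcome),
            reward_volume=float(row.reward_volume_ul),
            required_hold=required,
            t_outcome=t_outcome,
            trace=trace,
            trial_id=str(row.trial_id),
        ))
    return SimOutput(events=events, trials=trials, profiles=profiles,
                     config=config, seed=manifest.seed if manifest.seed is not None else 0)
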