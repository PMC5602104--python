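# levercage

A desk-scale software implementation of an automated home-cage
lever-positioning task for mice, of the kind used to assess skilled motor
learning and movement kinematics in models of Huntington's disease and other
movement disorders. The package provides the complete closed-loop task
controller, a per-trial kinematic and circadian analysis pipeline, and a
virtual-mouse simulator that stands in for the hardware (lever, rotary
encoder, RFID reader, water valve) and the animals, so that every part of the
system can be developed and tested without a cage.

It is intended for behavioral-neuroscience groups building or validating
home-cage operant systems, and for anyone who needs a fully reproducible
reference implementation of the task logic.

## The task

Group-housed, RFID-tagged mice have 24-h access to a small chamber containing
a lever restricted to a 24° range and held at rest by a counterweight.

* **Phase 1 (operant acquisition).** Entering the chamber dispenses a 5 µl
  water drop (at most 200 drops per animal per day). Pulling the lever past
  the center of its range (12° from rest) is a trial, rewarded with 10 µl on
  a continuous reinforcement schedule. Animals with ≤ 200 phase-1 trials fail
  the acquisition criterion.
* **Phase 2 (hold).** After initiation at 12°, the lever must stay inside a
  goal range of 4.5°–19.5° for a required hold duration *d*. The reward
  (10 µl) is dispensed when the hold elapses; leaving the range earlier fails
  the trial immediately. *d* follows a block-wise adaptive staircase: every
  25 trials, with block success rate *r*,

  d ← min(d + 100 ms, 800 ms)  if r > 75%
  d ← max(d − 100 ms, 100 ms)  if r < 10%
  d unchanged otherwise,

  starting from 100 ms.

* **Kinematics.** For each animal, successful trials at the 800-ms ceiling
  are summarised (once ≥ 200 such trials exist) by the maximum lever
  displacement, the OLS slope of the position trace over 200–800 ms after
  initiation (negative slope = progressive release, analogous to motor
  impersistence), and the mean absolute lever speed.
* **Circadian and activity metrics.** Trials binned by hour of day,
  dark-phase trial percentage, trials and time-in-chamber per day
  (days bounded at lights-on), and staircase progression per 25-trial block.

## Worked example

Simulate a mixed cage with one steady-holding ("WT-like") and one
overshoot-and-release ("HD-like") virtual mouse — 2 days of phase 1 followed
by 3 days of phase 2 — then analyse it:

```bash
levercage simulate --preset WT-like --preset HD-like \
    --phase1-days 2 --days 3 --seed 42 --out demo
levercage analyze --run demo
levercage report --run demo
```

prints

```
wrote 3417 trials from 2 animals to demo
analysis tables written to demo/analysis
run: demo  (seed 42, 3417 trials)
total water dispensed: 32635 ul
  HD-like-00: phase1=711 (acquired), phase2=1031 (776 success), final hold=800 ms (reached), dark-phase trials=55.6%
  WT-like-00: phase1=689 (acquired), phase2=986 (986 success), final hold=800 ms (reached), dark-phase trials=82.4%
```

Both animals clear the >200-trial acquisition criterion and reach the 800-ms
hold ceiling; the HD-like animal fails ~25% of its hold trials (overshoots
through the top of the goal range) and performs relatively more of its trials
in the light phase. The kinematic summary (`demo/analysis/kinematics.csv`)
separates the phenotypes:

```
animal_id,n_eligible_trials,excluded,mean_max_displacement,sd_max_displacement,mean_hold_slope,...
HD-like-00,497,False,18.48,0.65,-5.03,...
WT-like-00,811,False,14.69,0.84,-0.48,...
```

i.e. the HD-like agent pulls ~4° further and releases the lever at ~−5 °/s
during the hold, while the WT-like agent holds steady. `levercage replay`
re-runs the controller over a run's stored traces and entry/exit events and
reproduces the recorded outcomes exactly.

## Layout

```
src/levercage/
  config.py       task geometry/timing constants (TaskConfig)
  task_engine.py  trial detection, phase-1/2 classification, staircase,
                  entry rewards, session orchestration
  kinematics.py   per-trial features and per-animal aggregation
  metrics.py      acquisition, circadian histograms, progression, activity
  simulator.py    virtual mice: visit schedules, lever-trace generation,
                  logistic competence model, full cage simulation
  io.py           JSON-lines event logs, trace/trial CSVs, YAML profiles,
                  run manifests
  cli.py          `levercage simulate | replay | analyze | report`
```

See `docs/methods.md` for the model details, parameter defaults, and design
decisions.
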