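# Methods

This note documents the task model implemented by `levercage`, the
parameters that matter, the generative model behind the virtual mice, the
numerical choices, and the known limitations.

## Task controller

### Trial detection

The controller consumes a uniformly sampled lever-angle stream (degrees from
the counterweighted rest position; 100 Hz default). It starts *armed*; a
trial initiates at the first sample with angle ≥ `pull_threshold` (12°)
while armed. The controller then disarms until the first subsequent sample
with angle < `rearm_threshold` (1°), giving one trial per arm/disarm cycle
and debouncing oscillations around the initiation threshold. Trial segments
run from the initiation sample to the re-arm sample inclusive.

Thresholds are inclusive (initiation at ≥ 12°, goal range [4.5°, 19.5°]
closed on both ends): encoder quantization makes open and closed intervals
indistinguishable in a physical system, and the closed form is the simplest
testable contract. An optional ±tolerance band on initiation can be emulated
by adjusting `pull_threshold`; the default is the sharp 12° threshold.

### Classification

*Phase 1*: every detected pull is a success, rewarded with
`trial_reward_volume` (10 µl) at initiation.

*Phase 2*: success iff **every** sample from initiation through
`required_hold` ms later (inclusive on the sample lattice) lies inside
`[goal_low, goal_high]`. The hold timer starts at the 12° crossing — not at
goal-range entry — which is well-defined because the initiation threshold
lies strictly inside the goal range. A failure is recorded at the first
out-of-range sample and dispenses nothing. A segment that ends (stream end)
before the hold elapses without leaving the range is discarded unscored
rather than counted either way, avoiding truncation bias.

### Staircase

Per animal, over non-overlapping consecutive blocks of `block_size` (25)
scored trials, continuing across visits and days:

* success fraction strictly > 75% → `required_hold` += 100 ms (cap 800 ms);
* strictly < 10% → −100 ms (floor 100 ms);
* otherwise unchanged.

Threshold comparisons use exact rational arithmetic so that a block landing
exactly on a threshold (e.g. 1/10 vs. 0.10) never moves the staircase;
binary floating-point representations of 0.10 would otherwise make this
edge case platform- and ordering-dependent. A perfect agent therefore
reaches the 800-ms ceiling after exactly (800−100)/100 × 25 = 175 trials
and never earlier.

### Entry rewards and the day boundary

Each chamber entry dispenses `entry_reward_volume` (5 µl) until the animal
has received `entry_reward_daily_cap` (200) drops that day; the counter
increments only when a drop is actually dispensed. "Day" is anchored at
lights-on (`lights_on_hour`, default 07:00) for the cap and for all per-day
metrics, which keeps reward accounting and circadian analyses on the same
clock. The cap is per animal (a per-cage variant is a one-line config
change, `entry_reward_daily_cap` being consulted per animal id).

## Kinematic features

Computed on trial segments (initiation to re-arm):

* **max_displacement** — maximum sampled angle, degrees.
* **hold_slope** — ordinary least-squares slope of angle vs. time over
  200–800 ms after initiation, degrees/s, inclusive endpoints on the sample
  lattice, no smoothing. Negative values indicate progressive release of
  the lever during the hold.
* **mean_speed** — mean |Δθ|/Δt over consecutive samples, degrees/s, over
  the full segment by default (a hold-window variant is exposed; "speed" has
  no canonical window, and the full-segment reading is the most literal).

Per-animal summaries average per-trial features (not features of the
averaged trace) over successful trials at the 800-ms ceiling, and are
emitted only when ≥ 200 such eligible trials exist; dispersion is reported
as the sample SD. Averaging per-trial slopes rather than fitting the
averaged trace keeps the estimator unbiased under trial-to-trial latency
jitter; the averaged-trace variant can be built from the stored traces if
needed.

## Behavioral metrics

* **Acquisition**: strictly more than 200 phase-1 trials.
* **Circadian histogram**: trials binned into 24 half-open wall-clock hour
  bins; percentages sum to 100; the dark-phase percentage sums the 12 bins
  from lights-off. Bin origin is configurable (midnight default; pass
  lights-on for photoperiod-aligned axes) — rotating the origin permutes
  bins without changing their multiset.
* **Progression curve**: offline replay of the staircase over an animal's
  outcome sequence, reporting the post-evaluation hold and success rate per
  25-trial block; a 500-trial horizon is the default for cross-animal
  comparison. The replay is an independent code path from the live
  controller and is tested to agree with it.
* **Daily activity**: per animal-day trial counts, time in chamber (visits
  clipped at lights-on boundaries; no clipping loss), and a natural-log
  transformed count column (undefined for zero-count days, which fail
  acquisition anyway).

## The virtual mouse

The simulator is an explicit invention: its purpose is parameter recovery
and end-to-end testing, not fitting any real animal. The simplest forms
able to express the phenotypes of interest were chosen:

* **Visits**: daily counts ~ Poisson(`visits_per_day`, default 20); start
  hours categorical on `circadian_weights`; durations ~ clipped Gaussian
  (mean 150 s). One animal occupies the chamber at a time; overlapping
  visits are queued deterministically. Default presets put most weight on
  the first 6 h of the dark phase (the HD-like preset shifts weight into
  the late light phase and drops it early in the dark).
* **Competence**: an agent holding-skill `skill_ms` grows linearly by
  `learning_rate` per trial (default 2 ms, cap 1500 ms). The probability of
  *attempting* a sufficient hold at required duration *d* is logistic,
  p = 1/(1+exp((d−skill)/τ)), τ = 50 ms.
* **Traces**: linear rise at `rise_speed` (80°/s) to a Gaussian peak, a hold
  segment at a Gaussian level with Gaussian sample noise and linear drift
  (`release_slope`), then a linear return to rest; samples clipped to
  [0°, 24°]. Outcomes are *always* produced by running the real classifier
  on the generated trace, so simulator and engine cannot disagree.
* **Intended failures** are generated as phase-1-style vigorous pulls
  through the top of the goal range (peak ≈ 21.5°). This choice is
  deliberate: with the hold timer anchored at the 12° crossing and a finite
  lever return speed, an "early release" at the 100-ms staircase floor
  would still keep the lever inside the goal range long enough to succeed,
  so release-timing alone cannot produce a controlled failure rate at short
  holds. The vigorous-pull failure is classifier-guaranteed and mirrors how
  non-adapting animals actually fail (persisting with the acquisition-phase
  movement).
* **Presets**: `WT-like` (peak 14.5±1.0°, hold 13.0±0.8°, drift −0.5 °/s) —
  steady hold just past the goal-range center; `HD-like` (peak 18.5±1.2°,
  hold 17.5±0.8°, drift −5 °/s) — near-ceiling pulls with ~20% overshoot
  failures and progressive release. The HD-like peak mean sits *below*
  19.5° by design: a mean overshoot beyond the goal range would fail nearly
  every trial and stall the staircase, leaving no eligible trials to
  summarise; 18.5±1.2 keeps the staircase progressing while still
  separating strongly from WT-like in both max displacement and hold slope.
  `perfect` (noiseless, always succeeds), `deadzone` (skill 80 ms: ~40%
  success at the floor, inside the no-change zone with negligible
  probability of crossing either block threshold), and `nonacquirer`
  (explores on day 0, then stops) complete the corners of the behaviour
  space.
* **RNG**: one master seed; each animal draws from an independent substream
  keyed by (seed, CRC32(animal id)), so adding a cage-mate never perturbs
  an existing animal's draws. Runs are byte-for-byte reproducible.

### What the simulator does and does not emulate

It reproduces the *structure* of the real data (event streams, trace
morphologies, staircase dynamics, circadian load) but not real-mouse
physiology: no satiety/motivation dynamics, no weight, no inter-animal
interaction beyond chamber queueing, no encoder noise model, and lever
kinematics are piecewise-linear-plus-noise rather than biomechanical.
Passing tests therefore demonstrate that the pipeline recovers known ground
truth from data of this structure — not that any biological claim holds in
real animals.

## Numerical choices and scales

* Sampling 10 ms (100 Hz): resolves the 100-ms staircase step with 10×
  margin; hold durations are constrained to multiples of the sample period.
* Hold-window endpoints inclusive on the sample lattice; OLS slope computed
  in closed form (centered covariance over variance) and cross-checked in
  tests against a normal-equations solve at 1e-9.
* Bisection recoveries of the classifier boundaries run at 0.01°
  resolution on noiseless constructed traces.
* Test-suite scales: staircase properties exhaustively over short per-block
  count sequences; classifier-vs-oracle on 1000 random-walk traces;
  phenotype sign recovery over 100 seeded replicates of 20 agents/group ×
  250 trials/agent; circadian recovery on a 100-day single-animal run
  (total-variation distance < 0.05 to the generator weights). These sizes
  keep the full suite under ~2 minutes on one CPU while leaving each check
  statistically comfortable.

## Known limitations

* No hardware I/O or real-time guarantees; the controller is an offline/
  stream replay of recorded or simulated traces.
* Inferential statistics (ANOVA, post-hoc, nonparametric tests) are out of
  scope by design; outputs are tidy per-animal tables for any statistics
  environment.
* The event-log and trace formats are this package's own documented
  dialect (JSON-lines + CSV); real cage software would need an adapter.
* A visit whose trials would overrun its scheduled duration truncates the
  remainder, so realised trials-per-visit can fall slightly below the
  Poisson mean at high trial loads.
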