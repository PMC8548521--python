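# File formats

All artefacts are plain text. Positions are cm, angles degrees, time
seconds; ticks are 0-based and samples are stamped at the *end* of each
tick (the first sample sits at t = tick).

## Trajectory log (CSV, one file per bee per run)

```
t_s,x_cm,y_cm,heading_deg,locked,fix_plus,fix_minus
0.017000,-0.001803,0.024920,3.103462,0,0,0
...
```

- `t_s` — sample time; strictly increasing with spacing equal to the tick.
- `x_cm`, `y_cm` — position in the arena frame (origin = trial start,
  +y toward the screen centre, left = −x).
- `heading_deg` — heading in (−180, 180], leftward positive.
- `locked` — 1 during the 8 s post-choice screen lock (training trials
  only); the pose is frozen while locked.
- `fix_plus`, `fix_minus` — 1 when the CS+ (resp. CS−) centre falls within
  the screen-centre fixation window that tick.

File names follow `bee{NNN}_train{TT}.csv` and `bee{NNN}_test.csv`.

## Manifest (`manifest.yaml`, one per run directory)

Contains the package version, condition label, experiment seed, the full
arena and protocol configuration snapshots, and one entry per bee with its
contingency (CS+/CS− colours), per-bee seed, and a map from log file name
to per-trial outcomes (`phase`, `trial_index`, `choice`, `latency`,
`reinforcement`, `cs_plus_side`). A run directory is fully regenerable
from its manifest; write → read → write is byte-identical.

Choice categories: `cs_plus`, `cs_minus`, `red`, `no_stimulus`, `nc`.
`latency` is null for `nc`. `cs_plus_side` is `left`/`right` (for
phototaxis runs it is the red-stimulus side).

## Config file (YAML, two flat sections)

```yaml
arena:
  start_pose: [0.0, 0.0, 0.0]   # x, y, heading
  stimulus_azimuth: 50.0
  start_distance: 44.0
  choice_axis_distance: 5.0
  facing_tolerance: 15.0
  screen_radius: 9.0
  fixation_halfwidth: 0.25
  wall_radius: 100.0
  grating_bar_angle: 6.0
  background: transparent       # grating_closed_loop | grating_gaze_fixed | grating_rotating
  grating_speed: 12.0
  ventral_flow: false
  tick: 0.017
protocol:
  n_trials: 10
  trial_cap: 60.0
  iti: 60.0
  initial_dark: 60.0
  lock_duration: 8.0
  lambda_plus: 1.0
  lambda_minus: -1.0
  test_duration: 60.0
  min_choices_to_keep: 5
  balanced_contingency: true
```

The values above are the shipped baseline. `apivr simulate --config FILE`
consumes this format; `apivr.io.write_config` emits it.

## Analysis outputs

- `metrics.csv` — one row per kept bee per trial: `bee_id, trial,
  cs_plus_color, choice, latency_s, distance_cm, mean_speed_cm_s,
  tortuosity, cumulative_turning_deg` (tortuosity empty for closed loops).
- `learning_curves.csv` — one row per trial × category: `trial, category,
  proportion, ci_low, ci_high` (95% percentile bootstrap).
- `occupancy_train.csv` — raw integer bin counts of the 1 cm² occupancy
  grid (the 10% display cap is applied at render time only).
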