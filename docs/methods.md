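# Methods

## The simulated paradigm

The engine reproduces, headlessly, a closed-loop VR arena for walking
honey bees. An agent has a planar pose — position in cm and heading in
degrees, wrapped to (−180, 180], with 0 pointing at the screen centre and
positive headings to the left. Every 0.017 s tick the agent emits a motion
increment (forward/lateral translation and a heading change), the pose is
integrated (rotate, then translate in the new heading frame), and the
engine evaluates the choice and fixation predicates. Nothing is rendered:
the display geometry enters only through bearings and angular subtenses,
which is sufficient because every behavioural criterion of the paradigm is
horizontal.

Two vertical cuboids (5 × 5 cm base; the 1 m height is metadata) start at
azimuths ±50° and 44.0 cm from the agent. The start distance is chosen so
that a 5 cm face subtends 6.5° at trial start; the choice boundary is
5.0 cm from the cuboid axis, where the face subtends ≈53°. A choice
registers when the agent is inside that boundary *and* faces the cuboid
centre within 15° (the facing tolerance is a package choice; the source
protocol requires "directly facing" without a number). Fixation uses the
ray-casting criterion: the cuboid centre within ±2.5 mm of the screen
centre at 9 cm, i.e. a closed half-angle of atan(0.25/9) ≈ 1.59°.

The wall grating (6° bars on a 100 cm cylindrical wall) exists in three
motion regimes, distinguished entirely by the evolution of its retinal
phase: world-anchored (closed loop; apparent motion equals the agent's
yaw), gaze-servoed (identically zero retinal slip), and rotating
(anticlockwise at 12 m/s along the wall ⇒ 12 rad/s ≈ 687.5°/s). The
published per-cm expansion rates of cuboid and grating are emergent
diagnostics of this geometry, not constraints: they cannot all be derived
from a single pinhole convention at the stated distances, so the package
treats the printed angles (6.5°, 53°, 6° bars) as authoritative.

## Treadmill kinematics

Two optical sensors aimed at the ball equator, 90° apart (±45° off the
body axis), each report horizontal and vertical surface displacements per
tick. The standard two-sensor trackball solution applies: yaw rate is the
mean horizontal displacement divided by the ball radius (ball-left =
animal-right), and the two vertical displacements rotate through ±45° into
forward and lateral translation (ball-backward = animal-forward). The
inverse map is exact on consistent readings (h1 = h2) and is used to emit
synthetic raw sensor logs. Slip, inertia and the 7 mm sensor standoff are
ignored; the ball texture (plain vs. checkered) changes perception, not
mechanics, so it only sets the ventral-flow flag consumed by agents.

## Trial protocol

Ten training trials per bee: each runs until the first choice-zone entry
or a 60 s cap (no choice, NC). At a choice the scene freezes for 8 s, the
reinforcer is delivered and the learning update applied exactly once — the
3 s physical delivery has no computational consequence and is collapsed
into an instantaneous event at lock onset. Latency is stamped at zone
entry. Inter-trial intervals (60 s) and the initial 60 s dark screen are
bookkeeping only. The non-reinforced test has a fixed 60 s duration; the
first choice is recorded and per-tick fixation flags accumulate to the
end. CS+ colour assignment is balanced across the cohort (exact half-split
at even n) and the CS+ side is re-randomised uniformly each trial. Bees
with fewer than 5 choices in 10 trials are excluded from analysis. The
phototaxis scenario runs four consecutive 60 s extinction tests against a
single red cuboid, with a mirror-image probe zone on the empty side
scoring "no stimulus" choices.

Everything is reproducible: each bee consumes an independent RNG substream
spawned from the experiment seed, and identical (seed, config) pairs give
byte-identical logs.

## Synthetic agents

The agents are generative stand-ins for real bees, built to reproduce the
paradigm's qualitative effect pattern — not neural or biomechanical
models.

**Phototactic walker.** Speed is max(0, 1.5 + N(0, 0.75)) cm/s; heading
receives Gaussian noise of 5°/tick plus, when the stimulus irradiance
exceeds a 50 µW/cm² detection threshold (between the dimmest red at 13 and
the mid red at 140), an attraction term g·sin(bearing). The steering gain
g = 0.291 was fixed by a one-off grid search so that the brightest red
(1130 µW/cm²) is chosen in ≈52.5% of 60 s tests, the published rate; the
calibration is committed in `agents.PHOTOTAXIS_CALIBRATION` and frozen.
Below threshold the walk is an unbiased correlated random walk, so red and
empty-side choices are symmetric by construction and most tests end NC.

**Rescorla–Wagner learner.** Each colour carries an associative strength V
updated at reinforcement by V ← V + α_eff(λ − V), with λ = +1 (sucrose)
and −1 (quinine/NaCl; the two aversive reinforcers differ only through
this configurable asymptote). Per tick the agent computes a utility for
each visible cuboid, salience + V, where salience is 0.5·log10(irradiance),
and steers toward the argmax with drive A·4.0·sin(bearing). The attention
factor A ∈ [0, 1] expresses distraction by the frontal background
(defaults 1.0 transparent, 0.7 gaze-fixed, 0.3 closed-loop and rotating —
calibration constants with the qualitative ordering as the shipped
default, not measured quantities). A also multiplies the learning rate
(α_eff = A·α, α = 0.15) and divides the steering noise as 1/√A (floored at
A = 0.05 so the A = 0 limit is a finite pure-noise walk). An optomotor
term adds optomotor_gain × (per-tick retinal slip of the grating) to the
heading — non-zero (0.02) only under the rotating grating — and a ventral
factor multiplies walking speed by 0.8 when the treadmill ball is
textured.

The parameterisation makes the mechanism of the distraction effect
explicit: a naive agent's argmax is salience-driven (blue outshines green
by a fixed 0.41 utility gap), and learning must overcome that gap. At
A = 1 about four reinforcements suffice, so cohorts separate CS+ from CS−
within ten trials; at A = 0.3 the effective learning rate is too small to
close the gap within a session, so choices stay salience-driven and —
because the rewarded colour is balanced across bees — CS+ and CS−
proportions remain at chance. This also yields the faster learning when
blue is rewarded that the paradigm reports.

What the generator does **not** emulate: motivational decline across
trials (a constant NC rate rather than a late rise), trial-to-trial
individual differences beyond RNG substreams, antennal/contact events, and
any vertical visual structure. Retained cohorts are consequently cleaner
than real ones (e.g. near-unanimous CS+ choice by trial 10 in the
transparent condition); passing tests show that the pipeline recovers the
programmed effect pattern, not that real bees behave this cleanly.

## Analysis battery

Tortuosity is path length over the first-to-last-point chord (1 for a
straight path); closed loops (chord < 1 nm) are flagged undefined, warned
about, and excluded from aggregation. Distance, mean speed (distance over
elapsed time, pauses included) and signed cumulative turning are computed
over the pre-lock portion of each trial, including the one-tick step from
the start pose. Learning curves are per-trial one-hot category proportions
(CS+/CS−/NC sum to 1) over kept bees with 95% percentile-bootstrap CIs
(default 10 000 replicates, resampling bees; the bootstrap variant and
replicate count are package choices). Occupancy maps bin pose samples into
1 cm² cells after reflecting each log so the CS+ is on the right by
convention; the 10% display cap applies only to the rendering colour
scale, never to the stored counts. Fixation times are tick counts times
the tick length; the CS+/CS− comparison is a two-sided Wilcoxon
signed-rank test (exact null for ≤25 non-zero pairs, normal approximation
with tie correction above; the statistic is reported as the positive-rank
sum V). An all-zero difference vector is flagged with a warning and
reported as p = 1. Cohort-level inference is deliberately descriptive —
proportions, bootstrap CIs and signed-rank tests; no mixed-model fitting.

## Numerical and design notes

- Angles are degrees at every API boundary, radians internally; heading
  wrapping uses IEEE remainder so in-range values pass through exactly.
- Boundary conventions are closed: a bearing exactly at the fixation
  half-angle counts as fixating; exactly 5 choices keeps a bee.
- Heading-then-translate integration per tick; the ordering matters only
  at second order in the 0.017 s step.
- The arena wall clamps positions at radius 99.5 cm (agents essentially
  never reach it under shipped parameters).
- The optomotor turning assay runs in an empty arena (stationary-start
  agent, grating only): with stimuli present the steering loop absorbs a
  small optomotor bias into a shifted equilibrium bearing, while a bias
  large enough to dominate steering abolishes choices; the empty-arena
  drift isolates the response itself.
- The ventral-flow distance/speed comparison uses fixed-duration (test
  phase) runs: choice-terminated trials are path-length-limited, so a
  slower agent takes longer but walks the same distance; over a fixed
  60 s the 0.8 speed factor produces strictly less distance.
- Monte-Carlo checks in the test suite use cohort sizes of 24 bees
  (learning separation), 100 paired seeds (optomotor drift), 50 paired
  seeds (ventral flow), 200–800 phototaxis tests and 1000 bootstrap
  cohorts — sizes chosen to keep each check's false-failure probability
  well below 1% at the programmed effect sizes.

## Known limitations

The engine is strictly planar and pixel-free: no perspective beyond
azimuth bearings, no vertical field, no photoreceptor model (the palette
carries the published RGB/irradiance values but colour processing is
reduced to a log-irradiance salience). Agent parameters are calibrated to
one published effect pattern; transferring them to other arenas or
stimulus sets requires recalibration (`apivr calibrate` re-runs the
phototaxis grid search).
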