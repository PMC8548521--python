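"""Experiment engine: trials, tests, reinforcement and cohort scheduling.

A differential-conditioning session consists of 10 training trials and one
non-reinforced test. Each training trial runs in 0.017 s ticks for at most
60 s; the first entry into a stimulus choice zone registers the choice,
freezes the displayed scene for 8 s (during which the reinforcer is
delivered and the learning update applied once), and ends the trial. The
test has a fixed 60 s duration with no reinforcement: the first choice is
recorded and logging continues to the end, accumulating per-tick fixation
flags. Inter-trial intervals (60 s of dark screen) are bookkeeping only —
no stimuli, no samples, no agent updates.

The phototaxis scenario replaces the stimulus pair with a single red cuboid
and a mirror-image "no stimulus" probe zone on the empty side; each bee
runs four consecutive 60 s extinction tests.

Bees that fail to make a choice in at least 5 of their 10 training trials
are excluded from analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .agents import CuboidView, Percept
from .geometry import (
    ArenaConfig,
    Background,
    Cuboid,
    StimulusRole,
    _azimuth_point,
    fixation_half_angle,
    grating_angular_speed,
    normalize_heading,
)

__all__ = [
    "Stimulus",
    "PALETTE",
    "Phase",
    "Choice",
    "ProtocolConfig",
    "TrialLog",
    "BeeLog",
    "ExperimentLog",
    "make_stimulus_pair",
    "run_trial",
    "run_test",
    "run_phototaxis_tests",
    "run_experiment",
    "apply_exclusion",
]


@dataclass(frozen=True)
class Stimulus:
    """A named display colour with its RGB triple and irradiance (uW/cm^2)."""

    name: str
    rgb: Tuple[int, int, int]
    irradiance: float


#: the rig's stimulus palette: training colours, the three red intensities of
#: the phototaxis scenario, and the grating colours.
PALETTE: Dict[str, Stimulus] = {
    s.name: s
    for s in (
        Stimulus("blue", (0, 0, 255), 161_000.0),
        Stimulus("green", (0, 51, 0), 24_370.0),
        Stimulus("red_10", (26, 0, 0), 13.0),
        Stimulus("red_50", (128, 0, 0), 140.0),
        Stimulus("red_100", (255, 0, 0), 1130.0),
        Stimulus("black", (0, 0, 0), 45.0),
    )
}


class Phase(str, Enum):
    TRAIN = "train"
    TEST = "test"
    PHOTOTAXIS_TEST = "phototaxis_test"


class Choice(str, Enum):
    CS_PLUS = "cs_plus"
    CS_MINUS = "cs_minus"
    RED = "red"
    NO_STIMULUS = "no_stimulus"
    NC = "nc"


@dataclass(frozen=True)
class ProtocolConfig:
    """Trial schedule and reinforcement constants.

    ``lambda_plus``/``lambda_minus`` are the associative asymptotes handed to
    the agent for correct/incorrect choices (sucrose vs. quinine or NaCl;
    the aversive reinforcers differ only through this configurable value).
    """

    n_trials: int = 10
    trial_cap: float = 60.0
    iti: float = 60.0
    initial_dark: float = 60.0
    lock_duration: float = 8.0
    reinforcer_plus: str = "sucrose 1.5 M"
    lambda_plus: float = 1.0
    reinforcer_minus: str = "quinine 60 mM"
    lambda_minus: float = -1.0
    test_duration: float = 60.0
    min_choices_to_keep: int = 5
    balanced_contingency: bool = True

    def __post_init__(self) -> None:
        if min(self.trial_cap, self.iti, self.lock_duration, self.test_duration) <= 0:
            raise ValueError("durations must be positive")
        if not 0 < self.min_choices_to_keep <= self.n_trials:
            raise ValueError("min_choices_to_keep must lie in (0, n_trials]")


@dataclass
class TrialLog:
    """Timestamped pose samples and the single choice event of one run."""

    phase: Phase
    trial_index: int
    t: List[float] = field(default_factory=list)
    x: List[float] = field(default_factory=list)
    y: List[float] = field(default_factory=list)
    heading: List[float] = field(default_factory=list)
    locked: List[bool] = field(default_factory=list)
    fix_plus: List[bool] = field(default_factory=list)
    fix_minus: List[bool] = field(default_factory=list)
    choice: Choice = Choice.NC
    latency: Optional[float] = None
    reinforcement: Optional[float] = None
    cs_plus_side: Optional[str] = None  # "left" | "right" (stimulus side for red probe runs)

    @property
    def n_samples(self) -> int:
        return len(self.t)


@dataclass
class BeeLog:
    """One simulated bee: contingency, ten training trials and the test."""

    bee_id: int
    cs_plus_color: str
    cs_minus_color: str
    trials: List[TrialLog]
    test: Optional[TrialLog]
    seed: int

    @property
    def n_choices(self) -> int:
        return sum(1 for tr in self.trials if tr.choice is not Choice.NC)


@dataclass
class ExperimentLog:
    arena: ArenaConfig
    protocol: ProtocolConfig
    bees: List[BeeLog]
    seed: int


def make_stimulus_pair(
    arena: ArenaConfig, cs_plus: Stimulus, cs_minus: Stimulus, cs_plus_side: str
) -> Tuple[Cuboid, Cuboid]:
    """Place the CS+/CS- cuboids at the +/-50 deg start azimuths.

    ``cs_plus_side`` is "left" (positive bearing) or "right".
    """
    if cs_plus_side not in ("left", "right"):
        raise ValueError("cs_plus_side must be 'left' or 'right'")
    sign = 1.0 if cs_plus_side == "left" else -1.0
    p = arena.start_pose
    plus_center = _azimuth_point(p, sign * arena.stimulus_azimuth, arena.start_distance)
    minus_center = _azimuth_point(p, -sign * arena.stimulus_azimuth, arena.start_distance)
    plus = Cuboid(
        center=plus_center,
        color_rgb=cs_plus.rgb,
        irradiance=cs_plus.irradiance,
        role=StimulusRole.CS_PLUS,
        color_name=cs_plus.name,
    )
    minus = Cuboid(
        center=minus_center,
        color_rgb=cs_minus.rgb,
        irradiance=cs_minus.irradiance,
        role=StimulusRole.CS_MINUS,
        color_name=cs_minus.name,
    )
    return plus, minus


def _slip_per_tick(arena: ArenaConfig, last_dheading: float) -> float:
    """Retinal phase change (deg) of the wall grating over one tick, given
    the agent's heading change on the previous tick."""
    bg = arena.background
    if bg is Background.TRANSPARENT or bg is Background.GRATING_GAZE_FIXED:
        return 0.0
    slip = -last_dheading
    if bg is Background.GRATING_ROTATING:
        slip += grating_angular_speed(arena) * arena.tick
    return slip


def _run(
    agent,
    arena: ArenaConfig,
    protocol: ProtocolConfig,
    rng: np.random.Generator,
    cuboids: Sequence[Cuboid],
    phase: Phase,
    trial_index: int,
    duration: float,
    *,
    lock_and_reinforce: bool,
    mirror_probe: Optional[Tuple[float, float]] = None,
) -> TrialLog:
    log = TrialLog(phase=phase, trial_index=trial_index)
    tick = arena.tick
    n_ticks = int(round(duration / tick))
    fix_half = fixation_half_angle(arena)
    zone_r2 = arena.choice_axis_distance ** 2
    face_tol = arena.facing_tolerance
    wall_r = arena.wall_radius - 0.5
    wall_r2 = wall_r * wall_r

    pose = arena.start_pose
    x, y, heading = pose.x, pose.y, pose.heading
    last_dheading = 0.0
    choice_made = False

    plus = next((c for c in cuboids if c.role is StimulusRole.CS_PLUS), None)
    minus = next((c for c in cuboids if c.role is StimulusRole.CS_MINUS), None)

    deg = math.degrees
    rad = math.radians
    atan2, sin, cos = math.atan2, math.sin, math.cos

    for k in range(n_ticks):
        percept_views = []
        bearings = {}
        d2s = {}
        for c in cuboids:
            dx = c.center[0] - x
            dy = c.center[1] - y
            b = normalize_heading(deg(atan2(-dx, dy)) - heading)
            bearings[id(c)] = b
            d2s[id(c)] = dx * dx + dy * dy
            percept_views.append(CuboidView(b, c.irradiance, c.color_name, c.role.value))
        percept = Percept(
            views=tuple(percept_views),
            background=arena.background,
            grating_slip=_slip_per_tick(arena, last_dheading),
            ventral_flow=arena.ventral_flow,
            tick=tick,
        )
        delta = agent.step(percept, rng)
        if not (
            math.isfinite(delta.forward)
            and math.isfinite(delta.lateral)
            and math.isfinite(delta.dheading)
        ):
            raise RuntimeError(
                f"agent produced non-finite motion at tick {k}: {delta!r}"
            )
        last_dheading = delta.dheading
        heading = normalize_heading(heading + delta.dheading)
        a = rad(heading)
        sa, ca = sin(a), cos(a)
        x += -delta.forward * sa - delta.lateral * ca
        y += delta.forward * ca - delta.lateral * sa
        r2 = x * x + y * y
        if r2 > wall_r2:
            scale = wall_r / math.sqrt(r2)
            x *= scale
            y *= scale

        t = (k + 1) * tick
        fp = fm = False
        for c in cuboids:
            dx = c.center[0] - x
            dy = c.center[1] - y
            b = normalize_heading(deg(atan2(-dx, dy)) - heading)
            bearings[id(c)] = b
            d2s[id(c)] = dx * dx + dy * dy
            if abs(b) <= fix_half:
                if c.role is StimulusRole.CS_PLUS:
                    fp = True
                elif c.role is StimulusRole.CS_MINUS:
                    fm = True
        log.t.append(t)
        log.x.append(x)
        log.y.append(y)
        log.heading.append(heading)
        log.locked.append(False)
        log.fix_plus.append(fp)
        log.fix_minus.append(fm)

        if not choice_made:
            chosen: Optional[Cuboid] = None
            for c in cuboids:
                if d2s[id(c)] <= zone_r2 and abs(bearings[id(c)]) <= face_tol:
                    chosen = c
                    break
            probe_hit = False
            if chosen is None and mirror_probe is not None:
                dx = mirror_probe[0] - x
                dy = mirror_probe[1] - y
                if dx * dx + dy * dy <= zone_r2:
                    b = normalize_heading(deg(atan2(-dx, dy)) - heading)
                    probe_hit = abs(b) <= face_tol
            if chosen is not None or probe_hit:
                choice_made = True
                log.latency = t
                if chosen is None:
                    log.choice = Choice.NO_STIMULUS
                elif phase is Phase.PHOTOTAXIS_TEST:
                    log.choice = Choice.RED
                elif chosen.role is StimulusRole.CS_PLUS:
                    log.choice = Choice.CS_PLUS
                else:
                    log.choice = Choice.CS_MINUS
                if lock_and_reinforce:
                    lam = (
                        protocol.lambda_plus
                        if log.choice is Choice.CS_PLUS
                        else protocol.lambda_minus
                    )
                    if chosen is not None:
                        log.reinforcement = lam
                        agent.reinforce(chosen.color_name, lam, arena.background)
                    n_lock = int(round(protocol.lock_duration / tick))
                    for j in range(1, n_lock + 1):
                        log.t.append(t + j * tick)
                        log.x.append(x)
                        log.y.append(y)
                        log.heading.append(heading)
                        log.locked.append(True)
                        log.fix_plus.append(fp)
                        log.fix_minus.append(fm)
                    return log
    return log


def run_trial(
    agent,
    arena: ArenaConfig,
    protocol: ProtocolConfig,
    rng: np.random.Generator,
    cuboids: Sequence[Cuboid],
    trial_index: int = 0,
) -> TrialLog:
    """One training trial: ends at the first choice (followed by the 8 s
    screen lock and a single reinforcement) or at the 60 s cap with NC."""
    return _run(
        agent,
        arena,
        protocol,
        rng,
        cuboids,
        Phase.TRAIN,
        trial_index,
        protocol.trial_cap,
        lock_and_reinforce=True,
    )


def run_test(
    agent,
    arena: ArenaConfig,
    protocol: ProtocolConfig,
    rng: np.random.Generator,
    cuboids: Sequence[Cuboid],
    trial_index: int = 0,
) -> TrialLog:
    """The non-reinforced test: fixed duration, first choice recorded,
    logging (with fixation flags) continues to the end."""
    return _run(
        agent,
        arena,
        protocol,
        rng,
        cuboids,
        Phase.TEST,
        trial_index,
        protocol.test_duration,
        lock_and_reinforce=False,
    )


def run_phototaxis_tests(
    agent,
    arena: ArenaConfig,
    stimulus: Stimulus,
    rng: np.random.Generator,
    n_tests: int = 4,
    test_duration: float = 60.0,
    inter_test: float = 10.0,
    side_sequence: Optional[Sequence[str]] = None,
    protocol: Optional[ProtocolConfig] = None,
) -> List[TrialLog]:
    """Four consecutive extinction tests against a single red cuboid.

    The empty side carries a mirror-image probe zone; entering it registers
    a NO_STIMULUS choice. ``side_sequence`` fixes the stimulus side per test
    ("left"/"right"); by default sides are drawn uniformly. The 10 s
    inter-test interval is bookkeeping only.
    """
    protocol = protocol or ProtocolConfig(test_duration=test_duration)
    logs: List[TrialLog] = []
    for i in range(n_tests):
        side = (
            side_sequence[i % len(side_sequence)]
            if side_sequence
            else ("left" if rng.integers(2) else "right")
        )
        sign = 1.0 if side == "left" else -1.0
        p = arena.start_pose
        center = _azimuth_point(p, sign * arena.stimulus_azimuth, arena.start_distance)
        mirror = _azimuth_point(p, -sign * arena.stimulus_azimuth, arena.start_distance)
        red = Cuboid(
            center=center,
            color_rgb=stimulus.rgb,
            irradiance=stimulus.irradiance,
            role=StimulusRole.PROBE,
            color_name=stimulus.name,
        )
        agent.reset()
        log = _run(
            agent,
            arena,
            protocol,
            rng,
            [red],
            Phase.PHOTOTAXIS_TEST,
            i,
            test_duration,
            lock_and_reinforce=False,
            mirror_probe=mirror,
        )
        log.cs_plus_side = side
        logs.append(log)
    return logs


def run_experiment(
    agent_factory: Callable[[], object],
    arena: ArenaConfig,
    protocol: ProtocolConfig,
    n_bees: int,
    seed: int,
    cs_colors: Tuple[str, str] = ("blue", "green"),
) -> ExperimentLog:
    """Simulate a cohort: per bee, a balanced random CS+ colour assignment,
    a fresh agent, ten training trials with the CS+ side re-randomised per
    trial, then the non-reinforced test. Each bee consumes an independent
    RNG substream, so runs are reproducible bee-by-bee from the seed."""
    if n_bees < 1:
        raise ValueError("need at least one bee")
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    if protocol.balanced_contingency:
        half = n_bees // 2
        assignment = [cs_colors[0]] * half + [cs_colors[1]] * (n_bees - half)
        master.shuffle(assignment)
    else:
        assignment = [cs_colors[master.integers(2)] for _ in range(n_bees)]

    bee_seeds = ss.spawn(n_bees)
    bees: List[BeeLog] = []
    for b in range(n_bees):
        rng = np.random.default_rng(bee_seeds[b])
        plus_name = assignment[b]
        minus_name = cs_colors[1] if plus_name == cs_colors[0] else cs_colors[0]
        agent = agent_factory()
        trials: List[TrialLog] = []
        for tr in range(protocol.n_trials):
            side = "left" if rng.integers(2) else "right"
            cuboids = make_stimulus_pair(
                arena, PALETTE[plus_name], PALETTE[minus_name], side
            )
            log = run_trial(agent, arena, protocol, rng, cuboids, trial_index=tr)
            log.cs_plus_side = side
            trials.append(log)
        side = "left" if rng.integers(2) else "right"
        cuboids = make_stimulus_pair(arena, PALETTE[plus_name], PALETTE[minus_name], side)
        test = run_test(agent, arena, protocol, rng, cuboids, trial_index=protocol.n_trials)
        test.cs_plus_side = side
        bees.append(
            BeeLog(
                bee_id=b,
                cs_plus_color=plus_name,
                cs_minus_color=minus_name,
                trials=trials,
                test=test,
                seed=int(bee_seeds[b].generate_state(1)[0] % (2**31)),
            )
        )
    return ExperimentLog(arena=arena, protocol=protocol, bees=bees, seed=seed)


def apply_exclusion(
    log: ExperimentLog, protocol: Optional[ProtocolConfig] = None
) -> Tuple[List[BeeLog], List[BeeLog]]:
    """Split a cohort into (kept, excluded): a bee is kept iff it made a
    choice (anything but NC) in at least ``min_choices_to_keep`` of its
    training trials."""
    protocol = protocol or log.protocol
    kept = [b for b in log.bees if b.n_choices >= protocol.min_choices_to_keep]
    excluded = [b for b in log.bees if b.n_choices < protocol.min_choices_to_keep]
    return kept, excluded
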