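"""Synthetic walking-bee agents.

Two generative agents stand in for real animals:

* :class:`PhototaxisAgent` — a correlated random walker whose steering is
  biased toward a single stimulus whenever that stimulus is bright enough to
  be detected. Used in the red-intensity phototaxis scenario.

* :class:`RWLearningAgent` — a Rescorla–Wagner learner. Each colour carries
  an associative strength V updated by V <- V + alpha*(lambda - V) at
  reinforcement. Steering aims at the cuboid with the highest utility
  (irradiance salience + V), scaled by an attention factor A in [0, 1] that
  expresses distraction by the frontal background; A also multiplies the
  effective learning rate, and steering noise grows as A falls. An optomotor
  term follows the retinal slip of the wall grating, and a ventral-flow
  factor slows walking when the treadmill ball is textured.

These agents make no claim of biological realism beyond reproducing the
qualitative effect pattern of the paradigm: graded phototactic attraction,
learning that degrades under frontal background motion, turning that follows
a rotating grating, and slower/shorter walks under ventral optic flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, NamedTuple, Tuple

import numpy as np

from .geometry import Background
from .treadmill import MotionDelta

__all__ = [
    "CuboidView",
    "Percept",
    "AgentParams",
    "rw_update",
    "ScriptedAgent",
    "PhototaxisAgent",
    "RWLearningAgent",
    "learning_params_for_condition",
    "phototaxis_params",
    "PHOTOTAXIS_CALIBRATION",
    "DEFAULT_DISTRACTION",
]


class CuboidView(NamedTuple):
    """One stimulus as perceived this tick: signed bearing (deg, leftward
    positive), irradiance (uW/cm^2), colour label and protocol role."""

    bearing: float
    irradiance: float
    color: str
    role: str


class Percept(NamedTuple):
    """Everything the engine shows an agent on one tick."""

    views: Tuple[CuboidView, ...]
    background: Background
    grating_slip: float  # retinal phase change of the grating this tick, deg
    ventral_flow: bool
    tick: float


#: shipped attention factors per frontal background condition; the ordering
#: (transparent > gaze-fixed > closed-loop ~ rotating) is the package default.
DEFAULT_DISTRACTION: Dict[Background, float] = {
    Background.TRANSPARENT: 1.0,
    Background.GRATING_GAZE_FIXED: 0.7,
    Background.GRATING_CLOSED_LOOP: 0.3,
    Background.GRATING_ROTATING: 0.3,
}

_MIN_ATTENTION = 0.05  # floor for the 1/sqrt(A) noise inflation


@dataclass(frozen=True)
class AgentParams:
    """Tunable parameters of the synthetic bees.

    Speeds are cm/s, angles degrees. ``heading_noise_sd`` is the standard
    deviation of the per-tick Gaussian heading kick. ``attraction_gain`` is
    the maximal deterministic heading change per tick toward the steering
    target. ``detection_threshold`` sits between the dimmest red (13
    uW/cm^2, undetectable) and the mid red (140 uW/cm^2, detectable).
    """

    base_speed: float = 1.5
    speed_noise_sd: float = 0.75
    heading_noise_sd: float = 5.0
    attraction_gain: float = 4.0
    detection_threshold: float = 50.0
    alpha: float = 0.15
    v0: float = 0.0
    salience_gain: float = 0.50
    distraction: Dict[Background, float] = field(
        default_factory=lambda: dict(DEFAULT_DISTRACTION)
    )
    optomotor_gain: float = 0.0
    ventral_speed_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.base_speed < 0 or self.speed_noise_sd < 0:
            raise ValueError("speeds must be non-negative")
        for a in self.distraction.values():
            if not 0.0 <= a <= 1.0:
                raise ValueError("attention factors must lie in [0, 1]")


def rw_update(v: float, lam: float, alpha: float) -> float:
    """One Rescorla–Wagner step: V <- V + alpha*(lambda - V).

    A contraction toward lambda: |V' - lambda| = (1 - alpha)|V - lambda|.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return v + alpha * (lam - v)


class ScriptedAgent:
    """Deterministic agent replaying a fixed per-tick motion or a callable
    ``(tick_index, percept) -> MotionDelta``; used as a test probe."""

    def __init__(self, motion: MotionDelta | Callable[[int, Percept], MotionDelta]):
        self._motion = motion
        self._k = 0

    def step(self, percept: Percept, rng: np.random.Generator) -> MotionDelta:
        m = self._motion
        delta = m(self._k, percept) if callable(m) else m
        self._k += 1
        return delta

    def reinforce(self, color: str, lam: float, background: Background) -> None:
        pass

    def reset(self) -> None:
        self._k = 0


class _NoisyWalker:
    def __init__(self, params: AgentParams):
        self.params = params

    def _speed(self, rng: np.random.Generator) -> float:
        p = self.params
        s = p.base_speed + (rng.normal(0.0, p.speed_noise_sd) if p.speed_noise_sd else 0.0)
        return p.ventral_speed_factor * max(0.0, s)


class PhototaxisAgent(_NoisyWalker):
    """Single-stimulus phototactic walker.

    Below ``detection_threshold`` the stimulus exerts no pull and the agent
    performs an unbiased correlated random walk; above it, steering is
    biased toward the stimulus by ``attraction_gain * sin(bearing)`` per
    tick, with Gaussian heading noise throughout.
    """

    def step(self, percept: Percept, rng: np.random.Generator) -> MotionDelta:
        p = self.params
        drive = 0.0
        if percept.views:
            view = percept.views[0]
            if view.irradiance >= p.detection_threshold:
                drive = p.attraction_gain * math.sin(math.radians(view.bearing))
        dheading = drive
        if p.heading_noise_sd:
            dheading += rng.normal(0.0, p.heading_noise_sd)
        forward = self._speed(rng) * percept.tick
        return MotionDelta(forward, 0.0, dheading)

    def reinforce(self, color: str, lam: float, background: Background) -> None:
        pass

    def reset(self) -> None:
        pass


class RWLearningAgent(_NoisyWalker):
    """Rescorla–Wagner learner with attention, optomotor and ventral terms.

    Per tick the utility of each visible cuboid is
    ``salience_gain * log10(irradiance) + V[colour]``; the agent steers
    toward the argmax with drive ``A * attraction_gain * sin(bearing)``,
    plus ``optomotor_gain`` times the grating's retinal slip, plus Gaussian
    noise with standard deviation ``heading_noise_sd / sqrt(A)``. At
    reinforcement the chosen colour's V moves toward lambda with effective
    learning rate ``A * alpha``.
    """

    def __init__(self, params: AgentParams):
        super().__init__(params)
        self.v: Dict[str, float] = {}

    def _value(self, color: str) -> float:
        return self.v.get(color, self.params.v0)

    def _attention(self, background: Background) -> float:
        return self.params.distraction.get(background, 1.0)

    def step(self, percept: Percept, rng: np.random.Generator) -> MotionDelta:
        p = self.params
        attention = self._attention(percept.background)
        dheading = p.optomotor_gain * percept.grating_slip
        if percept.views:
            best = max(
                percept.views,
                key=lambda v: p.salience_gain * math.log10(max(v.irradiance, 1e-9))
                + self._value(v.color),
            )
            dheading += attention * p.attraction_gain * math.sin(math.radians(best.bearing))
        if p.heading_noise_sd:
            sd = p.heading_noise_sd / math.sqrt(max(attention, _MIN_ATTENTION))
            dheading += rng.normal(0.0, sd)
        forward = self._speed(rng) * percept.tick
        return MotionDelta(forward, 0.0, dheading)

    def reinforce(self, color: str, lam: float, background: Background) -> None:
        """Apply one associative update for the chosen colour; the attention
        factor of the current background scales the learning rate."""
        alpha_eff = self._attention(background) * self.params.alpha
        self.v[color] = rw_update(self._value(color), lam, alpha_eff)

    def reset(self) -> None:
        self.v = {}


#: Phototaxis steering calibration per red intensity, frozen after a one-off
#: grid search against the published choice proportions (Red 100: ~52.5%
#: red choices over pooled tests). All three intensities share one
#: parameterisation; behaviour differs only through the detection threshold.
PHOTOTAXIS_CALIBRATION: Dict[str, float] = {
    "attraction_gain": 0.291,
    "heading_noise_sd": 5.0,
    "base_speed": 1.5,
    "speed_noise_sd": 0.75,
}


def phototaxis_params(**overrides) -> AgentParams:
    """Shipped phototaxis-scenario parameters (see PHOTOTAXIS_CALIBRATION)."""
    kwargs = dict(PHOTOTAXIS_CALIBRATION)
    kwargs.update(overrides)
    return AgentParams(**kwargs)


def learning_params_for_condition(
    background: Background,
    ventral_flow: bool = False,
    rotating_optomotor_gain: float = 0.02,
    **overrides,
) -> AgentParams:
    """Shipped learning-agent parameters for one experimental condition.

    The optomotor gain is non-zero only under the rotating grating, and the
    ventral speed factor drops to 0.8 when the treadmill ball is textured.
    """
    kwargs = dict(
        optomotor_gain=rotating_optomotor_gain
        if background is Background.GRATING_ROTATING
        else 0.0,
        ventral_speed_factor=0.8 if ventral_flow else 1.0,
    )
    kwargs.update(overrides)
    return AgentParams(**kwargs)
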