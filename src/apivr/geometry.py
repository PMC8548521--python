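"""Planar geometry of the virtual arena.

The arena is modelled in two dimensions: an agent has a position (cm) and a
heading (degrees) in a world frame whose origin is the trial start point.
Heading 0 points at the centre of the semicircular projection screen (the +y
direction); positive headings turn counterclockwise, i.e. to the agent's
left, which lies toward -x. All public angles are degrees; internals use
radians where convenient.

Stimuli are vertical cuboids whose height is irrelevant to every choice and
fixation criterion, so only their footprint centre and width enter the
computations. The four frontal-background conditions differ only in how the
wall grating's angular phase evolves; that phase is what downstream agents
consume as retinal slip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple

__all__ = [
    "Background",
    "StimulusRole",
    "Pose",
    "Cuboid",
    "ArenaConfig",
    "normalize_heading",
    "horizontal_visual_angle",
    "place_stimuli",
    "bearing_to",
    "in_choice_zone",
    "is_fixating",
    "fixation_half_angle",
    "grating_angular_speed",
    "grating_retinal_phase",
]


class Background(str, Enum):
    """Frontal wall condition of the virtual arena."""

    TRANSPARENT = "transparent"
    #: grating anchored to the world; apparent motion follows the agent's yaw
    GRATING_CLOSED_LOOP = "grating_closed_loop"
    #: grating servoed to the gaze; zero retinal slip by construction
    GRATING_GAZE_FIXED = "grating_gaze_fixed"
    #: grating revolving anticlockwise around the wall at constant speed
    GRATING_ROTATING = "grating_rotating"


class StimulusRole(str, Enum):
    CS_PLUS = "cs_plus"
    CS_MINUS = "cs_minus"
    PROBE = "probe"
    NONE = "none"


def normalize_heading(deg: float) -> float:
    """Wrap an angle in degrees into (-180, 180].

    Uses IEEE remainder so values already inside the interval pass through
    exactly (no precision loss near the boundaries).
    """
    h = math.remainder(deg, 360.0)
    return 180.0 if h == -180.0 else h


@dataclass(frozen=True)
class Pose:
    """Agent position (cm) and heading (deg, (-180, 180], leftward positive)."""

    x: float = 0.0
    y: float = 0.0
    heading: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "heading", normalize_heading(self.heading))


@dataclass(frozen=True)
class Cuboid:
    """Vertical cuboid stimulus; height is metadata in the planar engine."""

    center: Tuple[float, float]
    width: float = 5.0
    depth: float = 5.0
    height: float = 100.0
    color_rgb: Tuple[int, int, int] = (0, 0, 0)
    irradiance: float = 0.0
    role: StimulusRole = StimulusRole.NONE
    color_name: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("cuboid width must be positive")
        if self.irradiance < 0:
            raise ValueError("irradiance must be non-negative")


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry, background condition and timing of the virtual arena.

    Defaults reproduce the reference rig: stimuli start at azimuths +/-50 deg
    subtending 6.5 deg (hence the 44 cm start distance), a choice registers
    within 5 cm of a stimulus axis while facing it (the stimulus then subtends
    ~53 deg), fixation is scored against a +/-2.5 mm window at screen centre
    on a 9 cm screen, and the simulation ticks at 0.017 s.
    """

    start_pose: Pose = field(default_factory=Pose)
    stimulus_azimuth: float = 50.0
    start_distance: float = 44.0
    choice_axis_distance: float = 5.0
    facing_tolerance: float = 15.0
    screen_radius: float = 9.0
    fixation_halfwidth: float = 0.25
    wall_radius: float = 100.0
    grating_bar_angle: float = 6.0
    background: Background = Background.TRANSPARENT
    grating_speed: float = 12.0  # m/s along the wall, rotating condition only
    ventral_flow: bool = False
    tick: float = 0.017

    def __post_init__(self) -> None:
        if self.tick <= 0:
            raise ValueError("tick must be positive")
        if not self.start_distance > self.choice_axis_distance:
            raise ValueError("start_distance must exceed choice_axis_distance")
        if self.grating_bar_angle <= 0 or 360.0 % self.grating_bar_angle != 0:
            raise ValueError("grating_bar_angle must divide 360 evenly")


def horizontal_visual_angle(width: float, axis_distance: float) -> float:
    """Angle (deg) subtended horizontally by a flat face of ``width`` cm seen
    from ``axis_distance`` cm away.

    At the 44 cm start distance a 5 cm cuboid subtends ~6.5 deg; on the 5 cm
    choice boundary it subtends ~53 deg.
    """
    if width <= 0 or axis_distance <= 0:
        raise ValueError("width and axis_distance must be positive")
    return math.degrees(2.0 * math.atan(width / (2.0 * axis_distance)))


def place_stimuli(config: ArenaConfig) -> Tuple[Cuboid, Cuboid]:
    """Return the (left, right) cuboids at +/-stimulus_azimuth deg from the
    start heading, ``start_distance`` cm from the start position.

    Roles and colours are assigned by the protocol layer; here both cuboids
    are role NONE. Left is the positive-bearing (negative-x) side.
    """
    p = config.start_pose
    left = Cuboid(center=_azimuth_point(p, config.stimulus_azimuth, config.start_distance))
    right = Cuboid(center=_azimuth_point(p, -config.stimulus_azimuth, config.start_distance))
    return left, right


def _azimuth_point(pose: Pose, bearing_deg: float, distance: float) -> Tuple[float, float]:
    """World point at a signed bearing (leftward positive) and distance from a pose."""
    a = math.radians(pose.heading + bearing_deg)
    return (pose.x - distance * math.sin(a), pose.y + distance * math.cos(a))


def bearing_to(pose: Pose, point: Tuple[float, float]) -> float:
    """Signed angle (deg) from the heading to the line of sight toward ``point``,
    in (-180, 180], positive to the agent's left."""
    dx = point[0] - pose.x
    dy = point[1] - pose.y
    if dx == 0.0 and dy == 0.0:
        raise ValueError("bearing undefined for a coincident point")
    # world bearing of the line of sight, measured like heading (0 = +y, left = -x)
    sight = math.degrees(math.atan2(-dx, dy))
    return normalize_heading(sight - pose.heading)


def in_choice_zone(pose: Pose, cuboid: Cuboid, config: ArenaConfig) -> bool:
    """A choice registers when the agent is within ``choice_axis_distance`` cm
    of the cuboid's vertical axis and faces its centre within
    ``facing_tolerance`` degrees."""
    dx = cuboid.center[0] - pose.x
    dy = cuboid.center[1] - pose.y
    if dx * dx + dy * dy > config.choice_axis_distance ** 2:
        return False
    return abs(bearing_to(pose, cuboid.center)) <= config.facing_tolerance


def fixation_half_angle(config: ArenaConfig) -> float:
    """Half-angle (deg) of the screen-centre fixation window: the +/-2.5 mm
    window on a screen ``screen_radius`` cm away spans atan(0.25/9) ~ 1.59 deg."""
    return math.degrees(math.atan(config.fixation_halfwidth / config.screen_radius))


def is_fixating(pose: Pose, cuboid: Cuboid, config: ArenaConfig) -> bool:
    """Ray-cast fixation test: true iff the cuboid centre sits within the
    screen-centre window (closed boundary)."""
    return abs(bearing_to(pose, cuboid.center)) <= fixation_half_angle(config)


def grating_angular_speed(config: ArenaConfig) -> float:
    """Angular speed (deg/s, anticlockwise positive) of the rotating grating:
    the linear wall speed in m/s converted on the cylindrical wall radius."""
    omega_rad = config.grating_speed * 100.0 / config.wall_radius
    return math.degrees(omega_rad)


def grating_retinal_phase(
    config: ArenaConfig, pose: Pose, t: float, world_phase0: float = 0.0
) -> float:
    """Angular phase (deg) of the wall grating in the retinal (heading-centred)
    frame at time ``t``.

    * closed loop: the grating is world-anchored, phase = phase0 - heading;
      apparent motion arises purely from the agent's yaw.
    * gaze fixed: servoed to the gaze, phase is constant — zero retinal slip.
    * rotating: phase = phase0 + omega*t - heading with omega the anticlockwise
      wall rotation rate.
    """
    if config.background is Background.TRANSPARENT:
        raise ValueError("no grating in the transparent condition")
    if config.background is Background.GRATING_GAZE_FIXED:
        return normalize_heading(world_phase0)
    if config.background is Background.GRATING_CLOSED_LOOP:
        return normalize_heading(world_phase0 - pose.heading)
    return normalize_heading(world_phase0 + grating_angular_speed(config) * t - pose.heading)
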