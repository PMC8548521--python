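"""Spherical-treadmill kinematics.

A tethered insect walks stationary on an air-suspended ball; two optical
sensors aimed at the ball equator, 90 deg apart (+/-45 deg off the body
axis), each report a horizontal and a vertical surface displacement per
tick. The standard two-sensor trackball solution maps those four numbers to
the animal's intended motion: the mean horizontal displacement gives yaw
(ball moving left = animal turning right), and the two vertical
displacements combine through the +/-45 deg rotation into forward and
lateral translation (ball moving backward = animal stepping forward).

The inverse mapping is exact and is used to emit synthetic raw sensor logs.
"""

from __future__ import annotations

import math
from typing import NamedTuple

from .geometry import Pose, normalize_heading

__all__ = [
    "SensorReading",
    "BallSpec",
    "MotionDelta",
    "recommended_ball_mass",
    "sensors_to_motion",
    "motion_to_sensors",
    "integrate_pose",
]

_SQRT2 = math.sqrt(2.0)


class SensorReading(NamedTuple):
    """Surface displacement (cm per tick) seen by each sensor.

    h: horizontal (equatorial) component, positive when the ball surface
    moves toward the animal's left under the sensor; v: vertical component,
    positive when the surface moves downward past the sensor (ball rolling
    backward under a forward-stepping animal).
    """

    h1: float
    v1: float
    h2: float
    v2: float


class BallSpec(NamedTuple):
    """Treadmill ball: 50 mm Styrofoam sphere, 1.07 g, sensors at +/-45 deg.

    ``texture`` flags whether the ball surface provides ventral optic flow
    (checkered) or not (plain white); it has no kinematic effect.
    """

    diameter_mm: float = 50.0
    mass_g: float = 1.07
    sensor_azimuths: tuple = (45.0, -45.0)
    texture: str = "plain_white"  # or "checkered_7mm"

    @property
    def radius_cm(self) -> float:
        return self.diameter_mm / 20.0


class MotionDelta(NamedTuple):
    """Per-tick intended motion of the animal: forward/lateral translation
    (cm, leftward positive) and heading change (deg, leftward positive)."""

    forward: float
    lateral: float
    dheading: float


def recommended_ball_mass(animal_mass: float) -> float:
    """Recommended treadmill-sphere mass: 2.5x the animal's mass (g).

    A 0.09 g honey bee calls for a 0.23 g sphere (to two decimals).
    """
    if animal_mass <= 0:
        raise ValueError("animal mass must be positive")
    return 2.5 * animal_mass


def _check_spec(spec: BallSpec) -> None:
    a1, a2 = spec.sensor_azimuths
    if a1 == a2:
        raise ValueError("sensor azimuths must be distinct")
    if {abs(a1), abs(a2)} != {45.0}:
        raise ValueError("sensor model requires sensors at +/-45 deg from the body axis")
    if spec.diameter_mm <= 0:
        raise ValueError("ball diameter must be positive")


def sensors_to_motion(reading: SensorReading, spec: BallSpec = BallSpec()) -> MotionDelta:
    """Solve the two-sensor equatorial trackball model for the animal's motion."""
    _check_spec(spec)
    h1, v1, h2, v2 = reading
    forward = (v1 + v2) / _SQRT2
    lateral = (v1 - v2) / _SQRT2
    # ball surface moving left under the sensors = animal turning right
    dheading = -math.degrees(0.5 * (h1 + h2) / spec.radius_cm)
    return MotionDelta(forward, lateral, dheading)


def motion_to_sensors(delta: MotionDelta, spec: BallSpec = BallSpec()) -> SensorReading:
    """Exact inverse of :func:`sensors_to_motion`."""
    _check_spec(spec)
    v1 = (delta.forward + delta.lateral) / _SQRT2
    v2 = (delta.forward - delta.lateral) / _SQRT2
    h = -math.radians(delta.dheading) * spec.radius_cm
    return SensorReading(h, v1, h, v2)


def integrate_pose(pose: Pose, delta: MotionDelta) -> Pose:
    """Apply a per-tick motion: rotate first, then translate in the new
    heading frame (the tick is short, so the ordering matters only at
    second order in the step size)."""
    heading = normalize_heading(pose.heading + delta.dheading)
    a = math.radians(heading)
    sin_a, cos_a = math.sin(a), math.cos(a)
    # heading unit vector (-sin, cos); its leftward normal (-cos, -sin)
    x = pose.x - delta.forward * sin_a - delta.lateral * cos_a
    y = pose.y + delta.forward * cos_a - delta.lateral * sin_a
    return Pose(x, y, heading)
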