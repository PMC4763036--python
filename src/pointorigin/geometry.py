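"""Outbound-path kinematics and strategy geometry for the point-to-origin task.

The observer is carried along a two-segment excursion: a straight approach,
a single yaw turn, and a second straight segment, after which they indicate
the egocentric quadrant containing the origin.  Four hypothesised response
strategies (turner, non-turner, non-mover, spinner) each predict a distinct
quadrant for any turn magnitude below 135 degrees.

Conventions
-----------
Bird's-eye right-handed frame: the start pose faces +z, +x points right,
headings are measured clockwise from +z in degrees, so left turns carry a
negative turn angle.  All bearings are normalised to (-180, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.special import fresnel

from .errors import DegenerateGeometryError, InvalidParameterError

__all__ = [
    "PathSpec",
    "Pose",
    "Quadrant",
    "Strategy",
    "DEFAULT_TRIAL_PLAN",
    "trial_specs",
    "turn_duration",
    "simulate_trajectory",
    "end_pose",
    "homing_bearing",
    "predicted_quadrant",
    "normalize_angle",
    "quadrant_of_bearing",
]

#: Signed turn angles (degrees) of the four trials: 60 left, 90 right,
#: 90 right, 60 left.
DEFAULT_TRIAL_PLAN: tuple[float, ...] = (-60.0, 90.0, 90.0, -60.0)


class Quadrant(str, Enum):
    """Egocentric answer quadrant, encoded as in the cohort files."""

    FRONT_LEFT = "FL"
    FRONT_RIGHT = "FR"
    BACK_LEFT = "BL"
    BACK_RIGHT = "BR"


class Strategy(str, Enum):
    """Hypothesised per-trial response strategy."""

    TURNER = "turner"
    NON_TURNER = "non-turner"
    NON_MOVER = "non-mover"
    SPINNER = "spinner"


@dataclass(frozen=True)
class PathSpec:
    """Kinematic recipe for one outbound trial.

    Parameters
    ----------
    turn_angle : float
        Signed turn angle in degrees; positive is rightward (clockwise).
    lin_accel : float
        Linear acceleration of the first phase, m/s^2.
    cruise_speed : float
        Constant translational speed, m/s; must equal
        ``lin_accel * t_accel1``.
    ang_accel : float
        Constant angular acceleration magnitude of the symmetric
        accelerate/decelerate turn, deg/s^2.
    t_accel1, t_const1, t_const2, t_decel2 : float
        Durations in seconds of the linear-acceleration phase, the first
        cruise, the second cruise, and the final linear deceleration.
    """

    turn_angle: float
    lin_accel: float = 10.0
    cruise_speed: float = 10.0
    ang_accel: float = 15.0
    t_accel1: float = 1.0
    t_const1: float = 2.0
    t_const2: float = 3.0
    t_decel2: float = 1.0

    def __post_init__(self) -> None:
        if self.lin_accel <= 0 or self.cruise_speed <= 0 or self.ang_accel <= 0:
            raise InvalidParameterError(
                "lin_accel, cruise_speed and ang_accel must be positive"
            )
        for name in ("t_accel1", "t_const1", "t_const2", "t_decel2"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if not math.isclose(
            self.cruise_speed, self.lin_accel * self.t_accel1, rel_tol=1e-9
        ):
            raise InvalidParameterError(
                "cruise_speed must equal lin_accel * t_accel1 "
                "(the acceleration phase ends at cruise speed)"
            )
        if abs(self.turn_angle) >= 360.0:
            raise InvalidParameterError("|turn_angle| must be below 360 degrees")

    @property
    def turn_time(self) -> float:
        return turn_duration(self.turn_angle, self.ang_accel)

    @property
    def total_time(self) -> float:
        return (
            self.t_accel1
            + self.t_const1
            + self.turn_time
            + self.t_const2
            + self.t_decel2
        )

    def mirrored(self) -> "PathSpec":
        """The left/right mirror image of this path."""
        return replace(self, turn_angle=-self.turn_angle)

    @classmethod
    def from_file(cls, path) -> "PathSpec":
        """Load a path specification from a JSON or YAML mapping."""
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls(**data)

    def to_file(self, path) -> None:
        """Write the path specification as JSON (YAML-compatible)."""
        import dataclasses
        import json

        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2)


@dataclass(frozen=True)
class Pose:
    """Position and heading on the ground plane.

    ``x`` is rightward displacement (m), ``z`` displacement along the
    initial facing direction (m), ``heading`` in degrees clockwise from the
    initial facing, normalised to (-180, 180].
    """

    x: float
    z: float
    heading: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "heading", normalize_angle(self.heading))


def normalize_angle(angle: float) -> float:
    """Map an angle in degrees to the half-open interval (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def turn_duration(turn_angle: float, ang_accel: float) -> float:
    """Duration of a symmetric accelerate/decelerate turn covering the angle.

    The turn ramps angular velocity linearly up for half the duration and
    back down for the other half at constant angular acceleration, giving
    ``T = 2 * sqrt(|turn_angle| / ang_accel)``.

    >>> turn_duration(60, 15)
    4.0
    """
    if ang_accel <= 0:
        raise InvalidParameterError("ang_accel must be positive")
    return 2.0 * math.sqrt(abs(turn_angle) / ang_accel)


def _heading_at(spec: PathSpec, tau: np.ndarray) -> np.ndarray:
    """Heading in degrees at time ``tau`` after turn onset (vectorised)."""
    T = spec.turn_time
    if T == 0.0:
        return np.zeros_like(tau)
    s = math.copysign(1.0, spec.turn_angle)
    half = T / 2.0
    mag = np.where(
        tau <= half,
        0.5 * spec.ang_accel * tau**2,
        abs(spec.turn_angle) - 0.5 * spec.ang_accel * (T - tau) ** 2,
    )
    return s * np.clip(mag, 0.0, abs(spec.turn_angle))


def simulate_trajectory(spec: PathSpec, dt: float = 1e-3) -> pd.DataFrame:
    """Integrate the five-phase trajectory on a fixed time grid.

    Phases: linear acceleration, cruise, turn (triangular angular-velocity
    profile at constant translational speed), cruise, linear deceleration.

    Returns a DataFrame with columns ``time, x, z, heading`` (seconds,
    metres, metres, degrees).  Speed and heading are evaluated in closed
    form at every sample; positions are trapezoid-integrated, so the path
    length matches the analytic phase distances to O(dt^2).
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    t1 = spec.t_accel1
    t2 = t1 + spec.t_const1
    t3 = t2 + spec.turn_time
    t4 = t3 + spec.t_const2
    t5 = t4 + spec.t_decel2

    grid = np.unique(
        np.concatenate(
            [np.arange(0.0, t5, dt), np.array([t1, t2, t3, t4, t5])]
        )
    )
    speed = np.where(
        grid < t1,
        spec.lin_accel * grid,
        np.where(
            grid <= t4,
            spec.cruise_speed,
            spec.cruise_speed * np.clip((t5 - grid) / max(spec.t_decel2, dt), 0, 1)
            if spec.t_decel2 > 0
            else 0.0,
        ),
    )
    in_turn = (grid >= t2) & (grid <= t3)
    heading = np.zeros_like(grid)
    heading[in_turn] = _heading_at(spec, grid[in_turn] - t2)
    heading[grid > t3] = spec.turn_angle

    h_rad = np.radians(heading)
    x = cumulative_trapezoid(speed * np.sin(h_rad), grid, initial=0.0)
    z = cumulative_trapezoid(speed * np.cos(h_rad), grid, initial=0.0)
    heading = np.vectorize(normalize_angle)(heading)
    return pd.DataFrame({"time": grid, "x": x, "z": z, "heading": heading})


def _fresnel_cs(x: float, a_r: float) -> tuple[float, float]:
    """(int_0^x cos(a_r t^2) dt, int_0^x sin(a_r t^2) dt) via Fresnel integrals."""
    k = math.sqrt(math.pi / (2.0 * a_r))
    s, c = fresnel(x / k)
    return k * c, k * s


def end_pose(spec: PathSpec) -> Pose:
    """Closed-form end pose of the trajectory (the dt -> 0 limit).

    The straight phases are elementary; the clothoid-like turn phases are
    evaluated with Fresnel integrals.
    """
    d1 = 0.5 * spec.lin_accel * spec.t_accel1**2 + spec.cruise_speed * spec.t_const1
    d2 = spec.cruise_speed * spec.t_const2 + 0.5 * spec.cruise_speed * spec.t_decel2
    x, z = 0.0, d1
    theta = spec.turn_angle
    if theta != 0.0:
        s = math.copysign(1.0, theta)
        theta_r = math.radians(abs(theta))
        a_r = math.radians(spec.ang_accel) / 2.0
        half = spec.turn_time / 2.0
        ci, si = _fresnel_cs(half, a_r)
        v = spec.cruise_speed
        # accelerating half: heading magnitude a_r * t^2
        x += s * v * si
        z += v * ci
        # decelerating half: heading magnitude theta_r - a_r * u^2, mirrored
        x += s * v * (math.sin(theta_r) * ci - math.cos(theta_r) * si)
        z += v * (math.cos(theta_r) * ci + math.sin(theta_r) * si)
    th_r = math.radians(theta)
    x += d2 * math.sin(th_r)
    z += d2 * math.cos(th_r)
    return Pose(x=x, z=z, heading=theta)


def homing_bearing(end: Pose, reference_heading: float) -> float:
    """Signed egocentric bearing of the origin as seen from ``end``.

    The bearing of the vector from the end position back to the origin,
    expressed in a frame facing ``reference_heading``; positive is
    rightward, normalised to (-180, 180].
    """
    vx, vz = -end.x, -end.z
    if math.hypot(vx, vz) < 1e-12:
        raise DegenerateGeometryError("homing vector has zero length")
    world = math.degrees(math.atan2(vx, vz))
    return normalize_angle(world - reference_heading)


def quadrant_of_bearing(bearing: float, tol: float = 1e-9) -> Quadrant:
    """Quadrant containing a bearing; boundaries are rejected, not broken."""
    b = normalize_angle(bearing)
    if min(abs(b), abs(abs(b) - 90.0), abs(abs(b) - 180.0)) < tol:
        raise DegenerateGeometryError(
            f"bearing {b!r} lies on a quadrant boundary"
        )
    front = abs(b) < 90.0
    left = b < 0.0
    if front:
        return Quadrant.FRONT_LEFT if left else Quadrant.FRONT_RIGHT
    return Quadrant.BACK_LEFT if left else Quadrant.BACK_RIGHT


def predicted_quadrant(strategy: Strategy, spec: PathSpec) -> Quadrant:
    """Quadrant in which ``strategy`` predicts the origin for this path.

    * turner: homing bearing relative to the final heading (updated frame);
    * non-turner: homing bearing relative to the initial heading (frame
      never rotated);
    * non-mover: bearing of the end point seen from the origin in the
      initial frame (pointing along the outbound displacement);
    * spinner: homing bearing in the final frame rotated by 180 degrees
      (as if having turned to face the path before answering).
    """
    strategy = Strategy(strategy)
    if not (0.0 < abs(spec.turn_angle) < 135.0):
        raise InvalidParameterError(
            "strategy-quadrant derivation requires |turn_angle| in (0, 135)"
        )
    end = end_pose(spec)
    if strategy is Strategy.TURNER:
        bearing = homing_bearing(end, end.heading)
    elif strategy is Strategy.NON_TURNER:
        bearing = homing_bearing(end, 0.0)
    elif strategy is Strategy.NON_MOVER:
        bearing = normalize_angle(math.degrees(math.atan2(end.x, end.z)))
    else:  # spinner
        bearing = homing_bearing(end, end.heading + 180.0)
    return quadrant_of_bearing(bearing)


@lru_cache(maxsize=None)
def strategy_quadrant_map(turn_angle: float) -> dict[Strategy, Quadrant]:
    """Strategy -> predicted quadrant for the default path with this angle."""
    spec = PathSpec(turn_angle=turn_angle)
    return {s: predicted_quadrant(s, spec) for s in Strategy}


def trial_specs(trial_plan=DEFAULT_TRIAL_PLAN) -> list[PathSpec]:
    """Default-kinematics PathSpec for each trial angle in the plan."""
    return [PathSpec(turn_angle=a) for a in trial_plan]
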