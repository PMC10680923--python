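"""Arena geometry and task logic: oval track and 8-maze.

The oval track has two 27 cm straights joined by 33 cm-diameter
semicircles (5 cm walls); the controlled path keeps 3 cm inside the outer
wall.  The 8-maze is two circular goal arms (36 cm outer / 20 cm inner
wall diameters, an 8 cm channel) overlapping in a triangular turning zone
where the mouse controls x, y, and yaw freely within position limits and
a yaw limit that ramps from ±20° to ±45° over the first 5 cm of
penetration.  A 1 cm × 3 cm transition zone upstream of the turning zone
ramps lateral and yaw velocities to zero so the mouse enters moving
purely forward.  In the goal arms the forward admittance output is
re-terminated onto the circular centerline (vector path correction) and a
trajectory servo holds the lateral offset and heading.

Task logic: alternating left/right cues (left: light left + one 4 s
5 kHz tone; right: light right + four 0.75 s ON / 0.25 s OFF 5 kHz
tones), an 8 µL reward on a correct choice, a 3 s air puff on a wrong
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from shapely.geometry import Point, Polygon

from .errors import ConfigurationError, ExotwinError

__all__ = [
    "Arc",
    "ArenaModel",
    "ZoneState",
    "TrialRecord",
    "oval_track",
    "eight_maze",
    "path_correct_velocity",
    "trajectory_servo_y_yaw",
    "turning_zone_step",
    "transition_zone_blend",
    "yaw_limit_at",
    "TaskEngine",
]


@dataclass(frozen=True)
class Arc:
    """Circular trajectory segment: center (m), radius (m), travel sense."""

    center: tuple[float, float]
    radius: float
    ccw: bool = True

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigurationError("arc radius must be > 0")


class Zone(str, Enum):
    ARM_LEFT = "arm_left"
    ARM_RIGHT = "arm_right"
    TURNING = "turning"
    TRANSITION = "transition"
    TREADMILL = "treadmill"


@dataclass
class ZoneState:
    """Where the mouse is and which limits apply there."""

    zone: Zone
    penetration_depth: float = 0.0  # m into the turning zone
    global_arm_angle: float = 0.0  # theta_a, rad
    yaw_error: float = 0.0  # theta_gamma, rad

    @property
    def yaw_limit(self) -> float:
        """Ramped yaw limit (rad) in the turning zone."""
        return yaw_limit_at(self.penetration_depth)


def yaw_limit_at(penetration_depth: float) -> float:
    """Turning-zone yaw limit: ±20° at entry scaling linearly to ±45° at
    5 cm penetration, constant beyond."""
    frac = np.clip(penetration_depth / 0.05, 0.0, 1.0)
    return np.deg2rad(20.0 + 25.0 * frac)


@dataclass
class ArenaModel:
    """Geometry + zones of one arena."""

    kind: str  # "oval" | "eightmaze"
    centerline_arcs: dict[str, Arc]
    wall_polylines: dict[str, np.ndarray] = field(default_factory=dict)
    turning_polygon: Polygon | None = None
    transition_length: float = 0.03
    transition_width: float = 0.01
    channel_width: float | None = None
    wall_height: float = 0.05
    path_length: float | None = None  # linearized path length (m)

    def zone_at(self, position) -> ZoneState:
        x, y = float(position[0]), float(position[1])
        if self.turning_polygon is not None and self.turning_polygon.covers(Point(x, y)):
            entry_x = self.turning_polygon.bounds[0]
            return ZoneState(Zone.TURNING, penetration_depth=x - entry_x)
        if self.kind == "eightmaze":
            if -self.transition_length <= x <= 0 and abs(y) <= self.transition_width / 2:
                return ZoneState(Zone.TRANSITION)
            zone = Zone.ARM_LEFT if y >= 0 else Zone.ARM_RIGHT
            return ZoneState(zone)
        return ZoneState(Zone.ARM_LEFT)


def oval_track() -> ArenaModel:
    """Linear oval: 27 cm straights, 33 cm-diameter semicircle ends, path
    3 cm inside the outer wall (semicircle path radius 13.5 cm)."""
    r_path = 0.33 / 2 - 0.03
    half = 0.27 / 2
    arcs = {
        "end_pos": Arc(center=(half, 0.0), radius=r_path),
        "end_neg": Arc(center=(-half, 0.0), radius=r_path),
    }
    return ArenaModel(kind="oval", centerline_arcs=arcs, wall_height=0.05)


def eight_maze(
    turn_zone_depth: float = 0.10,
    turn_zone_exit_halfwidth: float = 0.08,
) -> ArenaModel:
    """8-maze: goal-arm circles of centerline radius 14 cm (midway between
    the 18 cm outer and 10 cm inner wall radii), overlapping at the origin
    where the triangular turning zone sits.

    The turning-zone triangle (narrow 1 cm entry matching the transition
    zone, widening to span both arm entrances) and door/beam positions
    are configuration values; the published drawings give only the wall
    diameters, so the defaults here are documented assumptions.
    """
    r_out, r_in = 0.36 / 2, 0.20 / 2
    r_center = (r_out + r_in) / 2
    arcs = {
        "arm_left": Arc(center=(0.0, r_center), radius=r_center, ccw=False),
        "arm_right": Arc(center=(0.0, -r_center), radius=r_center, ccw=True),
    }
    entry_hw = 0.005
    tri = Polygon(
        [
            (0.0, -entry_hw),
            (0.0, entry_hw),
            (turn_zone_depth, turn_zone_exit_halfwidth),
            (turn_zone_depth, -turn_zone_exit_halfwidth),
        ]
    )
    # per-arm circumference plus the turning-zone crossing
    path_length = 2 * np.pi * r_center + turn_zone_depth
    return ArenaModel(
        kind="eightmaze",
        centerline_arcs=arcs,
        turning_polygon=tri,
        channel_width=r_out - r_in,
        path_length=path_length,
    )


# ----------------------------------------------------------------------------
# Goal-arm trajectory control
# ----------------------------------------------------------------------------

def path_correct_velocity(position, velocity, arc: Arc, dt: float = 0.01) -> np.ndarray:
    """Re-terminate the admittance velocity vector onto the circular
    trajectory.

    The admittance output is tangent to the arc and would integrate off
    it; the corrected vector ends at the radial projection of the raw
    endpoint onto the arc, so the integrated position never drifts
    off-path.
    """
    p = np.asarray(position, float).reshape(2)
    v = np.asarray(velocity, float).reshape(2)
    c = np.asarray(arc.center, float)
    if np.allclose(v, 0):
        return np.zeros(2)
    end = p + v * dt
    rel = end - c
    dist = np.linalg.norm(rel)
    if dist < 1e-12:
        raise ExotwinError("path correction undefined: endpoint at arc center")
    corrected_end = c + arc.radius * rel / dist
    return (corrected_end - p) / dt


def _heading_error_sine(yaw: float, theta_a: float) -> float:
    """Sine of the heading error relative to the global arm angle.

    Formed from the cross product of the two heading vectors, so the
    correction is continuous everywhere — in particular across the ±π
    wrap, where a trigonometric angle difference would jump by 2π."""
    return float(np.sin(yaw - theta_a))


def trajectory_servo_y_yaw(
    position,
    yaw: float,
    arc: Arc,
    gains: tuple[float, float] = (5.0, 5.0),
) -> tuple[float, float]:
    """Lateral and yaw velocity corrections holding the mouse on the arm.

    The radial error is the offset from the arc centerline; the yaw
    correction is proportional to the *sine* of the heading error
    theta_gamma (heading relative to the local tangent, the global arm
    angle theta_a), computed in vector form so there is no angle-wrap
    discontinuity.  Corrections are signed to drive both errors to zero.
    """
    p = np.asarray(position, float).reshape(2)
    c = np.asarray(arc.center, float)
    rel = p - c
    r = np.linalg.norm(rel)
    if r < 1e-12:
        raise ExotwinError("servo undefined at arc center")
    radial_err = r - arc.radius
    ang = np.arctan2(rel[1], rel[0])
    theta_a = ang + (np.pi / 2 if arc.ccw else -np.pi / 2)
    # outward radial error -> inward lateral command (mouse frame: +y left)
    sign_in = -1.0 if arc.ccw else 1.0
    v_lat = sign_in * gains[0] * radial_err
    v_yaw = -gains[1] * _heading_error_sine(yaw, theta_a)
    return float(v_lat), float(v_yaw)


def turning_zone_step(
    position,
    proposed_step,
    yaw: float,
    zone: ZoneState,
    polygon: Polygon,
) -> tuple[np.ndarray, float]:
    """Clamp a proposed turning-zone step to the zone polygon and the
    ramped yaw limit.

    The step magnitude is scaled down (direction preserved) until the end
    position stays inside the boundary — the admittance output is
    limited, never teleported.  Yaw is clipped to ±limit.
    """
    if zone.zone is not Zone.TURNING:
        raise ExotwinError("turning_zone_step called outside the turning zone")
    p = np.asarray(position, float).reshape(2)
    step = np.asarray(proposed_step, float).reshape(2)
    if not polygon.covers(Point(*p)):
        raise ExotwinError("state machine bug: start position outside turning zone")
    end = p + step
    if not polygon.covers(Point(*end)):
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if polygon.covers(Point(*(p + mid * step))):
                lo = mid
            else:
                hi = mid
        step = lo * step
    limit = zone.yaw_limit
    return p + step, float(np.clip(yaw, -limit, limit))


def transition_zone_blend(velocities, progress: float, shape: str = "linear") -> np.ndarray:
    """Ramp lateral and yaw velocity to zero across the transition zone.

    ``progress`` is the fraction of the 3 cm zone traversed; the forward
    component passes through unchanged.  Linear ramp by default (the
    published description says only that the velocities "transitioned to
    0"); a cosine ramp is switchable.
    """
    if not 0.0 <= progress <= 1.0:
        raise ConfigurationError("progress must be in [0, 1]")
    v = np.asarray(velocities, float).reshape(3).copy()
    if shape == "linear":
        g = 1.0 - progress
    elif shape == "cosine":
        g = 0.5 * (1.0 + np.cos(np.pi * progress))
    else:
        raise ConfigurationError("shape must be linear|cosine")
    if progress >= 1.0:
        g = 0.0
    v[1] *= g
    v[2] *= g
    return v


# ----------------------------------------------------------------------------
# Task engine: cues, doors, rewards, air puffs, trial records
# ----------------------------------------------------------------------------

@dataclass
class TrialRecord:
    index: int
    cued: str  # "left" | "right"
    chosen: str | None = None
    correct: bool | None = None
    t_start: float = 0.0
    t_end: float | None = None
    voided: bool = False
    path: list = field(default_factory=list)
    events: list = field(default_factory=list)  # (t, name, value)


# cue specifications: (tone duration s, gap s, count)
CUE_TONES = {"left": (4.0, 0.0, 1), "right": (0.75, 0.25, 4)}
CUE_TONE_HZ = 5000.0
REWARD_UL = 8.0
AIR_PUFF_S = 3.0


class TaskEngine:
    """State machine scoring 8-maze trials from break-beam events.

    ``mode="decision"``: the cued direction alternates left/right; a
    correct choice triggers the reward event (8 µL marker), a wrong one a
    3 s air puff.  ``mode="turn_training"``: the training door forces the
    cued arm, every completed trial is correct.  An inconsistent beam
    sequence voids the trial with a warning in the log.
    """

    def __init__(self, mode: str = "decision", first_cue: str = "left"):
        if mode not in ("decision", "turn_training"):
            raise ConfigurationError("mode must be decision|turn_training")
        if first_cue not in ("left", "right"):
            raise ConfigurationError("first_cue must be left|right")
        self.mode = mode
        self.trials: list[TrialRecord] = []
        self.warnings: list[str] = []
        self._next_cue = first_cue
        self._active: TrialRecord | None = None

    @property
    def completed(self) -> list[TrialRecord]:
        return [tr for tr in self.trials if tr.t_end is not None and not tr.voided]

    def _cue_events(self, direction: str, t: float) -> list[tuple[float, str, float]]:
        dur, gap, count = CUE_TONES[direction]
        out = [(t, f"cue_light_{direction}", 1.0)]
        tt = t
        for _ in range(count):
            out.append((tt, "cue_tone_on", CUE_TONE_HZ))
            out.append((tt + dur, "cue_tone_off", 0.0))
            tt += dur + gap
        return out

    def step(self, t: float, beam: str | None) -> list[tuple[float, str, float]]:
        """Advance on one (possibly absent) break-beam event.

        Beam names: ``"goal_end_left"`` / ``"goal_end_right"`` (end-of-arm
        beam: starts a trial and fires the cue for the *next* decision) and
        ``"goal_start_left"`` / ``"goal_start_right"`` (beginning-of-arm
        beam: registers the choice and actuates the doors).
        """
        if beam is None:
            return []
        out: list[tuple[float, str, float]] = []
        if beam.startswith("goal_end"):
            if self._active is not None and self._active.t_end is None:
                self._active.voided = True
                msg = f"t={t:.2f}s: new cue before choice; trial {self._active.index} voided"
                self.warnings.append(msg)
            cued = self._next_cue
            rec = TrialRecord(index=len(self.trials), cued=cued, t_start=t)
            self.trials.append(rec)
            self._active = rec
            cue_evts = self._cue_events(cued, t)
            rec.events.extend(cue_evts)
            out.extend(cue_evts)
            if self.mode == "turn_training":
                out.append((t, f"training_door_{cued}", 1.0))
        elif beam.startswith("goal_start"):
            chosen = "left" if beam.endswith("left") else "right"
            rec = self._active
            if rec is None or rec.t_end is not None:
                self.warnings.append(f"t={t:.2f}s: choice beam with no active trial")
                return out
            rec.chosen = chosen
            rec.correct = chosen == rec.cued
            rec.t_end = t
            out.append((t, "door_close_opposite", 1.0))
            if rec.correct:
                out.append((t, "reward", REWARD_UL))
            else:
                out.append((t, "air_puff", AIR_PUFF_S))
            rec.events.extend(out[-1:])
            self._next_cue = "right" if rec.cued == "left" else "left"
            self._active = None
        else:
            self.warnings.append(f"t={t:.2f}s: unknown beam '{beam}'")
        return out

    def trial_table(self):
        """Trial table as records (trial, cued, chosen, correct, t_start, t_end)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "trial": tr.index,
                    "cued": tr.cued,
                    "chosen": tr.chosen,
                    "correct": tr.correct,
                    "t_start": tr.t_start,
                    "t_end": tr.t_end,
                    "voided": tr.voided,
                }
                for tr in self.trials
            ]
        )


# ----------------------------------------------------------------------------
# Linearized path coordinate (used by the neural encoding design matrix)
# ----------------------------------------------------------------------------

def linearize_eight_maze(arena: ArenaModel, position, chosen_arm: str) -> float:
    """Arc-length coordinate along entry -> turning zone -> chosen arm ->
    return, half-open per bin [start, end).

    Within the turning zone, progress is the x-penetration; in an arm it
    is the angle swept along that arm's circle from its junction with the
    turning-zone exit.
    """
    if arena.kind != "eightmaze":
        raise ConfigurationError("linearization defined for the 8-maze")
    depth = arena.turning_polygon.bounds[2] - arena.turning_polygon.bounds[0]
    x, y = float(position[0]), float(position[1])
    zs = arena.zone_at((x, y))
    if zs.zone is Zone.TURNING:
        return float(np.clip(zs.penetration_depth, 0.0, depth))
    arc = arena.centerline_arcs["arm_left" if chosen_arm == "left" else "arm_right"]
    c = np.asarray(arc.center)
    ang = np.arctan2(y - c[1], x - c[0])
    # angle of the arm's junction with the turning zone exit
    ang0 = np.arctan2(-c[1], depth - c[0])
    sweep = (ang - ang0) if arc.ccw else (ang0 - ang)
    sweep = float(np.mod(sweep, 2 * np.pi))
    return depth + sweep * arc.radius
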