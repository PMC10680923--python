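"""Discrete-time admittance force-feedback controller.

The mouse pushes on a 6-axis force sensor; the controller renders a
virtual mass-damper, F = m a + c v, on the mouse-relevant axes (forward x,
lateral y, yaw).  Each 10 ms cycle: the raw force is dead-banded to reject
sensor noise and slip-ring drift, rotated from the sensor frame into the
mouse's frame, fed through the admittance law to a target acceleration,
and double-integrated (explicit Euler at the cycle time) to a commanded
velocity and target position.  The commanded forward velocity saturates at
0.16 m/s, and arena modes may disable backward motion.  The inner
position/velocity loops of the real servo drives are abstracted as an
ideal first-order lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .session import SAMPLE_RATE, SessionLog, empty_frame

__all__ = [
    "AdmittanceParams",
    "ForceReading",
    "ControllerState",
    "apply_deadband",
    "force_to_mouse_frame",
    "admittance_step",
    "position_loop_step",
    "run_closed_loop",
]

AXES = ("x", "y", "yaw")


@dataclass(frozen=True)
class AdmittanceParams:
    """Virtual admittance and loop constants per axis (x, y, yaw).

    Masses in kg (kg·m² for yaw), damping in N·s/m (N·m·s/rad).  The
    published system shows its tuned mass/damping only graphically; the
    defaults here are plausible-tuned values consistent with the
    admittance-plane relation at the reported peak forces, velocities,
    and accelerations, and nothing that asserts published constants
    depends on them.  Dead-bands (25 mN in x and y, 0.3 mN·m in yaw),
    the 16 cm/s forward velocity limit, and the 10 ms cycle are the
    as-built constants.
    """

    virtual_mass: tuple[float, float, float] = (0.2, 0.2, 0.002)
    virtual_damping: tuple[float, float, float] = (0.6, 0.6, 0.006)
    deadband: tuple[float, float, float] = (0.025, 0.025, 3e-4)
    velocity_limit_forward: float = 0.16
    cycle_time: float = 0.01
    backward_disabled: bool = False
    deadband_mode: str = "subtract"  # or "passthrough"
    inner_loop_lag: float = 0.005

    def __post_init__(self):
        if any(m <= 0 for m in self.virtual_mass):
            raise ConfigurationError("virtual mass must be > 0 on every axis")
        if any(c < 0 for c in self.virtual_damping):
            raise ConfigurationError("virtual damping must be >= 0")
        if any(d < 0 for d in self.deadband):
            raise ConfigurationError("deadband must be >= 0")
        if self.cycle_time <= 0:
            raise ConfigurationError("cycle_time must be > 0")
        if self.deadband_mode not in ("subtract", "passthrough"):
            raise ConfigurationError("deadband_mode must be subtract|passthrough")


@dataclass
class ForceReading:
    """6-axis force/torque sample in the sensor frame."""

    force: np.ndarray
    torque: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self):
        self.force = np.asarray(self.force, float).reshape(3)
        self.torque = np.asarray(self.torque, float).reshape(3)
        if not (np.all(np.isfinite(self.force)) and np.all(np.isfinite(self.torque))):
            raise ConfigurationError("force reading must be finite")


@dataclass
class ControllerState:
    """Controller-side state on the mouse-relevant axes (x, y, yaw)."""

    pose: np.ndarray = field(default_factory=lambda: np.zeros(3))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    target_pose: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.pose = np.asarray(self.pose, float).reshape(3).copy()
        self.velocity = np.asarray(self.velocity, float).reshape(3).copy()
        self.target_pose = np.asarray(self.target_pose, float).reshape(3).copy()


def apply_deadband(reading: ForceReading, params: AdmittanceParams) -> np.ndarray:
    """Dead-band the mouse-relevant axis forces (fx, fy, yaw torque).

    Inside the closed band (|input| <= threshold) the output is exactly 0.
    Outside, the default subtracts the threshold, sign(F)(|F| - band),
    keeping the map continuous so no 25 mN step excites the loop; the
    raw-passthrough variant of an idealized dead-band is switchable.
    """
    raw = np.array([reading.force[0], reading.force[1], reading.torque[2]])
    band = np.asarray(params.deadband)
    inside = np.abs(raw) <= band
    if params.deadband_mode == "subtract":
        out = np.sign(raw) * (np.abs(raw) - band)
    else:
        out = raw.copy()
    out[inside] = 0.0
    return out


def force_to_mouse_frame(axis_forces, yaw: float) -> np.ndarray:
    """Rotate planar forces from the sensor frame into the mouse frame.

    The sensor rides on the yaw stage, so the transform is a planar
    rotation by -yaw of (fx, fy); the yaw torque is about the shared
    vertical axis and is unchanged.  An isometry on the planar force.
    """
    f = np.asarray(axis_forces, float).reshape(3)
    c, s = np.cos(-yaw), np.sin(-yaw)
    return np.array([c * f[0] - s * f[1], s * f[0] + c * f[1], f[2]])


def admittance_step(
    force_mouse_frame,
    state: ControllerState,
    params: AdmittanceParams,
    dt: float | None = None,
) -> ControllerState:
    """One discrete admittance update.

    Per axis: a = (F - c v)/m, v <- v + a dt (explicit Euler), the
    commanded forward velocity clipped to the 0.16 m/s limit (lower bound
    0 when the arena mode disables backward motion), and the target pose
    advanced by v dt.
    """
    dt = params.cycle_time if dt is None else dt
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    F = np.asarray(force_mouse_frame, float).reshape(3)
    m = np.asarray(params.virtual_mass)
    c = np.asarray(params.virtual_damping)
    a = (F - c * state.velocity) / m
    v = state.velocity + a * dt
    lim = params.velocity_limit_forward
    lo = 0.0 if params.backward_disabled else -lim
    v[0] = np.clip(v[0], lo, lim)
    return ControllerState(
        pose=state.pose,
        velocity=v,
        target_pose=state.target_pose + v * dt,
    )


@dataclass(frozen=True)
class PositionLoopGains:
    kp: float = 20.0
    ki: float = 0.0
    kd: float = 0.0


def position_loop_step(
    target_pose,
    actual_pose,
    gains: PositionLoopGains,
    dt: float,
    integrator: np.ndarray | None = None,
    prev_error: np.ndarray | None = None,
):
    """Position loop: pose error -> operational-space velocity command.

    Proportional(-integral-derivative) on the target/actual error; with an
    empty integrator a zero error commands zero velocity.  Returns
    (command, integrator, error) so callers can carry the loop state.
    """
    e = np.asarray(target_pose, float) - np.asarray(actual_pose, float)
    integ = (integrator if integrator is not None else np.zeros_like(e)) + e * dt
    deriv = np.zeros_like(e) if prev_error is None else (e - prev_error) / dt
    cmd = gains.kp * e + gains.ki * integ + gains.kd * deriv
    return cmd, integ, e


def run_closed_loop(
    arena,
    params: AdmittanceParams,
    mouse,
    duration: float,
    seed: int,
) -> SessionLog:
    """Simulate the mouse-robot loop at 100 samples/s and return the log.

    ``arena`` is None (open field), or an arena object exposing
    ``constrain(pose, v_cmd, dt) -> (v_cmd, zone)`` and optionally
    ``events(pose, t) -> str``; ``mouse`` is a
    :class:`~exotwin.mouse.VirtualMouse`.  Each cycle: mouse muscle force
    from intent vs. actual velocity, dead-band, frame transform,
    admittance step, arena constraints, then the robot abstraction (a
    first-order lag on commanded velocity) advances the actual pose.
    Deterministic for a fixed seed.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    dt = params.cycle_time
    n = int(round(duration * SAMPLE_RATE))
    intent = mouse.generate_intent(duration, seed=seed)
    if len(intent.v_forward) < n:
        raise ConfigurationError("virtual mouse produced too few intent samples")
    state = ControllerState()
    actual_v = np.zeros(3)
    pose = np.zeros(3)  # x, y (global), yaw
    lag = params.inner_loop_lag
    alpha = 1.0 - np.exp(-dt / lag) if lag > 0 else 1.0
    poses = np.zeros((n, 3))
    forces = np.zeros((n, 3))
    cmds = np.zeros((n, 3))
    zones = []
    events = []
    for k in range(n):
        v_int = np.array(
            [intent.v_forward[k], intent.v_lateral[k], intent.v_yaw[k]]
        )
        f_raw = mouse.muscle_force(v_int, actual_v)
        reading = ForceReading(
            force=[f_raw[0], f_raw[1], 0.0], torque=[0.0, 0.0, f_raw[2]], timestamp=k * dt
        )
        f_db = apply_deadband(reading, params)
        f_mouse = force_to_mouse_frame(f_db, 0.0)  # sensor co-rotates: already mouse frame
        state = ControllerState(pose=state.pose, velocity=actual_v, target_pose=state.target_pose)
        state = admittance_step(f_mouse, state, params, dt)
        v_cmd = state.velocity.copy()
        zone = "open"
        if arena is not None:
            v_cmd, zone = arena.constrain(pose, v_cmd, dt)
        actual_v = actual_v + alpha * (v_cmd - actual_v)
        yaw = pose[2]
        pose = pose + dt * np.array(
            [
                actual_v[0] * np.cos(yaw) - actual_v[1] * np.sin(yaw),
                actual_v[0] * np.sin(yaw) + actual_v[1] * np.cos(yaw),
                actual_v[2],
            ]
        )
        ev = ""
        if arena is not None and hasattr(arena, "events"):
            ev = arena.events(pose, k * dt)
        poses[k] = pose
        forces[k] = f_mouse
        cmds[k] = v_cmd
        zones.append(zone)
        events.append(ev)
    df = empty_frame(n, dt)
    df[["x_m", "y_m", "yaw_rad"]] = poses
    df[["fx_N", "fy_N", "tz_Nm"]] = forces
    df[["vcmd_x", "vcmd_y", "vcmd_yaw"]] = cmds
    df["zone"] = zones
    df["event"] = events
    return SessionLog(df)
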