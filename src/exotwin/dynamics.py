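"""Coupled inverse dynamics of the delta robot and goniometer with payload.

The linkage is reduced to a set of point masses whose positions are smooth
functions of the six joint coordinates q = (th1, th2, th3, pitch, roll, yaw):

* each proximal link (a uniform rod rotating about its base joint) is
  replaced by its exact two-point equivalent — 3m/4 at 2L/3 along the link
  plus m/4 at the stationary joint (which drops out of the dynamics);
* each distal link is split between its elbow end and its platform end
  (default split 0.5), the standard simplification in lumped delta models;
* the platform, the platform-end distal masses, and the goniometer links
  rigid with the platform are lumped at the platform center;
* the final goniometer link and the payload (headstage) are lumped at the
  virtual pivot, so goniometer motion reacts back on the delta platform
  as an additional wrench, coupling the two mechanisms.

Joint torques follow from d'Alembert's principle,
``tau = sum_k J_k^T m_k (a_k + g zhat)``, which is exact for point masses:
the energy balance ``sum tau_i qdot_i = dE/dt`` holds to the accuracy of
the one directional finite difference used for dJ/dt of the (implicit)
platform Jacobian.

Point masses carry no rotational inertia, so the yaw axis sees zero torque
in this model; the yaw motor is checked against its velocity limit only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, SingularityError
from .kinematics import (
    DeltaGeometry,
    GoniometerGeometry,
    JointConfig,
    _delta_jacobian,
    _pivot_direction,
    _pivot_direction_derivs,
    delta_fk,
)

__all__ = [
    "InertialParams",
    "TorqueBreakdown",
    "MotorSpec",
    "default_motors",
    "inverse_dynamics",
    "decompose_torques",
    "check_feasibility",
    "FeasibilityReport",
    "mechanism_energy",
]

_ZHAT = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class InertialParams:
    """Link and payload masses (kg).

    Link masses are documented estimates for the carbon-fiber arms and
    aluminium platform (the as-built values are not public); tests that
    assert published numbers must not depend on them.  The payload
    default covers the 1.0 kg electrophysiology / 1.5 kg imaging
    headstage range.
    """

    proximal_link_mass: float = 0.25
    distal_link_mass: float = 0.15
    platform_mass: float = 0.8
    goniometer_link_masses: tuple[float, float, float] = (0.5, 0.5, 0.5)
    payload_mass: float = 1.5
    gravity: float = 9.81
    distal_mass_split: float = 0.5

    def __post_init__(self):
        masses = (
            self.proximal_link_mass,
            self.distal_link_mass,
            self.platform_mass,
            *self.goniometer_link_masses,
            self.payload_mass,
        )
        if any(m < 0 for m in masses):
            raise ConfigurationError("masses must be >= 0")
        if not 0.0 <= self.distal_mass_split <= 1.0:
            raise ConfigurationError("distal_mass_split must be in [0, 1]")


@dataclass
class TorqueBreakdown:
    """Joint torques parsed into gravitational, velocity, and acceleration
    components; the three sum to the total identically by construction."""

    gravitational: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.gravitational + self.velocity + self.acceleration


@dataclass(frozen=True)
class MotorSpec:
    """Torque (N·m) and velocity (deg/s) limits for one joint."""

    torque_limit: float
    velocity_limit: float
    applies_to: int

    def __post_init__(self):
        if self.torque_limit <= 0 or self.velocity_limit <= 0:
            raise ConfigurationError("motor limits must be > 0")


def default_motors() -> list[MotorSpec]:
    """As-built servo limits: delta 30 N·m / 576 deg/s, goniometer
    4.8 N·m / 360 deg/s."""
    return [MotorSpec(30.0, 576.0, i) for i in range(3)] + [
        MotorSpec(4.8, 360.0, i) for i in range(3, 6)
    ]


# ----------------------------------------------------------------------------
# Point-mass bookkeeping
# ----------------------------------------------------------------------------

def _platform_group_mass(inertial: InertialParams) -> float:
    # platform + platform-end distal lumps + goniometer links rigid with it
    g1, g2, _ = inertial.goniometer_link_masses
    return (
        inertial.platform_mass
        + 3 * (1.0 - inertial.distal_mass_split) * inertial.distal_link_mass
        + g1
        + g2
    )


def _pivot_group_mass(inertial: InertialParams) -> float:
    return inertial.goniometer_link_masses[2] + inertial.payload_mass


def _arm_point(geom: DeltaGeometry, i: int, theta: float, radius: float) -> np.ndarray:
    u = geom.arm_units[i]
    return geom.r_fixed * u + radius * (np.cos(theta) * u + np.sin(theta) * _ZHAT)


def _arm_point_derivs(geom: DeltaGeometry, i: int, theta: float, radius: float):
    u = geom.arm_units[i]
    d1 = radius * (-np.sin(theta) * u + np.cos(theta) * _ZHAT)
    d2 = radius * (-np.cos(theta) * u - np.sin(theta) * _ZHAT)
    return d1, d2


def _platform_jacobian_dot(
    th: np.ndarray, thd: np.ndarray, geom: DeltaGeometry, h: float = 1e-6
) -> np.ndarray:
    """Directional derivative dJ/dt = sum_j dJ/dth_j thd_j by central difference."""
    nrm = np.linalg.norm(thd)
    if nrm == 0:
        return np.zeros((3, 3))
    step = h / nrm
    Jp = _delta_jacobian(th + step * thd, geom)
    Jm = _delta_jacobian(th - step * thd, geom)
    return (Jp - Jm) / (2.0 * step)


def inverse_dynamics(
    cfg: JointConfig,
    joint_rates,
    joint_accels,
    inertial: InertialParams,
    dg: DeltaGeometry | None = None,
    gg: GoniometerGeometry | None = None,
) -> np.ndarray:
    """Joint torques (6,) realizing the given joint rates and accelerations.

    Raises :class:`SingularityError` at delta fold singularities where the
    platform Jacobian does not exist.
    """
    dg = dg or DeltaGeometry()
    gg = gg or GoniometerGeometry()
    qd = np.asarray(joint_rates, float).reshape(6)
    qdd = np.asarray(joint_accels, float).reshape(6)
    th, thd, thdd = cfg.delta_angles, qd[:3], qdd[:3]
    pitch, roll = cfg.gonio_angles[0], cfg.gonio_angles[1]
    pd, rd = qd[3], qd[4]
    pdd, rdd = qdd[3], qdd[4]
    g_vec = inertial.gravity * _ZHAT  # torque integrand uses (a + g zhat)

    tau = np.zeros(6)

    # --- per-arm masses (proximal rod equivalent + elbow-end distal lump)
    Lp = dg.len_proximal
    arm_lumps = (
        (0.75 * inertial.proximal_link_mass, 2.0 * Lp / 3.0),
        (inertial.distal_mass_split * inertial.distal_link_mass, Lp),
    )
    for i in range(3):
        for m, radius in arm_lumps:
            if m == 0:
                continue
            d1, d2 = _arm_point_derivs(dg, i, th[i], radius)
            a = d2 * thd[i] ** 2 + d1 * thdd[i]
            tau[i] += m * d1 @ (a + g_vec)

    # --- platform-attached group (implicit function of delta joints)
    J = _delta_jacobian(th, dg)
    Jdot = _platform_jacobian_dot(th, thd, dg)
    a_plat = J @ thdd + Jdot @ thd
    m_plat = _platform_group_mass(inertial)
    if m_plat > 0:
        tau[:3] += J.T @ (m_plat * (a_plat + g_vec))

    # --- pivot group: platform motion + a4 swing from pitch/roll
    m_piv = _pivot_group_mass(inertial)
    if m_piv > 0:
        a4 = gg.pivot_extension_a4
        d_p, d_r, d_pp, d_pr, d_rr = _pivot_direction_derivs(pitch, roll)
        a_piv = a_plat + a4 * (
            d_p * pdd
            + d_r * rdd
            + d_pp * pd**2
            + 2.0 * d_pr * pd * rd
            + d_rr * rd**2
        )
        F = m_piv * (a_piv + g_vec)
        tau[:3] += J.T @ F
        tau[3] += a4 * d_p @ F
        tau[4] += a4 * d_r @ F
        # yaw column is zero: the extension line is the yaw axis
    return tau


def decompose_torques(
    cfg: JointConfig,
    joint_rates,
    joint_accels,
    inertial: InertialParams,
    dg: DeltaGeometry | None = None,
    gg: GoniometerGeometry | None = None,
) -> TorqueBreakdown:
    """Parse joint torques into gravitational, velocity, and acceleration
    components:  grav = ID(q,0,0);  vel = ID(q,qd,0) - grav;
    accel = ID(q,qd,qdd) - ID(q,qd,0)."""
    zeros = np.zeros(6)
    grav = inverse_dynamics(cfg, zeros, zeros, inertial, dg, gg)
    with_rates = inverse_dynamics(cfg, joint_rates, zeros, inertial, dg, gg)
    total = inverse_dynamics(cfg, joint_rates, joint_accels, inertial, dg, gg)
    return TorqueBreakdown(
        gravitational=grav,
        velocity=with_rates - grav,
        acceleration=total - with_rates,
    )


def mechanism_energy(
    cfg: JointConfig,
    joint_rates,
    inertial: InertialParams,
    dg: DeltaGeometry | None = None,
    gg: GoniometerGeometry | None = None,
) -> float:
    """Total mechanical energy (kinetic + gravitational potential) of the
    point-mass model; used by the energy-balance checks."""
    dg = dg or DeltaGeometry()
    gg = gg or GoniometerGeometry()
    qd = np.asarray(joint_rates, float).reshape(6)
    th, thd = cfg.delta_angles, qd[:3]
    pitch, roll = cfg.gonio_angles[0], cfg.gonio_angles[1]
    pd, rd = qd[3], qd[4]
    g = inertial.gravity
    E = 0.0
    Lp = dg.len_proximal
    arm_lumps = (
        (0.75 * inertial.proximal_link_mass, 2.0 * Lp / 3.0),
        (inertial.distal_mass_split * inertial.distal_link_mass, Lp),
    )
    for i in range(3):
        for m, radius in arm_lumps:
            if m == 0:
                continue
            x = _arm_point(dg, i, th[i], radius)
            d1, _ = _arm_point_derivs(dg, i, th[i], radius)
            v = d1 * thd[i]
            E += 0.5 * m * v @ v + m * g * x[2]
    plat = delta_fk(th, dg)
    J = _delta_jacobian(th, dg)
    v_plat = J @ thd
    m_plat = _platform_group_mass(inertial)
    E += 0.5 * m_plat * v_plat @ v_plat + m_plat * g * plat[2]
    m_piv = _pivot_group_mass(inertial)
    if m_piv > 0:
        a4 = gg.pivot_extension_a4
        d_p, d_r, *_ = _pivot_direction_derivs(pitch, roll)
        x_piv = plat - gg.offset_a1 * _ZHAT + a4 * _pivot_direction(pitch, roll)
        v_piv = v_plat + a4 * (d_p * pd + d_r * rd)
        E += 0.5 * m_piv * v_piv @ v_piv + m_piv * g * x_piv[2]
    return float(E)


# ----------------------------------------------------------------------------
# Feasibility against motor limits
# ----------------------------------------------------------------------------

@dataclass
class FeasibilityReport:
    """Per-joint peak torque/rate over a trajectory plus limit violations."""

    peak_torque: np.ndarray  # (6,) N·m
    peak_rate_deg_s: np.ndarray  # (6,)
    violations: list[dict] = field(default_factory=list)

    @property
    def feasible(self) -> bool:
        return len(self.violations) == 0


def check_feasibility(
    times,
    configs,
    rates,
    accels,
    inertial: InertialParams,
    motors: list[MotorSpec] | None = None,
    dg: DeltaGeometry | None = None,
    gg: GoniometerGeometry | None = None,
) -> FeasibilityReport:
    """Run inverse dynamics over a time-ordered trajectory and flag every
    sample whose torque or rate exceeds its motor limit.

    ``configs``, ``rates``, ``accels`` are (n, 6) arrays of joint
    positions, rates, and accelerations at uniform steps.
    """
    t = np.asarray(times, float)
    q = np.asarray(configs, float)
    qd = np.asarray(rates, float)
    qdd = np.asarray(accels, float)
    if t.size == 0:
        raise ConfigurationError("empty trajectory")
    if not (q.shape == qd.shape == qdd.shape and q.shape[1] == 6):
        raise ConfigurationError("trajectory arrays must be (n, 6) and congruent")
    if np.any(np.diff(t) <= 0):
        raise ConfigurationError("trajectory times must be strictly increasing")
    motors = motors if motors is not None else default_motors()
    limits = {m.applies_to: m for m in motors}
    peak_tau = np.zeros(6)
    peak_rate = np.zeros(6)
    violations: list[dict] = []
    for k in range(len(t)):
        cfg = JointConfig(delta_angles=q[k, :3], gonio_angles=q[k, 3:])
        tau = inverse_dynamics(cfg, qd[k], qdd[k], inertial, dg, gg)
        rate_deg = np.rad2deg(np.abs(qd[k]))
        peak_tau = np.maximum(peak_tau, np.abs(tau))
        peak_rate = np.maximum(peak_rate, rate_deg)
        for j in range(6):
            spec = limits.get(j)
            if spec is None:
                continue
            if abs(tau[j]) > spec.torque_limit:
                violations.append(
                    {"t": float(t[k]), "joint": j, "kind": "torque",
                     "value": float(abs(tau[j])), "limit": spec.torque_limit}
                )
            if rate_deg[j] > spec.velocity_limit:
                violations.append(
                    {"t": float(t[k]), "joint": j, "kind": "velocity",
                     "value": float(rate_deg[j]), "limit": spec.velocity_limit}
                )
    return FeasibilityReport(
        peak_torque=peak_tau, peak_rate_deg_s=peak_rate, violations=violations
    )
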