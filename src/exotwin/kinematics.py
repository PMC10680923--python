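"""Kinematics of the 3-arm delta robot and 3-axis goniometer.

The exoskeleton translates a mouse's head through a delta parallel robot
(pure x-y-z translation of its moving platform) and orients it through a
serial goniometer whose three axes intersect the virtual pivot point at
the head.  Coordinate frame: right handed, z up, robot mounted above the
arena with the arms reaching down, so the working volume sits at negative
z below the fixed platform.  Joint angle 0 places a proximal link
horizontal; positive angles rotate the link upward, which is why the
joint range [-90 deg, +45 deg] spans mostly-down postures.

Angles are radians everywhere in this module; degrees appear only in
configuration files.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError, OutOfWorkspaceError, SingularityError

__all__ = [
    "DeltaGeometry",
    "GoniometerGeometry",
    "JointConfig",
    "PivotPose",
    "JacobianMatrix",
    "WorkspaceReport",
    "load_geometry",
    "default_geometry",
    "delta_ik",
    "delta_fk",
    "pivot_pose",
    "jacobian",
    "workspace_extent",
]

# Arm azimuths of the three delta arms (3-fold symmetry).
_ARM_AZIMUTHS = np.deg2rad([90.0, 210.0, 330.0])

#: Condition number above which a Jacobian is flagged singular.
SINGULARITY_CONDITION_THRESHOLD = 1e6


@dataclass(frozen=True)
class DeltaGeometry:
    """Linkage dimensions of the delta robot.

    Defaults are the as-constructed dimensions: fixed platform radius
    0.19 m, moving platform radius 0.1 m, proximal link 0.34 m, distal
    link 0.656 m, joint limits [-90, +45] degrees.
    """

    r_fixed: float = 0.19
    r_moving: float = 0.1
    len_proximal: float = 0.34
    len_distal: float = 0.656
    joint_limit_low: float = -90.0  # deg
    joint_limit_high: float = 45.0  # deg

    def __post_init__(self):
        for name in ("r_fixed", "r_moving", "len_proximal", "len_distal"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.joint_limit_low >= self.joint_limit_high:
            raise ConfigurationError("joint_limit_low must be < joint_limit_high")

    @property
    def limits_rad(self) -> tuple[float, float]:
        return (np.deg2rad(self.joint_limit_low), np.deg2rad(self.joint_limit_high))

    def within_limits(self, angles) -> np.ndarray:
        """Per-arm boolean mask of angles inside the joint limits."""
        lo, hi = self.limits_rad
        a = np.asarray(angles, dtype=float)
        return (a >= lo - 1e-12) & (a <= hi + 1e-12)

    @property
    def arm_units(self) -> np.ndarray:
        """(3, 3) outward radial unit vectors of the three arm planes."""
        return np.stack(
            [np.cos(_ARM_AZIMUTHS), np.sin(_ARM_AZIMUTHS), np.zeros(3)], axis=1
        )


@dataclass(frozen=True)
class GoniometerGeometry:
    """Serial goniometer chain below the delta moving platform.

    ``offset_a1`` drops from the platform center to the common rotation
    point of the three axes; ``pivot_extension_a4`` extends from there to
    the virtual pivot at the mouse's head.  Rotation order is pitch
    (about the mouse's lateral axis), then roll, then yaw about the
    extension line itself, so pure yaw never translates the pivot —
    which is what permits infinite yaw rotation through a slip ring.
    """

    offset_a1: float = 0.1
    pivot_extension_a4: float = 0.25
    rotation_order: tuple[str, str, str] = ("pitch", "roll", "yaw")

    def __post_init__(self):
        if self.offset_a1 <= 0 or self.pivot_extension_a4 <= 0:
            raise ConfigurationError("goniometer offsets must be > 0")


@dataclass
class JointConfig:
    """Joint-space configuration: 3 delta angles + (pitch, roll, yaw), radians."""

    delta_angles: np.ndarray
    gonio_angles: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.delta_angles = np.asarray(self.delta_angles, dtype=float).reshape(3)
        self.gonio_angles = np.asarray(self.gonio_angles, dtype=float).reshape(3)

    def valid(self, geom: DeltaGeometry) -> bool:
        return bool(np.all(geom.within_limits(self.delta_angles)))

    @property
    def q(self) -> np.ndarray:
        return np.concatenate([self.delta_angles, self.gonio_angles])


@dataclass
class PivotPose:
    """6-DOF pose of the virtual pivot: position (m) and (pitch, roll, yaw) (rad).

    Yaw is an accumulated angle and is deliberately unbounded.
    """

    position: np.ndarray
    orientation: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.position)) and np.all(np.isfinite(self.orientation))):
            raise ConfigurationError("pose must be finite")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.position, self.orientation])


@dataclass
class JacobianMatrix:
    """6x6 map from joint rates (3 delta + 3 gonio) to pivot twist."""

    entries: np.ndarray
    singular: bool
    condition_number: float


def load_geometry(path) -> tuple[DeltaGeometry, GoniometerGeometry]:
    """Load delta + goniometer geometry from a flat key/value YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    dg = DeltaGeometry(
        r_fixed=raw["r_fixed_m"],
        r_moving=raw["r_moving_m"],
        len_proximal=raw["len_proximal_m"],
        len_distal=raw["len_distal_m"],
        joint_limit_low=raw["joint_limit_low_deg"],
        joint_limit_high=raw["joint_limit_high_deg"],
    )
    gg = GoniometerGeometry(
        offset_a1=raw["offset_a1_m"],
        pivot_extension_a4=raw["pivot_extension_a4_m"],
    )
    return dg, gg


def default_geometry() -> tuple[DeltaGeometry, GoniometerGeometry]:
    """Packaged as-constructed geometry (``exoskeleton_default``)."""
    ref = importlib.resources.files("exotwin.data") / "exoskeleton_default.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_geometry(path)


# ----------------------------------------------------------------------------
# Inverse / forward kinematics (geometric method)
# ----------------------------------------------------------------------------

def _arm_frame_components(p: np.ndarray, geom: DeltaGeometry, i: int):
    """Decompose the base-joint-to-platform-attachment vector for arm ``i``.

    Returns (radial, tangential, vertical) components in the arm plane.
    """
    u = geom.arm_units[i]
    t = np.array([-u[1], u[0], 0.0])  # z x u
    w = p + (geom.r_moving - geom.r_fixed) * u
    return float(w @ u), float(w @ t), float(w[2])


def delta_ik(platform_position, geom: DeltaGeometry) -> np.ndarray:
    """Joint angles reaching a platform position (geometric method).

    Of the two elbow solutions per arm the knuckles-out branch is chosen
    (elbow outboard of the platform, the branch a physical delta uses):
    deterministically the solution with the larger elbow radial
    coordinate ``L_p cos(theta)``.

    Raises
    ------
    OutOfWorkspaceError
        If an arm cannot close its kinematic loop, naming that arm.

    Joint limits are *not* enforced here; check with
    :meth:`DeltaGeometry.within_limits` (angles are flagged, never clamped).
    """
    p = np.asarray(platform_position, dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise ConfigurationError("platform position must be finite")
    Lp, Ld = geom.len_proximal, geom.len_distal
    angles = np.empty(3)
    for i in range(3):
        r, s, h = _arm_frame_components(p, geom, i)
        # loop closure: r cos(th) + h sin(th) = k
        k = (r * r + s * s + h * h + Lp * Lp - Ld * Ld) / (2.0 * Lp)
        rho = np.hypot(r, h)
        if rho < 1e-15 or abs(k) > rho * (1 + 1e-12):
            raise OutOfWorkspaceError(
                f"arm {i}: position unreachable (|k|={abs(k):.4g} > rho={rho:.4g})",
                arm=i,
            )
        delta = np.arccos(np.clip(k / rho, -1.0, 1.0))
        psi = np.arctan2(h, r)
        cand = np.array([psi - delta, psi + delta])
        angles[i] = cand[np.argmax(np.cos(cand))]
    return angles


def delta_fk(delta_angles, geom: DeltaGeometry) -> np.ndarray:
    """Platform position from joint angles, by three-sphere intersection.

    Each distal link constrains the platform-attachment point to a sphere
    of radius ``L_d`` about the elbow; shifting every sphere inboard by
    ``R_m`` makes all three concentric on the platform *center*, which is
    then found by trilateration.  The lower-z intersection branch is
    returned (the physical working side below the fixed platform).
    """
    th = np.asarray(delta_angles, dtype=float).reshape(3)
    if not np.all(np.isfinite(th)):
        raise ConfigurationError("joint angles must be finite")
    Lp, Ld = geom.len_proximal, geom.len_distal
    centers = np.empty((3, 3))
    for i in range(3):
        u = geom.arm_units[i]
        radial = (geom.r_fixed - geom.r_moving) + Lp * np.cos(th[i])
        centers[i] = radial * u
        centers[i, 2] = Lp * np.sin(th[i])
    p1, p2, p3 = centers
    ex = p2 - p1
    d = np.linalg.norm(ex)
    if d < 1e-12:
        raise ConfigurationError("degenerate configuration: coincident sphere centers")
    ex = ex / d
    v = p3 - p1
    i_ = ex @ v
    ey = v - i_ * ex
    j_ = np.linalg.norm(ey)
    if j_ < 1e-12:
        raise ConfigurationError("degenerate configuration: collinear sphere centers")
    ey = ey / j_
    ez = np.cross(ex, ey)
    x = d / 2.0  # equal radii
    y = (i_ * i_ + j_ * j_ - 2.0 * i_ * x) / (2.0 * j_)
    z2 = Ld * Ld - x * x - y * y
    if z2 < 0:
        raise ConfigurationError(
            "invalid configuration: distal-link spheres do not intersect"
        )
    z = np.sqrt(z2)
    pa = p1 + x * ex + y * ey + z * ez
    pb = p1 + x * ex + y * ey - z * ez
    return pa if pa[2] <= pb[2] else pb


def delta_fk_batch(th1, th2, th3, geom: DeltaGeometry) -> np.ndarray:
    """Vectorized forward kinematics; NaN rows mark invalid configurations.

    Used by the workspace sweep where ~2e7 joint triples are evaluated.
    """
    Lp, Ld = geom.len_proximal, geom.len_distal
    U = geom.arm_units
    th = (np.asarray(th1, float), np.asarray(th2, float), np.asarray(th3, float))
    n = th[0].shape[0]
    C = np.empty((3, n, 3))
    for i in range(3):
        radial = (geom.r_fixed - geom.r_moving) + Lp * np.cos(th[i])
        C[i, :, 0] = radial * U[i, 0]
        C[i, :, 1] = radial * U[i, 1]
        C[i, :, 2] = Lp * np.sin(th[i])
    p1, p2, p3 = C
    ex = p2 - p1
    d = np.linalg.norm(ex, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = ex / d[:, None]
        v = p3 - p1
        i_ = np.einsum("ij,ij->i", ex, v)
        ey = v - i_[:, None] * ex
        j_ = np.linalg.norm(ey, axis=1)
        ey = ey / j_[:, None]
        ez = np.cross(ex, ey)
        x = d / 2.0
        y = (i_ * i_ + j_ * j_ - 2.0 * i_ * x) / (2.0 * j_)
        z2 = Ld * Ld - x * x - y * y
        ok = z2 >= 0
        z = np.sqrt(np.where(ok, z2, 0.0))
        base = p1 + x[:, None] * ex + y[:, None] * ey
        pa = base + z[:, None] * ez
        pb = base - z[:, None] * ez
        out = np.where((pa[:, 2] <= pb[:, 2])[:, None], pa, pb)
    out[~ok] = np.nan
    return out


# ----------------------------------------------------------------------------
# Goniometer chain and full pivot pose
# ----------------------------------------------------------------------------

def _pivot_direction(pitch: float, roll: float) -> np.ndarray:
    """Unit vector from the common rotation point to the pivot.

    At zero angles the extension points straight down (-z); pitch swings
    it in the x-z plane, roll in the y-z plane.  Yaw rotates about this
    line and therefore never appears here.
    """
    sp, cp = np.sin(pitch), np.cos(pitch)
    sr, cr = np.sin(roll), np.cos(roll)
    return np.array([-sp * cr, sr, -cp * cr])


def _pivot_direction_derivs(pitch: float, roll: float):
    """First and second partials of the extension direction wrt (pitch, roll)."""
    sp, cp = np.sin(pitch), np.cos(pitch)
    sr, cr = np.sin(roll), np.cos(roll)
    d_p = np.array([-cp * cr, 0.0, sp * cr])
    d_r = np.array([sp * sr, cr, cp * sr])
    d_pp = np.array([sp * cr, 0.0, cp * cr])
    d_pr = np.array([cp * sr, 0.0, -sp * sr])
    d_rr = np.array([sp * cr, -sr, cp * cr])
    return d_p, d_r, d_pp, d_pr, d_rr


def pivot_pose(
    cfg: JointConfig, dg: DeltaGeometry, gg: GoniometerGeometry
) -> PivotPose:
    """6-DOF virtual-pivot pose from a joint configuration.

    Position composes the delta forward kinematics with the goniometer
    chain (drop ``a1`` to the common rotation point, extend ``a4`` along
    the pitch/roll-rotated line); orientation is the goniometer angles in
    the declared order.
    """
    plat = delta_fk(cfg.delta_angles, dg)
    pitch, roll, yaw = cfg.gonio_angles
    rot_pt = plat + np.array([0.0, 0.0, -gg.offset_a1])
    pos = rot_pt + gg.pivot_extension_a4 * _pivot_direction(pitch, roll)
    return PivotPose(position=pos, orientation=np.array([pitch, roll, yaw]))


# ----------------------------------------------------------------------------
# Jacobians (vector method for the delta; analytic chain for the goniometer)
# ----------------------------------------------------------------------------

def _delta_jacobian(delta_angles: np.ndarray, geom: DeltaGeometry) -> np.ndarray:
    """3x3 platform-velocity Jacobian via the vector method.

    Differentiating each loop-closure constraint |A_i - E_i| = L_d gives
    s_i . dP = (s_i . dE_i/dth_i) dth_i with s_i the distal-link vector,
    i.e. rows of the inverse Jacobian; the forward Jacobian is its inverse.
    """
    th = np.asarray(delta_angles, float).reshape(3)
    p = delta_fk(th, geom)
    Lp = geom.len_proximal
    J_inv = np.empty((3, 3))
    for i in range(3):
        u = geom.arm_units[i]
        elbow = geom.r_fixed * u + Lp * (np.cos(th[i]) * u + np.sin(th[i]) * np.array([0, 0, 1.0]))
        attach = p + geom.r_moving * u
        s = attach - elbow
        e_prime = Lp * (-np.sin(th[i]) * u + np.cos(th[i]) * np.array([0, 0, 1.0]))
        denom = s @ e_prime
        if abs(denom) < 1e-12:
            raise SingularityError(f"arm {i} at a fold singularity (s . e' = 0)")
        J_inv[i] = s / denom
    return np.linalg.inv(J_inv)


def jacobian(
    cfg: JointConfig, dg: DeltaGeometry, gg: GoniometerGeometry
) -> JacobianMatrix:
    """6x6 Jacobian from joint rates to pivot twist.

    Block structure: the delta sub-block maps joint rates to platform
    (hence pivot) translation; pitch/roll columns add the swing of the
    ``a4`` extension; orientation rows are the identity on the goniometer
    angles.  Flagged singular when the condition number exceeds
    :data:`SINGULARITY_CONDITION_THRESHOLD`.
    """
    pitch, roll, _ = cfg.gonio_angles
    try:
        J_delta = _delta_jacobian(cfg.delta_angles, dg)
    except SingularityError:
        J = np.full((6, 6), np.nan)
        return JacobianMatrix(entries=J, singular=True, condition_number=np.inf)
    d_p, d_r, *_ = _pivot_direction_derivs(pitch, roll)
    J = np.zeros((6, 6))
    J[:3, :3] = J_delta
    J[:3, 3] = gg.pivot_extension_a4 * d_p
    J[:3, 4] = gg.pivot_extension_a4 * d_r
    # yaw column of position is zero: yaw axis runs along the extension line
    J[3:, 3:] = np.eye(3)
    cond = np.linalg.cond(J)
    return JacobianMatrix(
        entries=J,
        singular=bool(cond > SINGULARITY_CONDITION_THRESHOLD),
        condition_number=float(cond),
    )


# ----------------------------------------------------------------------------
# Workspace sweep
# ----------------------------------------------------------------------------

@dataclass
class WorkspaceReport:
    """Reachable x-y region per z slice from a joint-space sweep.

    ``square_side_m`` maps slice z (m) -> side of the largest axis-aligned
    square centered on the robot axis fully covered by reachable cells.
    """

    grid_resolution_rad: float
    cell_size_m: float
    square_side_m: dict[float, float]
    empty: bool

    @property
    def best_square_side_m(self) -> float:
        if self.empty or not self.square_side_m:
            return 0.0
        return max(self.square_side_m.values())

    @property
    def best_z_m(self) -> float | None:
        if self.empty or not self.square_side_m:
            return None
        return max(self.square_side_m, key=self.square_side_m.get)


def workspace_extent(
    dg: DeltaGeometry,
    grid_resolution: float = np.deg2rad(0.5),
    cell_size: float = 0.01,
    chunk: int = 2_000_000,
) -> WorkspaceReport:
    """Sweep the joint space and report per-z-slice inscribed squares.

    Forward kinematics is evaluated on a regular joint grid within the
    limits; reachable platform positions are binned into ``cell_size``
    voxels and, per z slice, the largest centered square fully covered by
    occupied x-y cells is grown outward cell ring by cell ring.
    """
    if grid_resolution <= 0:
        raise ConfigurationError("grid resolution must be > 0")
    lo, hi = dg.limits_rad
    ang = np.arange(lo, hi + 1e-12, grid_resolution)
    if len(ang) == 0:
        return WorkspaceReport(grid_resolution, cell_size, {}, empty=True)
    if len(ang) == 1:
        # collapsed joint range: a single shell, zero-area square
        return WorkspaceReport(
            grid_resolution, cell_size, {0.0: 0.0}, empty=False
        )
    occupancy: dict[int, set] = {}
    A1, A2 = np.meshgrid(ang, ang, indexing="ij")
    A1 = A1.ravel()
    A2 = A2.ravel()
    for a3 in ang:
        p = delta_fk_batch(A1, A2, np.full_like(A1, a3), dg)
        good = np.isfinite(p[:, 0])
        p = p[good]
        if p.size == 0:
            continue
        zi = np.round(p[:, 2] / cell_size).astype(np.int64)
        xi = np.round(p[:, 0] / cell_size).astype(np.int64)
        yi = np.round(p[:, 1] / cell_size).astype(np.int64)
        for z in np.unique(zi):
            m = zi == z
            occupancy.setdefault(int(z), set()).update(
                zip(xi[m].tolist(), yi[m].tolist())
            )
    if not occupancy:
        return WorkspaceReport(grid_resolution, cell_size, {}, empty=True)
    sides: dict[float, float] = {}
    for z, cells in occupancy.items():
        k = 0
        while True:
            k2 = k + 1
            ring_ok = all(
                (i, j) in cells
                for i in range(-k2, k2 + 1)
                for j in (-k2, k2)
            ) and all(
                (i, j) in cells
                for i in (-k2, k2)
                for j in range(-k2, k2 + 1)
            )
            if ring_ok and (0, 0) in cells:
                k = k2
            else:
                break
        sides[round(z * cell_size, 9)] = 2 * k * cell_size
    return WorkspaceReport(grid_resolution, cell_size, sides, empty=False)
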