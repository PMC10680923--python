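"""Stochastic virtual mouse: locomotor intent bouts and a muscle model.

Freely behaving mice move in bouts: the speed rises from rest to a peak
and falls back, tracing an arching loop in the velocity-acceleration
plane with the acceleration peak at roughly 50-75 % of the peak speed.
Each bout here is a half-sine speed pulse v(t) = V sin(π (t/T)^γ); the
default warp γ = 2 skews the pulse so the acceleration peak falls at
about 61 % of V (γ = 1 recovers the symmetric half-sine whose peak
acceleration is πV/T).  Bouts alternate with rest intervals; heading
changes happen between forward bouts as yaw half-sine pulses.

Calibration is closed-form: bout peak speeds are log-normal with the
location parameter solved so the population mean of the top 20 % of
peaks equals the freely-behaving target (13 cm/s), and the median bout
duration solved so the implied acceleration-peak population's top-20 %
mean equals its target (35 cm/s²), using the log-normal truncated-mean
identity  E[X | X > q_0.8] = exp(μ + σ²/2) Φ(σ − z_0.8) / 0.2.

The muscle model abstracts force generation through the limbs and body:
a saturating proportional pull toward the intended velocity,
F = clip(k (v_intent − v_actual), ±F_max), per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .errors import ConfigurationError
from .session import SAMPLE_RATE, SessionLog, empty_frame

__all__ = [
    "IntentCalibration",
    "MuscleModel",
    "IntentSeries",
    "VirtualMouse",
    "generate_intent",
    "muscle_force",
    "free_behavior_session",
]

_Z80 = norm.ppf(0.8)


def _top20_factor(sigma: float) -> float:
    """Ratio of a log-normal's top-20% mean to exp(mu):
    exp(sigma^2/2) Phi(sigma - z_0.8) / 0.2."""
    return float(np.exp(sigma**2 / 2) * norm.cdf(sigma - _Z80) / 0.2)


def _accel_shape_factor(gamma: float) -> float:
    """max_t of dv/dt for v = sin(pi u^gamma), u = t/T, in units of V/T."""
    if gamma == 1.0:
        return float(np.pi)
    res = minimize_scalar(
        lambda u: -np.pi * gamma * u ** (gamma - 1) * np.cos(np.pi * u**gamma),
        bounds=(1e-6, 1.0 - 1e-6),
        method="bounded",
    )
    return float(-res.fun)


@dataclass(frozen=True)
class IntentCalibration:
    """Generator parameters for freely-behaving locomotor intent.

    The two top-20% targets are the published freely-behaving values;
    every other parameter is a documented modeling choice.
    """

    target_top20_velocity: float = 0.13  # m/s
    target_top20_acceleration: float = 0.35  # m/s^2
    sigma_velocity: float = 0.4  # log-normal shape of bout peak speeds
    sigma_duration: float = 0.15  # log-normal shape of bout durations
    rest_mean: float = 1.2  # s, exponential rest intervals
    rest_min: float = 0.3  # s
    skew_gamma: float = 2.0  # bout warp; 1.0 = symmetric half-sine
    yaw_peak_median: float = 1.5  # rad/s, median yaw bout peak
    yaw_sigma: float = 0.5
    yaw_duration: float = 0.4  # s
    turn_probability: float = 0.6  # chance of a heading bout in a rest gap

    def __post_init__(self):
        if self.target_top20_velocity <= 0 or self.target_top20_acceleration <= 0:
            raise ConfigurationError("calibration targets must be > 0")
        if self.sigma_velocity <= 0 or self.sigma_duration < 0:
            raise ConfigurationError("distribution shapes must be proper")

    @property
    def mu_velocity(self) -> float:
        return float(
            np.log(self.target_top20_velocity) - np.log(_top20_factor(self.sigma_velocity))
        )

    @property
    def mu_duration(self) -> float:
        """Solved so the top-20% mean of a_peak = kappa V / T hits its target.

        With V, T independent log-normals, a_peak is log-normal with
        mu_a = mu_V + ln(kappa) - mu_T and sigma_a^2 = sigma_V^2 + sigma_T^2.
        """
        kappa = _accel_shape_factor(self.skew_gamma)
        sigma_a = float(np.hypot(self.sigma_velocity, self.sigma_duration))
        mu_a = np.log(self.target_top20_acceleration) - np.log(_top20_factor(sigma_a))
        return float(self.mu_velocity + np.log(kappa) - mu_a)


@dataclass(frozen=True)
class MuscleModel:
    """Saturating proportional muscle: F = clip(k (v_int - v_act), ±F_max)."""

    gain: float = 15.0  # N per (m/s); a trained mouse tracks its intent tightly
    saturation: float = 0.25  # N
    yaw_gain: float = 0.02  # N·m per (rad/s)
    yaw_saturation: float = 0.005  # N·m

    def __post_init__(self):
        if self.gain <= 0 or self.yaw_gain <= 0:
            raise ConfigurationError("muscle gains must be > 0")


@dataclass
class IntentSeries:
    """Intended mouse-frame velocities at 100 samples/s."""

    t: np.ndarray
    v_forward: np.ndarray
    v_lateral: np.ndarray
    v_yaw: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


def _bout_profile(V: float, T: float, gamma: float, dt: float) -> np.ndarray:
    n = max(int(round(T / dt)), 2)
    u = np.arange(n) / n
    return V * np.sin(np.pi * u**gamma)


def generate_intent(
    duration: float, calib: IntentCalibration, seed: int
) -> IntentSeries:
    """Bout-structured intent series; reproducible under the seed.

    Forward bouts are warped half-sine speed pulses with log-normal peak
    and duration; heading bouts (yaw half-sines) fall in the rest gaps.
    Zero duration yields an empty series.
    """
    if duration < 0:
        raise ConfigurationError("duration must be >= 0")
    dt = 1.0 / SAMPLE_RATE
    n = int(round(duration * SAMPLE_RATE))
    rng = np.random.default_rng(seed)
    vf = np.zeros(n)
    vy = np.zeros(n)
    if n == 0:
        t = np.zeros(0)
        return IntentSeries(t=t, v_forward=vf, v_lateral=np.zeros(0), v_yaw=vy)
    k = 0
    # start mid-rest so sessions do not all open with a bout
    k += int(round(rng.exponential(calib.rest_mean) / dt))
    while k < n:
        V = float(np.exp(rng.normal(calib.mu_velocity, calib.sigma_velocity)))
        T = float(np.exp(rng.normal(calib.mu_duration, calib.sigma_duration)))
        prof = _bout_profile(V, T, calib.skew_gamma, dt)
        end = min(k + len(prof), n)
        vf[k:end] = prof[: end - k]
        k = end
        rest = calib.rest_min + rng.exponential(calib.rest_mean)
        n_rest = int(round(rest / dt))
        if rng.random() < calib.turn_probability and n_rest > 4:
            W = float(
                np.exp(rng.normal(np.log(calib.yaw_peak_median), calib.yaw_sigma))
            )
            W *= rng.choice([-1.0, 1.0])
            yaw_prof = _bout_profile(W, min(calib.yaw_duration, rest), 1.0, dt)
            yend = min(k + len(yaw_prof), n)
            vy[k:yend] = yaw_prof[: yend - k]
        k += n_rest
    t = np.arange(n) * dt
    return IntentSeries(t=t, v_forward=vf, v_lateral=np.zeros(n), v_yaw=vy)


def muscle_force(v_intent, v_actual, muscle: MuscleModel) -> np.ndarray:
    """Head force/torque (fx, fy, tz) from the velocity mismatch."""
    vi = np.asarray(v_intent, float).reshape(3)
    va = np.asarray(v_actual, float).reshape(3)
    e = vi - va
    f = np.empty(3)
    f[0] = np.clip(muscle.gain * e[0], -muscle.saturation, muscle.saturation)
    f[1] = np.clip(muscle.gain * e[1], -muscle.saturation, muscle.saturation)
    f[2] = np.clip(muscle.yaw_gain * e[2], -muscle.yaw_saturation, muscle.yaw_saturation)
    return f


class VirtualMouse:
    """Bundles a calibration and muscle model for closed-loop simulation."""

    def __init__(
        self,
        calib: IntentCalibration | None = None,
        muscle: MuscleModel | None = None,
    ):
        self.calib = calib or IntentCalibration()
        self.muscle = muscle or MuscleModel()

    def generate_intent(self, duration: float, seed: int) -> IntentSeries:
        return generate_intent(duration, self.calib, seed)

    def muscle_force(self, v_intent, v_actual) -> np.ndarray:
        return muscle_force(v_intent, v_actual, self.muscle)


def free_behavior_session(
    duration: float,
    calib: IntentCalibration | None = None,
    seed: int = 0,
) -> SessionLog:
    """Open-loop freely-behaving session: intent *is* the actual motion.

    Positions integrate the intended forward speed along the integrated
    heading; forces are zero (no robot).  This is the generator whose
    statistics the behavior pipeline should recover.
    """
    calib = calib or IntentCalibration()
    intent = generate_intent(duration, calib, seed)
    n = len(intent)
    dt = 1.0 / SAMPLE_RATE
    yaw = np.cumsum(intent.v_yaw) * dt
    vx = intent.v_forward * np.cos(yaw)
    vy_g = intent.v_forward * np.sin(yaw)
    df = empty_frame(n, dt)
    df["x_m"] = np.cumsum(vx) * dt
    df["y_m"] = np.cumsum(vy_g) * dt
    df["yaw_rad"] = yaw
    df["vcmd_x"] = intent.v_forward
    df["vcmd_yaw"] = intent.v_yaw
    df["zone"] = "open"
    return SessionLog(df)
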