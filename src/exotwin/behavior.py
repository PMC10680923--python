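"""Behavior analytics: filtered kinematics, peak statistics, admittance-plane
fits, turn scoring, tortuosity, gait extraction, and binomial intervals.

The kinematics pipeline mirrors the session-log processing used for
controller tuning: differentiate position, then a 13-point median filter
followed by a 5-point mean filter (windows shrink at the series edges).
Only positive local maxima of the filtered traces are treated as
independent observations; distribution comparisons resample to n = 100
peaks.  The admittance plane F = m a + c v is fit by least squares with
no intercept.  Turn scoring marks a trial incorrect when the x-y path
deviates more than 1 cm from the midline toward the side contralateral
to the turn; tortuosity is the arc-chord ratio.  Gait steps come from
stationary-paw detection with the published exclusion rules (step size
outside [1, 10] cm or duration < 0.05 s).  Success rates use the exact
Clopper-Pearson binomial interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import beta as beta_dist

from .errors import ConfigurationError, ExotwinError

__all__ = [
    "FilterSpec",
    "PeakSet",
    "StepRecord",
    "median_mean_filter",
    "kinematics_from_positions",
    "peak_stats",
    "top_fraction_mean",
    "resample_peaks",
    "fit_admittance_plane",
    "score_turn",
    "tortuosity",
    "gait_steps",
    "clopper_pearson",
]


@dataclass(frozen=True)
class FilterSpec:
    """Smoothing windows (samples): 13-point median + 5-point mean for
    session kinematics; 5-point median for gait tracks."""

    median_window: int = 13
    mean_window: int = 5
    gait_median_window: int = 5

    def __post_init__(self):
        for name in ("median_window", "mean_window", "gait_median_window"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ConfigurationError(f"{name} must be odd and >= 1")


def median_mean_filter(x, median_window: int = 13, mean_window: int = 5) -> np.ndarray:
    """Median then mean filter; centered windows shrink at the edges."""
    s = pd.Series(np.asarray(x, float))
    med = s.rolling(median_window, center=True, min_periods=1).median()
    return med.rolling(mean_window, center=True, min_periods=1).mean().to_numpy()


def kinematics_from_positions(
    positions, dt: float, filt: FilterSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Filtered velocity and acceleration from a position series.

    1-D input: signed velocity and acceleration.  2-D (n, 2) input: speed
    along the path and its (tangential) acceleration — the scalar traces
    whose velocity-acceleration loops arch.  Finite differences first,
    filtering second.
    """
    filt = filt or FilterSpec()
    p = np.asarray(positions, float)
    n = p.shape[0]
    if n < max(filt.median_window, filt.mean_window):
        raise ExotwinError("position series shorter than the filter window")
    if p.ndim == 1:
        v_raw = np.gradient(p, dt)
    elif p.ndim == 2 and p.shape[1] == 2:
        v_raw = np.hypot(np.gradient(p[:, 0], dt), np.gradient(p[:, 1], dt))
    else:
        raise ConfigurationError("positions must be (n,) or (n, 2)")
    a_raw = np.gradient(v_raw, dt)
    vel = median_mean_filter(v_raw, filt.median_window, filt.mean_window)
    acc = median_mean_filter(a_raw, filt.median_window, filt.mean_window)
    return vel, acc


@dataclass
class PeakSet:
    """Positive local maxima of one axis' trace."""

    amplitudes: np.ndarray
    source_axis: str = ""
    resample_size: int = 100

    def __len__(self) -> int:
        return len(self.amplitudes)


def peak_stats(series, source_axis: str = "") -> PeakSet:
    """Positive local maxima of a series (peaks only, so samples are
    independent observations)."""
    x = np.asarray(series, float)
    if x.size == 0:
        raise ExotwinError("empty series")
    idx, _ = find_peaks(x)
    amps = x[idx]
    return PeakSet(amplitudes=amps[amps > 0], source_axis=source_axis)


def top_fraction_mean(peaks: PeakSet | np.ndarray, fraction: float = 0.2) -> float:
    """Mean of the ceil(fraction · n) largest peak amplitudes."""
    amps = peaks.amplitudes if isinstance(peaks, PeakSet) else np.asarray(peaks, float)
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    if amps.size == 0:
        raise ExotwinError("no peaks to average")
    k = int(np.ceil(fraction * amps.size))
    return float(np.sort(amps)[-k:].mean())


def resample_peaks(peaks: PeakSet, n: int = 100, seed: int = 0) -> np.ndarray:
    """Seeded subsample (without replacement) to n peaks for distribution
    comparisons; the full set is returned when it is already <= n."""
    amps = peaks.amplitudes
    if amps.size <= n:
        return amps.copy()
    rng = np.random.default_rng(seed)
    return rng.choice(amps, size=n, replace=False)


def fit_admittance_plane(force, velocity, acceleration):
    """Least-squares fit of F = m a + c v (no intercept).

    Returns (m, c, residual_norm).  With the acceleration column absent
    of information (all ~0) the damping-only estimate c = <F,v>/<v,v> is
    returned with m = NaN flagged; truly collinear regressors raise.
    """
    F = np.asarray(force, float).ravel()
    v = np.asarray(velocity, float).ravel()
    a = np.asarray(acceleration, float).ravel()
    if not (F.size == v.size == a.size) or F.size < 2:
        raise ConfigurationError("need >= 2 congruent samples")
    scale = max(np.abs(a).max(), np.abs(v).max(), 1e-300)
    if np.abs(a).max() <= 1e-12 * scale:
        if np.abs(v).max() <= 1e-12 * scale:
            raise ExotwinError("degenerate fit: v and a both identically zero")
        c = float((F @ v) / (v @ v))
        return float("nan"), c, float(np.linalg.norm(F - c * v))
    X = np.column_stack([a, v])
    if np.linalg.matrix_rank(X) < 2:
        raise ExotwinError("rank-deficient fit: v and a are collinear")
    coef, *_ = np.linalg.lstsq(X, F, rcond=None)
    resid = float(np.linalg.norm(F - X @ coef))
    return float(coef[0]), float(coef[1]), resid


def score_turn(path, direction: str, midline_y: float = 0.0) -> str:
    """Score a turning-zone traversal.

    ``path`` is (n, 2) global x-y; ``direction`` the turn actually cued/
    taken.  Incorrect iff the path deviates strictly more than 1 cm from
    the midline toward the contralateral side (right of midline for a
    left turn and vice versa); exactly 1 cm is still correct.
    """
    p = np.asarray(path, float)
    if direction not in ("left", "right"):
        raise ConfigurationError("direction must be left|right")
    if p.ndim != 2 or p.shape[0] < 2:
        return "undecided"
    dev = p[:, 1] - midline_y
    contralateral = -dev if direction == "left" else dev
    return "incorrect" if contralateral.max() > 0.01 else "correct"


def tortuosity(path) -> float:
    """Arc-chord ratio: path length over straight entry-to-exit distance."""
    p = np.asarray(path, float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ConfigurationError("path needs >= 2 points")
    chord = np.linalg.norm(p[-1] - p[0])
    if chord < 1e-12:
        raise ExotwinError("tortuosity undefined: zero chord")
    arc = np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1))
    return float(arc / chord)


@dataclass
class StepRecord:
    """One recovered step of one paw."""

    paw: str
    length: float  # cm
    duration: float  # s
    cadence: float  # Hz, inverse onset-to-onset interval
    body_velocity: float  # cm/s at the step


def gait_steps(
    paw_xy,
    body_velocity,
    dt: float,
    paw: str = "forepaw",
    filt: FilterSpec | None = None,
    stationary_speed: float = 0.5,  # cm/s
    min_stance_samples: int = 3,
) -> tuple[list[StepRecord], dict]:
    """Extract steps from a paw keypoint track.

    Stances are runs (>= ``min_stance_samples``) where the median-filtered
    paw speed stays at or below the stationarity threshold (a literal
    0 cm/s never happens with tracking noise); a step is the swing between
    consecutive stances, its length the displacement between stance
    centroids, its cadence the inverse of the onset-to-onset interval.
    Records violating the exclusion rules (length outside [1, 10] cm,
    duration < 0.05 s) are dropped and counted.

    Positions in cm; returns (records, diagnostics).
    """
    filt = filt or FilterSpec()
    p = np.asarray(paw_xy, float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ConfigurationError("paw track must be (n, 2)")
    vx = np.gradient(p[:, 0], dt)
    vy = np.gradient(p[:, 1], dt)
    speed = np.hypot(vx, vy)
    w = filt.gait_median_window
    speed_f = (
        pd.Series(speed).rolling(w, center=True, min_periods=1).median().to_numpy()
    )
    stationary = speed_f <= stationary_speed
    # contiguous stance runs
    runs = []
    start = None
    for i, s in enumerate(stationary):
        if s and start is None:
            start = i
        elif not s and start is not None:
            if i - start >= min_stance_samples:
                runs.append((start, i))
            start = None
    if start is not None and len(stationary) - start >= min_stance_samples:
        runs.append((start, len(stationary)))
    diagnostics = {"n_stances": len(runs), "excluded": 0}
    if not runs:
        return [], diagnostics
    body_v = np.asarray(body_velocity, float)
    records: list[StepRecord] = []
    for (s0, e0), (s1, e1) in zip(runs[:-1], runs[1:]):
        c0 = p[s0:e0].mean(axis=0)
        c1 = p[s1:e1].mean(axis=0)
        length = float(np.linalg.norm(c1 - c0))
        duration = float((s1 - e0) * dt)  # swing time
        onset_interval = float((s1 - s0) * dt)
        cadence = 1.0 / onset_interval if onset_interval > 0 else np.nan
        if not (1.0 <= length <= 10.0) or duration < 0.05:
            diagnostics["excluded"] += 1
            continue
        records.append(
            StepRecord(
                paw=paw,
                length=length,
                duration=duration,
                cadence=cadence,
                body_velocity=float(body_v[e0 : s1 + 1].mean()) if body_v.size else np.nan,
            )
        )
    return records, diagnostics


def clopper_pearson(
    successes: int, trials: int, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Exact binomial interval: (point estimate, lower, upper).

    Beta-quantile form: lower = B(alpha/2; k, n-k+1),
    upper = B(1-alpha/2; k+1, n-k), with the conventional closed ends at
    k = 0 and k = n.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ConfigurationError("need 0 <= successes <= trials, trials >= 1")
    k, n = successes, trials
    lower = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return k / n, lower, upper
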