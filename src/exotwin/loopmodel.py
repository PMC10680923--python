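"""Frequency-domain model of the robot + admittance controller.

The controller renders a virtual admittance Y_virtual(s) = 1/(m s + c):
ideally the mouse's force F maps to velocity V = Y_virtual F.  Sensor
sampling, the discrete control cycle, and the inner servo loops degrade
this at higher frequency.  The apparent admittance is modeled as

    Y_app(s) = Y_virtual(s) · D(s),
    D(s) = exp(-s T_delay) / (1 + s τ_lag),

where T_delay aggregates the zero-order hold (half a cycle) plus the
full-cycle computation latency plus the sensor delay, and τ_lag is the
inner velocity-loop first-order lag.  |Y_app| -> 1/c as ω -> 0.

Bandwidth is the lowest frequency at which the apparent admittance
deviates from the virtual one by 3 dB, measured on the complex deviation:
|Y_app/Y_virtual − 1| reaching 1/√2.  A pure delay leaves |Y_app/Y_virtual|
at unity yet is very much a degradation, so the criterion must see phase;
the complex-error form does, and it reduces to the familiar corner
frequency for a delay-free first-order lag.  A magnitude-only variant is
switchable for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError

__all__ = ["LoopModel", "apparent_admittance", "bandwidth", "bandwidth_sweep"]

_DEV_THRESHOLD = 1.0 / np.sqrt(2.0)  # -3 dB on the deviation


@dataclass(frozen=True)
class LoopModel:
    """Virtual admittance plus the loop's delay/lag parameters.

    Defaults: 10 ms cycle, 10 ms sensor delay, 5 ms inner-loop lag, and
    the plausible-tuned virtual mass/damping of the forward axis.
    """

    virtual_mass: float = 0.2
    virtual_damping: float = 0.6
    cycle_time: float = 0.01
    sensor_delay: float = 0.01
    inner_loop_lag: float = 0.005
    frequency_grid: np.ndarray | None = None

    def __post_init__(self):
        for name in ("cycle_time", "sensor_delay", "inner_loop_lag"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.virtual_mass <= 0 or self.virtual_damping < 0:
            raise ConfigurationError("need virtual_mass > 0 and damping >= 0")
        if self.frequency_grid is None:
            object.__setattr__(
                self, "frequency_grid", np.logspace(-2, 2.5, 2000)
            )
        grid = np.asarray(self.frequency_grid, float)
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ConfigurationError("frequency grid must be positive ascending")
        object.__setattr__(self, "frequency_grid", grid)

    @property
    def total_delay(self) -> float:
        """ZOH half-cycle + full-cycle computation latency + sensor delay."""
        return 1.5 * self.cycle_time + self.sensor_delay


def virtual_admittance(model: LoopModel, f_hz=None) -> np.ndarray:
    f = model.frequency_grid if f_hz is None else np.asarray(f_hz, float)
    s = 2j * np.pi * f
    return 1.0 / (model.virtual_mass * s + model.virtual_damping)


def loop_degradation(model: LoopModel, f_hz=None) -> np.ndarray:
    """D(jω): delay and inner-loop lag; unity at ω -> 0."""
    f = model.frequency_grid if f_hz is None else np.asarray(f_hz, float)
    w = 2 * np.pi * f
    return np.exp(-1j * w * model.total_delay) / (1.0 + 1j * w * model.inner_loop_lag)


def apparent_admittance(model: LoopModel, f_hz=None) -> np.ndarray:
    """Complex apparent admittance Y_app(jω) = Y_virtual(jω) · D(jω)."""
    return virtual_admittance(model, f_hz) * loop_degradation(model, f_hz)


def _deviation(model: LoopModel, f_hz, criterion: str) -> np.ndarray:
    D = loop_degradation(model, f_hz)
    if criterion == "complex":
        return np.abs(D - 1.0)
    if criterion == "magnitude":
        return np.abs(np.abs(D) - 1.0)
    raise ConfigurationError("criterion must be complex|magnitude")


def bandwidth(model: LoopModel, criterion: str = "complex") -> tuple[float, bool]:
    """3 dB bandwidth (Hz) of the apparent admittance.

    Returns (frequency, crossed): the lowest grid frequency at which the
    apparent/virtual deviation reaches -3 dB, refined by bisection to
    ≤1e-3 Hz.  If no crossing occurs within the grid the upper grid bound
    is returned with ``crossed=False``.
    """
    grid = model.frequency_grid
    dev = _deviation(model, grid, criterion)
    above = np.nonzero(dev >= _DEV_THRESHOLD)[0]
    if above.size == 0:
        return float(grid[-1]), False
    i = int(above[0])
    if i == 0:
        return float(grid[0]), True
    lo, hi = grid[i - 1], grid[i]
    while hi - lo > 1e-3:
        mid = 0.5 * (lo + hi)
        if _deviation(model, np.array([mid]), criterion)[0] >= _DEV_THRESHOLD:
            hi = mid
        else:
            lo = mid
    return float(0.5 * (lo + hi)), True


def bandwidth_sweep(model: LoopModel, parameter: str, values) -> np.ndarray:
    """Bandwidth at each value of one delay/lag parameter (Hz)."""
    out = []
    for v in values:
        out.append(bandwidth(replace(model, **{parameter: float(v)}))[0])
    return np.asarray(out)
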