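"""Neural preprocessing and spatial-encoding analyses.

Imaging arm: band-pass the per-cell and neuropil fluorescence (4th-order
Butterworth, 0.05-5 Hz, zero phase), form
ΔF/F = (F_cell − 0.7 F_neu) / mean(F_cell − 0.7 F_neu) in percent (the
denominator uses the raw-trace mean — band-passing removes DC, so the
literal filtered mean would be near zero), then drop cells failing the
signal and morphology criteria (3·sd < max; 1·sd < 50 %; max between
20 % and 500 %; soma 20-400 pixels; aspect ratio 0.7-1.4, boundaries
inclusive).

Electrophysiology arm: subtract the common mode (mean over in-brain
channels) from every channel, high-pass at 250 Hz (4th-order
Butterworth) for waveform metrics, then bin spikes in 50 ms windows
stepped by 20 ms (resampling to 50 S/s), smooth with a Gaussian pulse of
260 ms width and 20 ms standard deviation, and z-score per cell.

Encoding: activity Y (time × cell) is regressed on a design matrix X of
one-hot location bins along the linearized 8-maze path (2 cm → 82 bins
imaging, 1 cm → 196 bins ephys as shipped reference configurations),
optionally extended with diagonalized event columns (each cue/reward
onset expanded into causal lagged indicators) and z-scored continuous
covariates.  The kernel K of Beta weights solves Y = X K either by the
Moore-Penrose pseudoinverse (minimum-norm when X is rank-deficient) or
by reduced-rank regression (OLS followed by SVD truncation of the fitted
values) when predictors co-occur.  Stationary samples are zeroed before
the fit and kernel rows with fewer than 5 predictor instances are zeroed
to avoid over-fitting sparse events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError, ExotwinError

__all__ = [
    "FluorSession",
    "EphysSession",
    "RateMatrix",
    "PredictorMatrix",
    "KernelMatrix",
    "PlaceTuningSpec",
    "compute_dff",
    "filter_cells",
    "preprocess_ephys",
    "build_predictors",
    "kernel_pinv",
    "kernel_rrr",
    "normalize_sort",
    "synth_place_cells",
    "synth_fluorescence_session",
    "true_kernel",
    "linear_traversals",
    "STATIONARY_SPEED",
]

NEUROPIL_COEF = 0.7
MIN_EVENT_INSTANCES = 5
#: speed below which the mouse is considered stationary (m/s); same
#: convention as the behavior module's 0.5 cm/s.
STATIONARY_SPEED = 0.005


# ----------------------------------------------------------------------------
# Containers
# ----------------------------------------------------------------------------

@dataclass
class FluorSession:
    """Imaging session: fluorescence + neuropil (time × cell) and soma
    morphology (pixels, aspect ratio, diameter) per cell."""

    F_cell: np.ndarray
    F_neu: np.ndarray
    sample_rate: float = 15.0
    morphology: np.ndarray | None = None  # (cell, [pixels, aspect, diameter])

    def __post_init__(self):
        self.F_cell = np.atleast_2d(np.asarray(self.F_cell, float))
        self.F_neu = np.atleast_2d(np.asarray(self.F_neu, float))
        if self.F_cell.shape != self.F_neu.shape:
            raise ConfigurationError("F_cell and F_neu shapes must match")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample rate must be > 0")


@dataclass
class EphysSession:
    """Electrophysiology session: raw channel voltages (time × channel) for
    preprocessing, spike times per cell (s), and the in-brain channel mask."""

    channel_voltages: np.ndarray | None
    spike_times: list[np.ndarray]
    in_brain_mask: np.ndarray | None = None
    sample_rate: float = 20000.0
    duration: float | None = None

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ConfigurationError("sample rate must be > 0")
        self.spike_times = [np.asarray(s, float) for s in self.spike_times]


@dataclass
class RateMatrix:
    """Activity Y (time × cell) at a stated sample rate."""

    Y: np.ndarray
    sample_rate: float
    zero_variance_cells: np.ndarray = field(default_factory=lambda: np.zeros(0, int))


@dataclass
class PredictorMatrix:
    """Design matrix X (time × predictor) with named column blocks."""

    X: np.ndarray
    location_slice: slice
    event_slices: dict[str, slice] = field(default_factory=dict)
    covariate_slice: slice | None = None
    off_path_samples: int = 0
    bin_edges: np.ndarray | None = None

    @property
    def n_location_bins(self) -> int:
        return self.location_slice.stop - self.location_slice.start


@dataclass
class KernelMatrix:
    """Beta-weight kernel K (location/event predictor × cell)."""

    K: np.ndarray
    normalized: bool = False
    sort_order: np.ndarray | None = None
    zeroed_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, int))


# ----------------------------------------------------------------------------
# Imaging preprocessing
# ----------------------------------------------------------------------------

def compute_dff(session: FluorSession) -> tuple[np.ndarray, np.ndarray]:
    """ΔF/F in percent, with 0.7-weighted neuropil subtraction.

    The numerator is the band-passed (0.05-5 Hz, zero-phase) neuropil-
    corrected trace; the denominator is the mean of the *raw* corrected
    trace.  Returns (dff, valid_mask); cells whose denominator is not
    positive are flagged invalid, never silently kept.
    """
    fs = session.sample_rate
    if fs <= 10:
        raise ConfigurationError("sample rate must exceed 10 S/s for the passband")
    corrected = session.F_cell - NEUROPIL_COEF * session.F_neu
    sos = signal.butter(4, [0.05, 5.0], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, corrected, axis=0)
    denom = corrected.mean(axis=0)
    valid = denom > 0
    dff = np.full_like(filtered, np.nan)
    dff[:, valid] = 100.0 * filtered[:, valid] / denom[valid]
    return dff, valid


def filter_cells(
    dff: np.ndarray, morphology: np.ndarray | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """Cell inclusion mask from the five published criteria.

    Signal: 3·sd < max; 1·sd < 50 %; max between 20 % and 500 %.
    Morphology: soma pixels between 20 and 400; aspect ratio between 0.7
    and 1.4.  "Between" is inclusive at the boundaries.  Returns the mask
    and per-criterion pass counts.
    """
    dff = np.atleast_2d(np.asarray(dff, float))
    sd = np.nanstd(dff, axis=0)
    mx = np.nanmax(dff, axis=0)
    crit = {
        "sd3_below_max": 3.0 * sd < mx,
        "sd_below_50": sd < 50.0,
        "max_in_range": (mx >= 20.0) & (mx <= 500.0),
    }
    if morphology is not None:
        morph = np.atleast_2d(np.asarray(morphology, float))
        crit["soma_pixels"] = (morph[:, 0] >= 20) & (morph[:, 0] <= 400)
        crit["aspect_ratio"] = (morph[:, 1] >= 0.7) & (morph[:, 1] <= 1.4)
    mask = np.logical_and.reduce(list(crit.values()))
    counts = {k: int(v.sum()) for k, v in crit.items()}
    return mask, counts


# ----------------------------------------------------------------------------
# Electrophysiology preprocessing
# ----------------------------------------------------------------------------

def subtract_common_mode(voltages: np.ndarray, in_brain_mask) -> np.ndarray:
    """Subtract the mean of the in-brain channels from every channel."""
    v = np.atleast_2d(np.asarray(voltages, float))
    mask = np.asarray(in_brain_mask, bool)
    if not mask.any():
        raise ConfigurationError("in-brain channel mask is empty")
    return v - v[:, mask].mean(axis=1, keepdims=True)


def highpass_voltages(voltages: np.ndarray, sample_rate: float, cutoff: float = 250.0):
    sos = signal.butter(4, cutoff, btype="highpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, voltages, axis=0)


def spike_rates(
    spike_times: list[np.ndarray],
    duration: float,
    window: float = 0.05,
    step: float = 0.02,
    zscore: bool = True,
) -> RateMatrix:
    """Windowed spike counts: 50 ms windows stepped by 20 ms (=> 50 S/s),
    Gaussian-smoothed (260 ms pulse, 20 ms sd) and z-scored per cell
    (``zscore=False`` returns the smoothed counts per window).

    Zero-variance cells are flagged and retained as zeros.
    """
    starts = np.arange(0.0, duration - window + 1e-12, step)
    n_t, n_c = len(starts), len(spike_times)
    Y = np.zeros((n_t, n_c))
    for j, st in enumerate(spike_times):
        st = st[(st >= 0) & (st <= duration)]
        for k, t0 in enumerate(starts):
            Y[k, j] = np.count_nonzero((st >= t0) & (st < t0 + window))
    # Gaussian pulse: 260 ms width at 20 ms sd on the 20 ms grid
    half = int(round(0.26 / 2 / step))
    tt = np.arange(-half, half + 1) * step
    g = np.exp(-0.5 * (tt / 0.02) ** 2)
    g /= g.sum()
    Y = np.apply_along_axis(lambda col: np.convolve(col, g, mode="same"), 0, Y)
    if not zscore:
        return RateMatrix(Y=Y, sample_rate=1.0 / step)
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0)
    flat = np.nonzero(sd == 0)[0]
    Yz = np.zeros_like(Y)
    ok = sd > 0
    Yz[:, ok] = (Y[:, ok] - mu[ok]) / sd[ok]
    return RateMatrix(Y=Yz, sample_rate=1.0 / step, zero_variance_cells=flat)


def preprocess_ephys(session: EphysSession) -> tuple[np.ndarray | None, RateMatrix]:
    """Full ephys pipeline: common-mode subtraction + 250 Hz high-pass on
    the voltages (when present) and smoothed z-scored rates at 50 S/s."""
    cleaned = None
    if session.channel_voltages is not None:
        if session.in_brain_mask is None:
            raise ConfigurationError("channel voltages given without in-brain mask")
        cleaned = subtract_common_mode(session.channel_voltages, session.in_brain_mask)
        cleaned = highpass_voltages(cleaned, session.sample_rate)
    duration = session.duration
    if duration is None:
        duration = max((float(s[-1]) for s in session.spike_times if s.size), default=0.0)
    if duration <= 0:
        raise ConfigurationError("cannot infer session duration")
    return cleaned, spike_rates(session.spike_times, duration)


# ----------------------------------------------------------------------------
# Design matrix
# ----------------------------------------------------------------------------

def build_predictors(
    lin_position,
    path_length: float,
    n_bins: int | None = None,
    bin_length: float | None = 0.02,
    events: dict[str, np.ndarray] | None = None,
    covariates: dict[str, np.ndarray] | None = None,
    sample_rate: float = 15.0,
    lag_span: float = 1.0,
) -> PredictorMatrix:
    """Design matrix from a linearized path coordinate.

    ``lin_position``: arc length (m) along the path at the Y sample rate;
    NaN marks out-of-maze samples.  Bins are half-open [start, end) along
    the path; exactly one location column is 1 per in-maze sample,
    off-path samples get an all-zero row and are counted.  Each event's
    onset indices expand into causal lagged indicator columns spanning
    ``lag_span`` seconds; continuous covariates are z-scored.
    """
    s = np.asarray(lin_position, float)
    if n_bins is None:
        if bin_length is None or bin_length <= 0:
            raise ConfigurationError("need n_bins or a positive bin_length")
        n_bins = int(round(path_length / bin_length))
    if n_bins < 1:
        raise ConfigurationError("need at least one location bin")
    edges = np.linspace(0.0, path_length, n_bins + 1)
    n_t = s.size
    in_maze = np.isfinite(s) & (s >= 0) & (s < path_length + 1e-12)
    idx = np.clip(np.searchsorted(edges, s[in_maze], side="right") - 1, 0, n_bins - 1)
    loc = np.zeros((n_t, n_bins))
    loc[np.nonzero(in_maze)[0], idx] = 1.0
    blocks = [loc]
    col = n_bins
    event_slices: dict[str, slice] = {}
    n_lags = max(int(round(lag_span * sample_rate)), 1)
    for name, onsets in (events or {}).items():
        onsets = np.asarray(onsets, int)
        block = np.zeros((n_t, n_lags))
        for lag in range(n_lags):
            tgt = onsets + lag
            tgt = tgt[(tgt >= 0) & (tgt < n_t)]
            block[tgt, lag] = 1.0
        event_slices[name] = slice(col, col + n_lags)
        blocks.append(block)
        col += n_lags
    cov_slice = None
    if covariates:
        cov = np.column_stack([np.asarray(v, float) for v in covariates.values()])
        mu, sd = cov.mean(axis=0), cov.std(axis=0)
        sd[sd == 0] = 1.0
        blocks.append((cov - mu) / sd)
        cov_slice = slice(col, col + cov.shape[1])
        col += cov.shape[1]
    X = np.column_stack(blocks)
    return PredictorMatrix(
        X=X,
        location_slice=slice(0, n_bins),
        event_slices=event_slices,
        covariate_slice=cov_slice,
        off_path_samples=int(n_t - in_maze.sum()),
        bin_edges=edges,
    )


# ----------------------------------------------------------------------------
# Kernel regression
# ----------------------------------------------------------------------------

def _zero_sparse_rows(K: np.ndarray, X: np.ndarray) -> np.ndarray:
    counts = (X != 0).sum(axis=0)
    rows = np.nonzero(counts < MIN_EVENT_INSTANCES)[0]
    K[rows, :] = 0.0
    return rows


def kernel_pinv(
    Y: np.ndarray | RateMatrix,
    X: np.ndarray | PredictorMatrix,
    stationary_mask=None,
) -> KernelMatrix:
    """Kernel of Beta weights by Moore-Penrose pseudoinverse.

    Y rows where the mouse is stationary are zeroed before the fit (to
    avoid fitting quiescent states); predictor columns with fewer than 5
    nonzero instances have their kernel rows zeroed afterwards.  The
    pseudoinverse gives the minimum-norm solution when X is
    rank-deficient.
    """
    Ym = Y.Y if isinstance(Y, RateMatrix) else np.asarray(Y, float)
    Xm = X.X if isinstance(X, PredictorMatrix) else np.asarray(X, float)
    if Ym.shape[0] != Xm.shape[0]:
        raise ConfigurationError("Y and X must share the time axis")
    if stationary_mask is not None:
        mask = np.asarray(stationary_mask, bool)
        if mask.all():
            raise ExotwinError("all-stationary session: nothing to regress")
        Ym = Ym.copy()
        Ym[mask, :] = 0.0
    K = np.linalg.pinv(Xm) @ Ym
    zeroed = _zero_sparse_rows(K, Xm)
    return KernelMatrix(K=K, zeroed_rows=zeroed)


def kernel_rrr(
    Y: np.ndarray | RateMatrix,
    X: np.ndarray | PredictorMatrix,
    rank: int,
    stationary_mask=None,
) -> KernelMatrix:
    """Reduced-rank kernel: OLS followed by SVD truncation of the fitted
    values (the classical RRR estimator).  Residual norm is non-increasing
    in rank; at full rank it equals the OLS solution."""
    Ym = Y.Y if isinstance(Y, RateMatrix) else np.asarray(Y, float)
    Xm = X.X if isinstance(X, PredictorMatrix) else np.asarray(X, float)
    if Ym.shape[0] != Xm.shape[0]:
        raise ConfigurationError("Y and X must share the time axis")
    max_rank = min(Xm.shape[1], Ym.shape[1])
    if not 1 <= rank <= max_rank:
        raise ConfigurationError(f"rank must be in [1, {max_rank}]")
    if stationary_mask is not None:
        mask = np.asarray(stationary_mask, bool)
        if mask.all():
            raise ExotwinError("all-stationary session: nothing to regress")
        Ym = Ym.copy()
        Ym[mask, :] = 0.0
    B_ols, *_ = np.linalg.lstsq(Xm, Ym, rcond=None)
    fitted = Xm @ B_ols
    _, _, Vt = np.linalg.svd(fitted, full_matrices=False)
    P = Vt[:rank].T @ Vt[:rank]
    K = B_ols @ P
    zeroed = _zero_sparse_rows(K, Xm)
    return KernelMatrix(K=K, zeroed_rows=zeroed)


def normalize_sort(
    kernel: KernelMatrix,
    order: str = "onset_of_max",
    depth_table=None,
) -> KernelMatrix:
    """Normalize each cell's Beta weights to max 1 and order the cells.

    ``onset_of_max`` sorts by the location of each cell's maximum (stable
    sort, all-zero cells last); ``depth`` sorts by the supplied cortical
    depth per cell.
    """
    K = kernel.K.copy()
    n_cells = K.shape[1]
    maxes = K.max(axis=0)
    nonzero = np.abs(K).max(axis=0) > 0
    scale = np.where(maxes > 0, maxes, np.abs(K).max(axis=0))
    scale[scale == 0] = 1.0
    K = K / scale
    if order == "onset_of_max":
        onset = np.argmax(K, axis=0).astype(float)
        onset[~nonzero] = np.inf  # all-zero cells last
        idx = np.argsort(onset, kind="stable")
    elif order == "depth":
        if depth_table is None:
            raise ConfigurationError("depth ordering requires a depth table")
        idx = np.argsort(np.asarray(depth_table, float), kind="stable")
    else:
        raise ConfigurationError("order must be onset_of_max|depth")
    return KernelMatrix(
        K=K[:, idx], normalized=True, sort_order=idx, zeroed_rows=kernel.zeroed_rows
    )


# ----------------------------------------------------------------------------
# Synthetic place-tuned sessions
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaceTuningSpec:
    """Population tuning parameters for synthetic place cells."""

    width_m: tuple[float, float] = (0.03, 0.08)  # field sd range
    peak_rate_hz: tuple[float, float] = (2.0, 10.0)
    baseline_rate_hz: float = 0.1


def linear_traversals(
    path_length: float, speed: float, duration: float, sample_rate: float = 15.0
) -> np.ndarray:
    """Linearized position of repeated constant-speed traversals 0 -> L."""
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    return np.mod(speed * t, path_length)


def synth_place_cells(
    n_cells: int, path_length: float, spec: PlaceTuningSpec, rng: np.random.Generator
):
    """Sample (centers, widths, peak rates) for a population; centers are
    spread evenly with jitter so the sorted kernel shows the diagonal."""
    centers = np.sort(
        np.mod(
            np.linspace(0, path_length, n_cells, endpoint=False)
            + rng.normal(0, path_length / (4 * max(n_cells, 1)), n_cells),
            path_length,
        )
    )
    widths = rng.uniform(*spec.width_m, n_cells)
    peaks = rng.uniform(*spec.peak_rate_hz, n_cells)
    return centers, widths, peaks


def _tuning_rates(lin_pos, centers, widths, peaks, baseline):
    s = np.asarray(lin_pos, float)[:, None]
    lam = peaks[None, :] * np.exp(-0.5 * ((s - centers[None, :]) / widths[None, :]) ** 2)
    return lam + baseline


def true_kernel(centers, widths, peaks, baseline, path_length, n_bins) -> np.ndarray:
    """Ground-truth kernel: tuning curves evaluated at bin centers."""
    edges = np.linspace(0, path_length, n_bins + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    return _tuning_rates(mid, centers, widths, peaks, baseline)


def synth_fluorescence_session(
    lin_position,
    n_cells: int,
    path_length: float,
    seed: int,
    spec: PlaceTuningSpec | None = None,
    sample_rate: float = 15.0,
    calcium_decay: float = 0.4,
    noise_sd: float = 0.0,
    neuropil_amp: float = 0.0,
    baseline_f: float = 100.0,
    poisson: bool = True,
):
    """Synthetic place-tuned imaging session + ground truth.

    Place cells with Gaussian tuning over the linearized path fire
    Poisson spikes (or emit their noiseless rate when ``poisson=False``);
    calcium transients are the spikes convolved with an exponential
    kernel (default 0.4 s decay) riding on a fluorescence baseline with
    optional white noise and a shared neuropil signal.

    Returns (FluorSession, rates λ(t), (centers, widths, peaks)); the
    ground-truth kernel follows from :func:`true_kernel` on the tuning
    parameters.
    """
    s = np.asarray(lin_position, float)
    if not np.isfinite(s).any():
        raise ExotwinError("behavior never enters the maze")
    rng = np.random.default_rng(seed)
    spec = spec or PlaceTuningSpec()
    centers, widths, peaks = synth_place_cells(n_cells, path_length, spec, rng)
    lam = _tuning_rates(s, centers, widths, peaks, spec.baseline_rate_hz)
    dt = 1.0 / sample_rate
    spikes = rng.poisson(lam * dt).astype(float) if poisson else lam * dt
    decay = np.exp(-dt / calcium_decay)
    ca = np.empty_like(spikes)
    acc = np.zeros(n_cells)
    for k in range(spikes.shape[0]):
        acc = acc * decay + spikes[k]
        ca[k] = acc
    neu = neuropil_amp * rng.standard_normal(spikes.shape[0])[:, None] * np.ones((1, n_cells))
    F_cell = baseline_f + 20.0 * ca + noise_sd * rng.standard_normal(spikes.shape)
    F_neu = baseline_f * 0.5 + neu
    morph = np.column_stack(
        [
            rng.integers(50, 300, n_cells).astype(float),
            rng.uniform(0.8, 1.3, n_cells),
            rng.uniform(8, 15, n_cells),
        ]
    )
    session = FluorSession(
        F_cell=F_cell, F_neu=F_neu, sample_rate=sample_rate, morphology=morph
    )
    return session, lam, (centers, widths, peaks)
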