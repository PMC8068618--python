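"""Gait time-series analysis: stride segmentation, stride-time variability,
and local dynamic stability (LDS) via the largest Lyapunov exponent (LLE).

Pipeline for one 6-minute hallway walk recorded with a foot-mounted gyro:

1. :func:`apply_exclusions` — drop the first and last 25 m bout, trim the
   first and last 2.5 m of every remaining bout (distance mapped linearly to
   time within a bout), and drop samples flagged non-stationary.
2. :func:`detect_strides` — stride events at prominent sagittal-plane
   angular-velocity peaks; stride times between consecutive events within a
   bout.
3. :func:`time_normalize_strides` — the first 63 complete strides, each
   linearly resampled to 100 samples per channel (6300 samples total), so
   that stride-duration differences are expressed on a common phase axis.
4. :func:`delay_embed` — multichannel delay embedding (3 channels x 5
   delayed copies = 15 state dimensions at the default tau = 11).
5. :func:`rosenstein_lle` — mean log divergence of nearest state-space
   neighbours vs. time, with the LLE as the slope of the initial (0-0.5
   stride) segment, in nats per stride.

Higher LLE = faster local divergence = lower dynamic stability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    ValidationError,
)
from .io_model import GyroTrace

logger = logging.getLogger(__name__)

__all__ = [
    "StrideSeries",
    "EmbeddingParams",
    "LleResult",
    "GaitConfig",
    "apply_exclusions",
    "detect_strides",
    "stride_time_stats",
    "time_normalize_strides",
    "ami_curve",
    "ami_first_minimum",
    "fnn_fractions",
    "fnn_dimension",
    "delay_embed",
    "rosenstein_lle",
    "gait_lds_pipeline",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class StrideSeries:
    """Detected stride events and the stride times between them.

    ``event_indices`` are global sample indices of stride-start events;
    ``stride_bounds`` pairs consecutive events that belong to the same
    walking bout (strides never span a bout boundary).
    """

    event_indices: np.ndarray
    stride_bounds: list[tuple[int, int]]
    stride_times: np.ndarray
    source_fs: float

    def __post_init__(self) -> None:
        self.event_indices = np.asarray(self.event_indices, dtype=int)
        self.stride_times = np.asarray(self.stride_times, dtype=float)
        if np.any(np.diff(self.event_indices) <= 0):
            raise ValidationError("event indices must be strictly increasing")
        if np.any(self.stride_times <= 0):
            raise ValidationError("stride times must be positive")

    @property
    def n_strides(self) -> int:
        return len(self.stride_bounds)


@dataclass
class EmbeddingParams:
    """Delay-embedding bookkeeping: tau (samples), delayed copies per
    channel, and the resulting total state dimension."""

    tau: int
    d_per_channel: int
    total_dim: int

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValidationError("tau must be >= 1")
        if self.total_dim < 2:
            raise ValidationError("total embedding dimension must be >= 2")


@dataclass
class LleResult:
    """Largest Lyapunov exponent with its divergence curve and provenance."""

    lle: float
    divergence_curve: np.ndarray  # mean log distance per step
    fit_range: tuple[int, int]
    embedding: EmbeddingParams
    n_state_vectors: int
    params_mode: str = "fixed"  # "fixed" or "auto"


@dataclass
class GaitConfig:
    """Tunable parameters of the gait pipeline.

    ``tau``/``d_per_channel`` set to None trigger automatic selection via
    the first AMI minimum and FNN analysis of the sagittal channel.
    """

    sagittal_channel: int = 0
    min_separation_s: float = 0.4
    prominence: float = 2.0
    n_strides: int = 63
    samples_per_stride: int = 100
    tau: int | None = 11
    d_per_channel: int | None = 5
    theiler: int = 100            # one stride at 100 samples/stride
    fit_range: tuple[int, int] = (0, 50)  # 0-0.5 stride
    hallway_length_m: float = 25.0
    edge_trim_m: float = 2.5
    run_exclusions: bool = True
    ami_max_lag: int = 50
    ami_bins: int = 16
    fnn_max_dim: int = 8
    fnn_rtol: float = 15.0
    fnn_atol_factor: float = 2.0


# ---------------------------------------------------------------------------
# exclusion windows
# ---------------------------------------------------------------------------

def apply_exclusions(
    trace: GyroTrace,
    hallway_length: float = 25.0,
    edge_trim: float = 2.5,
) -> GyroTrace:
    """Remove warm-up/cool-down and turning data from a hallway walk.

    Drops the first and the last full bout, trims ``edge_trim`` metres off
    both ends of every remaining bout (distance assumed linear in time
    within a bout), and removes samples flagged in ``exclusion_mask``.
    """
    if len(trace.bouts) < 3:
        raise InsufficientDataError(
            f"need >= 3 bouts to exclude first and last, got {len(trace.bouts)}"
        )
    frac = edge_trim / hallway_length
    if not 0 <= frac < 0.5:
        raise ValidationError("edge trim must be less than half the hallway")

    keep_chunks: list[np.ndarray] = []
    new_bouts: list[tuple[int, int]] = []
    pos = 0
    for s, e in trace.bouts[1:-1]:
        n = e - s
        trim = int(round(frac * n))
        idx = np.arange(s + trim, e - trim)
        idx = idx[~trace.exclusion_mask[idx]]
        if len(idx) == 0:
            continue
        keep_chunks.append(idx)
        new_bouts.append((pos, pos + len(idx)))
        pos += len(idx)
    if not keep_chunks:
        raise InsufficientDataError("no samples survive the exclusion windows")
    idx_all = np.concatenate(keep_chunks)
    return GyroTrace(
        t=trace.t[idx_all],
        w=trace.w[idx_all],
        fs=trace.fs,
        bouts=new_bouts,
        exclusion_mask=np.zeros(len(idx_all), dtype=bool),
    )


# ---------------------------------------------------------------------------
# stride segmentation and stride-time variability
# ---------------------------------------------------------------------------

def detect_strides(
    trace: GyroTrace,
    channel: int = 0,
    min_separation_s: float = 0.4,
    prominence: float = 2.0,
) -> StrideSeries:
    """Detect stride-start events at prominent sagittal gyro peaks.

    Peak picking runs per bout (whole trace if no bouts are annotated) with
    a minimum separation of ``min_separation_s`` seconds; stride times are
    formed only between consecutive events of the same bout.
    """
    x = trace.w[:, channel]
    distance = max(1, int(round(min_separation_s * trace.fs)))
    ranges = trace.bouts if trace.bouts else [(0, len(x))]

    events: list[int] = []
    bounds: list[tuple[int, int]] = []
    for s, e in ranges:
        peaks, _ = find_peaks(x[s:e], distance=distance, prominence=prominence)
        peaks = peaks + s
        events.extend(int(p) for p in peaks)
        bounds.extend((int(peaks[i]), int(peaks[i + 1])) for i in range(len(peaks) - 1))
    if len(events) < 2:
        raise DegenerateInputError("fewer than 2 stride events detected")
    stride_times = np.array([(e - s) / trace.fs for s, e in bounds])
    return StrideSeries(
        event_indices=np.array(events),
        stride_bounds=bounds,
        stride_times=stride_times,
        source_fs=trace.fs,
    )


def stride_time_stats(series: StrideSeries) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1) of stride times, seconds."""
    st = series.stride_times
    if len(st) < 2:
        raise ValidationError("need at least 2 stride times")
    return float(np.mean(st)), float(np.std(st, ddof=1))


def time_normalize_strides(
    trace: GyroTrace,
    series: StrideSeries,
    n_strides: int = 63,
    samples_per_stride: int = 100,
) -> np.ndarray:
    """Resample the first ``n_strides`` strides to a common phase axis.

    Each stride is linearly interpolated to ``samples_per_stride`` points
    per channel and the strides are concatenated, giving an
    (n_strides * samples_per_stride, 3) array — 6300 x 3 at the defaults.
    """
    if series.n_strides < n_strides:
        raise InsufficientDataError(
            f"need {n_strides} strides, only {series.n_strides} available"
        )
    target = np.linspace(0.0, 1.0, samples_per_stride, endpoint=False)
    out = np.empty((n_strides * samples_per_stride, trace.w.shape[1]))
    for k, (s, e) in enumerate(series.stride_bounds[:n_strides]):
        src = np.arange(e - s) / (e - s)
        seg = trace.w[s:e]
        row = k * samples_per_stride
        for c in range(seg.shape[1]):
            out[row:row + samples_per_stride, c] = np.interp(target, src, seg[:, c])
    return out


# ---------------------------------------------------------------------------
# embedding-parameter selection
# ---------------------------------------------------------------------------

def ami_curve(x: np.ndarray, max_lag: int, n_bins: int = 16) -> np.ndarray:
    """Average mutual information I(tau) for tau = 1..max_lag (nats),
    estimated with equiprobable (rank-based) bins."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has no mutual information")
    if n_bins < 2:
        raise ValidationError("need at least 2 bins")
    if len(x) <= max_lag + 1:
        raise ValidationError("series too short for the requested max_lag")
    ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    bins = np.minimum((ranks * n_bins) // len(x), n_bins - 1)
    out = np.empty(max_lag)
    for tau in range(1, max_lag + 1):
        a, b = bins[:-tau], bins[tau:]
        joint = np.bincount(a * n_bins + b, minlength=n_bins * n_bins).astype(float)
        joint = joint.reshape(n_bins, n_bins) / len(a)
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        nz = joint > 0
        out[tau - 1] = np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz]))
    return out


def ami_first_minimum(
    x: np.ndarray, max_lag: int = 50, n_bins: int = 16, window: int = 3
) -> int:
    """First local minimum of the AMI curve — the conventional embedding delay.

    A lag tau counts as a local minimum if I(tau) is strictly smaller than
    I at every lag within ``window`` on both sides (the window guards
    against estimator jitter on flat valleys; window = 1 is the textbook
    rule).  If the curve never turns upward, the global argmin is returned
    with a warning.
    """
    ami = ami_curve(x, max_lag, n_bins)
    for i in range(max_lag):
        if i + window >= max_lag:
            break
        lo = max(0, i - window)
        neigh = np.r_[ami[lo:i], ami[i + 1:i + window + 1]]
        if np.all(ami[i] < neigh):
            return i + 1
    lag = int(np.argmin(ami)) + 1
    warnings.warn(
        f"AMI has no local minimum up to lag {max_lag}; returning argmin {lag}",
        stacklevel=2,
    )
    return lag


def fnn_fractions(
    x: np.ndarray,
    tau: int,
    max_dim: int = 8,
    rtol: float = 15.0,
    atol_factor: float = 2.0,
) -> np.ndarray:
    """False-nearest-neighbour fraction for dimensions 1..max_dim.

    Kennel criteria: a neighbour pair (i, j) in dimension d is false if the
    extra coordinate added at dimension d+1 grows the distance by more than
    ``rtol`` relative to the d-dimensional distance, or if the (d+1)-distance
    exceeds ``atol_factor`` times the attractor size (std of the series).
    """
    from scipy.spatial import cKDTree

    x = np.asarray(x, dtype=float)
    sigma = float(np.std(x))
    if sigma == 0:
        raise DegenerateInputError("constant series cannot be embedded")
    n = len(x)
    if n <= (max_dim + 1) * tau + 1:
        raise ValidationError("series too short for the requested max_dim")

    fracs = np.empty(max_dim)
    for d in range(1, max_dim + 1):
        m = n - d * tau  # vectors with an extension coordinate available
        emb = np.column_stack([x[j * tau:j * tau + m] for j in range(d)])
        tree = cKDTree(emb)
        dist, idx = tree.query(emb, k=2)
        rd, nb = dist[:, 1], idx[:, 1]
        ext = np.abs(x[np.arange(m) + d * tau] - x[nb + d * tau])
        rd1 = np.sqrt(rd**2 + ext**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(rd > 0, ext / np.where(rd > 0, rd, 1.0), 0.0)
        false = (ratio > rtol) | (rd1 / sigma > atol_factor)
        fracs[d - 1] = float(np.mean(false))
    return fracs


def fnn_dimension(
    x: np.ndarray,
    tau: int,
    max_dim: int = 8,
    rtol: float = 15.0,
    atol_factor: float = 2.0,
    threshold: float = 0.01,
) -> int:
    """Smallest dimension whose false-neighbour fraction drops below
    ``threshold`` (default 1%); ``max_dim`` with a warning if never reached."""
    fracs = fnn_fractions(x, tau, max_dim, rtol, atol_factor)
    below = np.nonzero(fracs < threshold)[0]
    if len(below):
        return int(below[0]) + 1
    warnings.warn(
        f"FNN fraction never fell below {threshold:.0%} up to dim {max_dim} "
        f"(min {fracs.min():.3f}); returning max_dim",
        stacklevel=2,
    )
    return max_dim


# ---------------------------------------------------------------------------
# delay embedding and the Rosenstein exponent
# ---------------------------------------------------------------------------

def delay_embed(series: np.ndarray, tau: int, d_per_channel: int) -> np.ndarray:
    """Multichannel delay embedding.

    For a (n, k) series, state vectors at times t = (d-1)*tau .. n-1 hold
    [w_c(t - j*tau)] for every channel c and delay j = 0..d-1, giving
    n - (d-1)*tau vectors of dimension k*d.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    n, k = series.shape
    if tau < 1 or d_per_channel < 1:
        raise ValidationError("tau and d_per_channel must be >= 1")
    span = (d_per_channel - 1) * tau
    if n <= span:
        raise ValidationError(
            f"series of length {n} too short for (d-1)*tau = {span}"
        )
    m = n - span
    cols = [
        series[span - j * tau: span - j * tau + m, c]
        for c in range(k)
        for j in range(d_per_channel)
    ]
    return np.column_stack(cols)


def _nearest_neighbors(states: np.ndarray, theiler: int) -> np.ndarray:
    """Index of each state's nearest Euclidean neighbour outside the Theiler
    window (|i - j| > theiler).  Brute force in blocks."""
    n = len(states)
    sq = np.einsum("ij,ij->i", states, states)
    nn = np.empty(n, dtype=int)
    block = 512
    for s in range(0, n, block):
        e = min(s + block, n)
        d2 = sq[s:e, None] + sq[None, :] - 2.0 * states[s:e] @ states.T
        for r in range(s, e):
            lo = max(0, r - theiler)
            hi = min(n, r + theiler + 1)
            d2[r - s, lo:hi] = np.inf
        nn[s:e] = np.argmin(d2, axis=1)
        if not np.all(np.isfinite(d2[np.arange(e - s), nn[s:e] ])):
            raise DegenerateInputError(
                "no valid neighbour outside the Theiler window"
            )
    return nn


def rosenstein_lle(
    states: np.ndarray,
    fs_effective: float = 1.0,
    theiler: int = 0,
    fit_range: tuple[int, int] = (0, 50),
    max_steps: int | None = None,
) -> LleResult:
    """Largest Lyapunov exponent from a state matrix (Rosenstein method).

    Each state is paired with its nearest neighbour outside the Theiler
    window; the divergence curve is the mean natural-log distance of the
    surviving pairs after k steps (pairs that run off the end of the series
    drop out of the mean).  The LLE is the least-squares slope of the curve
    over ``fit_range`` (inclusive endpoints, in steps), multiplied by
    ``fs_effective`` to express it per time/stride/iteration unit.
    """
    states = np.asarray(states, dtype=float)
    n = len(states)
    if n < 10:
        raise ValidationError("too few state vectors")
    if theiler < 0:
        raise ValidationError("theiler must be >= 0")
    k0, k1 = fit_range
    if not 0 <= k0 < k1:
        raise ValidationError("fit_range must satisfy 0 <= start < end")
    if max_steps is None:
        max_steps = k1
    if max_steps < k1:
        raise ValidationError("max_steps must cover the fit range")
    if theiler >= n - 1:
        raise DegenerateInputError("Theiler window leaves no candidate pairs")

    nn = _nearest_neighbors(states, theiler)
    i_idx = np.arange(n)
    # floor for exact recurrences: an exactly periodic orbit then yields a
    # flat curve and a zero exponent rather than log(0)
    scale = float(np.mean(np.linalg.norm(states, axis=1))) or 1.0
    floor = 1e-12 * scale
    curve = np.full(max_steps + 1, np.nan)
    for k in range(max_steps + 1):
        valid = (i_idx + k < n) & (nn + k < n)
        if valid.sum() == 0:
            break
        d = np.linalg.norm(states[i_idx[valid] + k] - states[nn[valid] + k], axis=1)
        curve[k] = float(np.mean(np.log(np.maximum(d, floor))))
    seg = curve[k0:k1 + 1]
    if not np.all(np.isfinite(seg)):
        raise DegenerateInputError("divergence curve not finite over fit range")
    steps = np.arange(k0, k1 + 1, dtype=float)
    slope = float(np.polyfit(steps, seg, 1)[0])
    dim = states.shape[1]
    return LleResult(
        lle=slope * fs_effective,
        divergence_curve=curve[np.isfinite(curve)],
        fit_range=(k0, k1),
        embedding=EmbeddingParams(tau=1, d_per_channel=dim, total_dim=dim),
        n_state_vectors=n,
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def gait_lds_pipeline(trace: GyroTrace, config: GaitConfig | None = None) -> LleResult:
    """Local dynamic stability of one walking trial, in nats per stride.

    Runs exclusions (when bouts are annotated and ``run_exclusions`` is on),
    stride detection, 63-stride time normalisation, delay embedding with the
    configured (tau, d) or AMI/FNN-selected values, and the Rosenstein fit.
    """
    cfg = config or GaitConfig()
    work = trace
    if cfg.run_exclusions and len(trace.bouts) >= 3:
        work = apply_exclusions(trace, cfg.hallway_length_m, cfg.edge_trim_m)
    strides = detect_strides(
        work, cfg.sagittal_channel, cfg.min_separation_s, cfg.prominence
    )
    normalized = time_normalize_strides(
        work, strides, cfg.n_strides, cfg.samples_per_stride
    )

    mode = "fixed"
    tau, d_per_channel = cfg.tau, cfg.d_per_channel
    if tau is None or d_per_channel is None:
        mode = "auto"
        ref = normalized[:, cfg.sagittal_channel]
        if tau is None:
            tau = ami_first_minimum(ref, cfg.ami_max_lag, cfg.ami_bins)
        if d_per_channel is None:
            d_per_channel = max(
                2,
                fnn_dimension(ref, tau, cfg.fnn_max_dim, cfg.fnn_rtol,
                              cfg.fnn_atol_factor),
            )
    states = delay_embed(normalized, tau, d_per_channel)
    result = rosenstein_lle(
        states,
        fs_effective=float(cfg.samples_per_stride),
        theiler=cfg.theiler,
        fit_range=cfg.fit_range,
    )
    result.embedding = EmbeddingParams(
        tau=tau,
        d_per_channel=d_per_channel,
        total_dim=normalized.shape[1] * d_per_channel,
    )
    result.params_mode = mode
    logger.info(
        "LDS pipeline: %d strides detected, embedding (tau=%d, d=%d, dim=%d, %s), "
        "lle=%.4f per stride",
        strides.n_strides, tau, d_per_channel, result.embedding.total_dim,
        mode, result.lle,
    )
    return result
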