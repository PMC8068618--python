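"""Synthetic cohorts with a latent exercise factor and known ground truth.

The generator emulates the four measurement streams of a sensorimotor study
of blind/visually-impaired (BVI) vs. sighted children — centre-of-pressure
traces, foot gyro traces, triangle-completion trials, activity scores — so
that every pipeline stage can be validated against known generating values.

Structure: each participant carries a latent "exercise" factor
``E_i ~ lognormal(mu_g, sigma)`` with a group-specific location (sedentary
shift for the BVI group).  The group-standardised latent
``z_i = (log E_i - mu_g) / sigma`` loads on every outcome with a fixed sign
(negative for sway area, stride-time variability, LLE and navigation
errors; positive for single-leg stance time), inducing the within-group
correlation structure the analysis layer is meant to recover.  Outcomes can
be materialised either directly at the dv level or as raw traces pushed
through the actual measurement pipeline.

All generated magnitudes are plausible for paediatric posturography/gait
testing (sway areas of order 10 cm^2, stride times near 1.1 s, navigation
errors of tens of cm / degrees) but claim no match to any particular
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import ValidationError
from .io_model import (
    GROUP_BVI,
    GROUP_SIGHTED,
    CohortTable,
    CopTrace,
    GyroTrace,
    ParticipantRecord,
    build_cohort,
)
from . import gait_dynamics as gd
from . import navigation as nav
from . import posturography as post
from .io_model import TriangleTrial

__all__ = [
    "DvParams",
    "SynthConfig",
    "GroundTruth",
    "default_stride_template",
    "gen_cop",
    "gen_gait",
    "gen_triangle_trials",
    "gen_cohort",
]

_CHI2_95_2D = 5.991464547107979  # chi2.ppf(0.95, 2), large-n PEA factor


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DvParams:
    """Latent-to-outcome mapping for one outcome field.

    value = base + group_offset * [BVI] + loading * z + Normal(0, noise_sd),
    clipped to [clip_lo, clip_hi].
    """

    base: float
    group_offset: float
    loading: float
    noise_sd: float
    clip_lo: float = 0.0
    clip_hi: float = np.inf

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


def _default_dv_params() -> dict[str, DvParams]:
    return {
        # sway areas, cm^2
        "pea_bipedal_ec": DvParams(4.0, 7.0, -1.5, 2.2, clip_lo=0.3),
        "pea_semitandem_ec": DvParams(7.5, 7.0, -2.0, 3.0, clip_lo=0.3),
        "pea_bipedal_eo": DvParams(2.0, 0.0, -0.6, 0.8, clip_lo=0.3),
        "pea_semitandem_eo": DvParams(3.0, 0.0, -0.8, 1.0, clip_lo=0.3),
        # single-leg stance, s (20 s trial cap)
        "sls_time": DvParams(12.0, -5.6, 2.5, 3.0, clip_lo=0.0, clip_hi=20.0),
        # stride-time variability, s
        "stride_time_sd_ec": DvParams(0.030, 0.010, -0.006, 0.0045, clip_lo=0.008),
        "stride_time_sd_eo": DvParams(0.020, 0.0, -0.004, 0.003, clip_lo=0.006),
        # local dynamic stability, nats/stride (magnitudes as produced by
        # the Rosenstein pipeline on the synthetic gait traces)
        "lle_ec": DvParams(0.60, 0.12, -0.08, 0.10, clip_lo=0.05),
        "lle_eo": DvParams(0.45, 0.0, -0.06, 0.08, clip_lo=0.05),
        # triangle completion, degrees / cm
        "angle_error": DvParams(18.0, 6.1, -5.0, 8.0, clip_lo=0.5),
        "distance_error": DvParams(45.0, 2.2, -12.0, 14.0, clip_lo=1.0),
        # everyday activity, min/week (independent of the exercise factor)
        "basic_activity": DvParams(420.0, -120.0, 0.0, 150.0, clip_lo=0.0),
    }


@dataclass
class SynthConfig:
    """Cohort-generator configuration (see module docstring for the model)."""

    n_per_group: int = 14
    seed: int | None = None
    # latent exercise factor, minutes/week on the log scale
    log_exercise_mu: dict[str, float] = field(
        default_factory=lambda: {GROUP_BVI: float(np.log(150.0)),
                                 GROUP_SIGHTED: float(np.log(270.0))}
    )
    log_exercise_sigma: float = 0.4
    dv_params: dict[str, DvParams] = field(default_factory=_default_dv_params)
    # trace-level parameters
    cop_theta: float = 1.0          # OU mean reversion, 1/s
    cop_trials: int = 3
    cop_duration_s: float = 30.0
    cop_fs: float = 180.0
    gait_n_strides: int = 150
    gait_stride_time_mean: float = 1.1
    gait_noise_sd: float = 0.1      # rad/s additive sensor noise
    gait_fs: float = 100.0
    triangle_turn_sd_deg: float = 3.0
    triangle_dist_sd_frac: float = 0.02
    compute_lle: bool = False       # run the full LDS pipeline at trace level

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("need at least 2 participants per group")
        if self.log_exercise_sigma <= 0:
            raise ValidationError("latent sigma must be positive")

    @classmethod
    def null(cls, n_per_group: int = 14, seed: int | None = None) -> "SynthConfig":
        """A cohort with every effect nulled: no group offsets, no latent
        loadings, and equal outcome means across the conditions of each
        variable — so every test in the analysis report is under its null."""
        cfg = cls(n_per_group=n_per_group, seed=seed)
        mu = float(np.mean(list(cfg.log_exercise_mu.values())))
        cfg.log_exercise_mu = {GROUP_BVI: mu, GROUP_SIGHTED: mu}
        for p in cfg.dv_params.values():
            p.group_offset = 0.0
            p.loading = 0.0
        for name in ("pea_semitandem_ec", "pea_bipedal_eo", "pea_semitandem_eo"):
            cfg.dv_params[name].base = cfg.dv_params["pea_bipedal_ec"].base
        cfg.dv_params["stride_time_sd_eo"].base = cfg.dv_params["stride_time_sd_ec"].base
        cfg.dv_params["lle_eo"].base = cfg.dv_params["lle_ec"].base
        # mean of the lognormal exercise score, so the activity condition
        # contrast is null as well
        cfg.dv_params["basic_activity"].base = float(
            np.exp(mu + cfg.log_exercise_sigma**2 / 2.0)
        )
        return cfg


@dataclass
class GroundTruth:
    """Generating values per participant: the latent factor and the noise-free
    outcome targets the traces were synthesised from."""

    latent: pd.DataFrame          # participant_id, group, exercise, z
    dv_targets: pd.DataFrame      # participant_id x outcome-field targets
    details: dict = field(default_factory=dict)  # per-participant extras


# ---------------------------------------------------------------------------
# trace generators
# ---------------------------------------------------------------------------

def gen_cop(
    theta: float,
    sigma: float,
    duration_s: float = 30.0,
    fs: float = 180.0,
    seed: int | np.random.Generator | None = None,
) -> CopTrace:
    """2-D Ornstein-Uhlenbeck centre-of-pressure trace (exact discretisation).

    dX = -theta X dt + sigma dW per axis, stationary per-axis standard
    deviation sigma / sqrt(2 theta).  The process starts in its stationary
    distribution.
    """
    if theta <= 0 or sigma <= 0:
        raise ValidationError("theta and sigma must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration_s * fs))
    dt = 1.0 / fs
    alpha = np.exp(-theta * dt)
    s_stat = sigma / np.sqrt(2.0 * theta)
    q = s_stat * np.sqrt(1.0 - alpha**2)  # innovation sd
    xy = np.empty((n, 2))
    for c in range(2):
        e = rng.normal(0.0, q, size=n)
        x0 = rng.normal(0.0, s_stat)
        # AR(1) recursion x[k] = alpha x[k-1] + e[k] via an IIR filter
        xy[:, c], _ = lfilter([1.0], [1.0, -alpha], e, zi=np.array([alpha * x0]))
    t = np.arange(n) / fs
    return CopTrace(t=t, x=xy[:, 0], y=xy[:, 1], fs=fs)


def default_stride_template(samples: int = 100) -> np.ndarray:
    """A smooth 3-channel foot angular-velocity stride template (rad/s).

    Channel 0 (sagittal) carries one dominant swing peak early in the
    stride plus smaller stance-phase undulations; channels 1-2 are low-
    amplitude frontal/transverse oscillations.
    """
    ph = np.arange(samples) / samples
    c0 = (
        4.0 * np.exp(-((ph - 0.08) / 0.045) ** 2)
        - 1.0 * np.exp(-((ph - 0.50) / 0.15) ** 2)
        + 0.6 * np.exp(-((ph - 0.85) / 0.06) ** 2)
    )
    c1 = 0.8 * np.sin(2 * np.pi * ph) + 0.3 * np.sin(4 * np.pi * ph + 0.7)
    c2 = 0.5 * np.sin(2 * np.pi * ph + 1.1) + 0.2 * np.sin(6 * np.pi * ph)
    return np.column_stack([c0, c1, c2])


def gen_gait(
    stride_template: np.ndarray | None = None,
    n_strides: int = 70,
    stride_time_mean: float = 1.1,
    stride_time_sd: float = 0.03,
    noise_sd: float = 0.1,
    fs: float = 100.0,
    seed: int | np.random.Generator | None = None,
    n_bouts: int = 1,
) -> tuple[GyroTrace, dict]:
    """Synthetic walking trial: a stride template repeated with jittered
    timing, time-warped per stride, plus additive sensor noise.

    Each stride's two halves receive independent Gaussian duration jitter
    (sd = stride_time_sd / sqrt(2) each, truncated at 0.15 s), so total
    stride times have sd ``stride_time_sd`` while the internal phase
    structure varies from stride to stride — the within-stride timing
    irregularity that degrades local dynamic stability.

    Returns the trace and a ground-truth dict with the true per-stride
    times, stride start indices, and noise-free peak (event) indices.
    """
    if n_strides < 2:
        raise ValidationError("need at least 2 strides")
    if stride_time_mean <= 0.3:
        raise ValidationError("stride_time_mean must exceed 0.3 s")
    if stride_time_sd < 0 or noise_sd < 0:
        raise ValidationError("stride_time_sd and noise_sd must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    template = default_stride_template() if stride_template is None else np.asarray(stride_template, float)
    n_tpl = len(template)
    half = n_tpl // 2

    halves_sd = stride_time_sd / np.sqrt(2.0)
    segs: list[np.ndarray] = []
    starts: list[int] = []
    peaks: list[int] = []
    durations_s: list[float] = []
    pos = 0
    tpl_peak = int(np.argmax(template[:, 0]))
    for _ in range(n_strides):
        a = max(0.15, rng.normal(stride_time_mean / 2.0, halves_sd))
        b = max(0.15, rng.normal(stride_time_mean / 2.0, halves_sd))
        na = max(2, int(round(a * fs)))
        nb = max(2, int(round(b * fs)))
        first = _resample(template[:half], na)
        second = _resample(template[half:], nb)
        stride = np.vstack([first, second])
        starts.append(pos)
        # noise-free event location: the dominant sagittal peak of the warped stride
        if tpl_peak < half:
            peaks.append(pos + int(np.argmax(first[:, 0])))
        else:
            peaks.append(pos + na + int(np.argmax(second[:, 0])))
        durations_s.append((na + nb) / fs)
        segs.append(stride)
        pos += na + nb

    w = np.vstack(segs)
    if noise_sd > 0:
        w = w + rng.normal(0.0, noise_sd, size=w.shape)
    n = len(w)
    bouts = []
    if n_bouts > 1:
        stride_of_bout = np.array_split(np.arange(n_strides), n_bouts)
        ends = starts + [n]
        for chunk in stride_of_bout:
            bouts.append((ends[chunk[0]], ends[chunk[-1] + 1]))
    truth = {
        "stride_times": np.array(durations_s),
        "stride_starts": np.array(starts),
        "event_indices": np.array(peaks),
    }
    trace = GyroTrace(t=np.arange(n) / fs, w=w, fs=fs, bouts=bouts)
    return trace, truth


def _resample(seg: np.ndarray, n_out: int) -> np.ndarray:
    src = np.arange(len(seg)) / len(seg)
    dst = np.arange(n_out) / n_out
    return np.column_stack([np.interp(dst, src, seg[:, c]) for c in range(seg.shape[1])])


def gen_triangle_trials(
    turn_bias_deg: float = 0.0,
    turn_sd_deg: float = 5.0,
    dist_gain: float = 1.0,
    dist_sd_frac: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> list[TriangleTrial]:
    """The standard 4-trial sequence with a parameterised homing response.

    Produced turn = correct turn + bias + Normal(0, turn_sd); produced
    homing length = |A - C| * gain * (1 + Normal(0, dist_sd_frac)).
    """
    if dist_gain <= 0:
        raise ValidationError("dist_gain must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    trials = []
    for spec, direction in nav.standard_trial_sequence():
        base = spec.as_trial(P=spec.A, direction=direction)  # mirrored layout
        A, B, C = base.A, base.B, base.C
        incoming = C - B
        h = A - C
        correct = np.degrees(np.arctan2(incoming[0] * h[1] - incoming[1] * h[0],
                                        np.dot(incoming, h)))
        produced = correct + turn_bias_deg + rng.normal(0.0, turn_sd_deg)
        L = float(np.linalg.norm(A - C)) * dist_gain * (1.0 + rng.normal(0.0, dist_sd_frac))
        L = max(L, 1.0)
        ang = np.radians(produced)
        u = incoming / np.linalg.norm(incoming)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        P = C + L * (rot @ u)
        trials.append(TriangleTrial(A=A, B=B, C=C, P=P, direction=direction,
                                    triangle_id=spec.triangle_id))
    return trials


# ---------------------------------------------------------------------------
# whole-cohort generation
# ---------------------------------------------------------------------------

_PEA_FIELDS = ("pea_bipedal_ec", "pea_semitandem_ec", "pea_bipedal_eo",
               "pea_semitandem_eo")
_EO_FIELDS = ("pea_bipedal_eo", "pea_semitandem_eo", "stride_time_sd_eo", "lle_eo")


def gen_cohort(
    config: SynthConfig,
    level: Literal["dv", "trace"] = "dv",
    keep_traces: bool = False,
) -> tuple[CohortTable, dict, GroundTruth]:
    """Generate a full cohort.

    ``level="dv"`` draws every outcome directly from the latent model —
    fast, for statistical calibration.  ``level="trace"`` synthesises raw
    CoP, gait, and triangle data whose generating parameters hit the same
    targets and runs the actual measurement pipeline (prediction-ellipse
    fit, stride detection and stride-time statistics, trial scoring) to
    produce the recorded outcomes; the LLE outcome stays at the dv level
    unless ``config.compute_lle`` is set.

    Returns (cohort table, traces dict, ground truth).  The traces dict is
    populated only when ``keep_traces`` is true.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ParticipantRecord] = []
    latent_rows = []
    target_rows = []
    traces: dict[str, dict] = {}

    n = config.n_per_group
    roster = [(GROUP_BVI, f"b{i:03d}", f"s{i:03d}") for i in range(n)] + \
             [(GROUP_SIGHTED, f"s{i:03d}", f"b{i:03d}") for i in range(n)]

    for group, pid, match in roster:
        z = rng.standard_normal()
        exercise = float(np.exp(config.log_exercise_mu[group]
                                + config.log_exercise_sigma * z))
        latent_rows.append({"participant_id": pid, "group": group,
                            "exercise": exercise, "z": z})
        is_bvi = group == GROUP_BVI
        targets: dict[str, float] = {}
        values: dict[str, float] = {}
        for name, p in config.dv_params.items():
            if not is_bvi or name not in _EO_FIELDS:
                mean = p.base + (p.group_offset if is_bvi else 0.0) + p.loading * z
                targets[name] = float(np.clip(mean, p.clip_lo, p.clip_hi))
                values[name] = float(np.clip(mean + rng.normal(0.0, p.noise_sd),
                                             p.clip_lo, p.clip_hi))
        target_rows.append({"participant_id": pid, **targets})

        if level == "trace":
            values, ptraces = _measure_from_traces(config, values, rng)
            if keep_traces:
                traces[pid] = ptraces

        rec = ParticipantRecord(
            id=pid, group=group, match_id=match,
            basic_activity=values.pop("basic_activity"),
            exercise=exercise,
            **{_field_name(k): v for k, v in values.items()},
        )
        records.append(rec)

    cohort = build_cohort(records)
    truth = GroundTruth(
        latent=pd.DataFrame(latent_rows),
        dv_targets=pd.DataFrame(target_rows),
    )
    return cohort, traces, truth


def _field_name(key: str) -> str:
    return key  # dv_params keys coincide with ParticipantRecord field names


def _measure_from_traces(config: SynthConfig, values: dict,
                         rng: np.random.Generator) -> tuple[dict, dict]:
    """Replace dv-level draws with pipeline measurements of synthetic traces.

    Each participant's realised dv draw (latent effect plus unexplained
    individual variation) becomes the generating parameter of their traces;
    the measurement pipeline then adds only estimation noise."""
    out = dict(values)
    targets = values
    ptraces: dict = {"cop": {}, "gait": {}, "triangles": None}

    # --- posturography: OU traces with per-axis sd hitting the target area
    for name in _PEA_FIELDS:
        if name not in targets:
            continue
        area = targets[name]
        s_axis = np.sqrt(area / (np.pi * _CHI2_95_2D))
        sigma = s_axis * np.sqrt(2.0 * config.cop_theta)
        results = []
        trial_traces = []
        for _ in range(config.cop_trials):
            tr = gen_cop(config.cop_theta, sigma, config.cop_duration_s,
                         config.cop_fs, rng)
            results.append(post.compute_pea(tr))
            trial_traces.append(tr)
        out[name] = post.mean_pea(results)
        ptraces["cop"][name] = trial_traces

    # --- gait: stride-time sd from detected strides of a synthetic walk
    for cond, sd_field, lle_field in (("ec", "stride_time_sd_ec", "lle_ec"),
                                      ("eo", "stride_time_sd_eo", "lle_eo")):
        if sd_field not in targets:
            continue
        trace, truth = gen_gait(
            n_strides=config.gait_n_strides,
            stride_time_mean=config.gait_stride_time_mean,
            stride_time_sd=targets[sd_field],
            noise_sd=config.gait_noise_sd,
            fs=config.gait_fs,
            seed=rng,
        )
        strides = gd.detect_strides(trace)
        _, sd_est = gd.stride_time_stats(strides)
        out[sd_field] = sd_est
        if config.compute_lle and lle_field in targets:
            res = gd.gait_lds_pipeline(trace, gd.GaitConfig(run_exclusions=False))
            out[lle_field] = res.lle
        ptraces["gait"][cond] = trace

    # --- navigation: biased/noisy homing hitting the target mean errors
    if "angle_error" in targets and "distance_error" in targets:
        homing = 300.0  # |A - C| of both reference triangles, cm
        trials = gen_triangle_trials(
            turn_bias_deg=-targets["angle_error"],
            turn_sd_deg=config.triangle_turn_sd_deg,
            dist_gain=max(0.05, 1.0 - targets["distance_error"] / homing),
            dist_sd_frac=config.triangle_dist_sd_frac,
            seed=rng,
        )
        scores = [nav.score_trial(t) for t in trials]
        ang, dist = nav.summarize_trials(scores)
        out["angle_error"] = ang
        out["distance_error"] = dist
        ptraces["triangles"] = trials
    return out, ptraces
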