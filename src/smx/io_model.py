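"""Domain types, file readers/writers, and simple per-participant aggregations.

Units are fixed throughout the package: centimetres for centre-of-pressure
(CoP) displacement and triangle geometry, rad/s for foot angular velocity,
seconds for time, minutes/week for activity scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

GROUP_BVI = "bvi"
GROUP_SIGHTED = "sighted"
GROUPS = (GROUP_BVI, GROUP_SIGHTED)

DEFAULT_COP_FS = 180.0  # force-plate sampling rate, Hz
DEFAULT_GYRO_FS = 100.0  # inertial sensor sampling rate, Hz


# ---------------------------------------------------------------------------
# trace types
# ---------------------------------------------------------------------------

@dataclass
class CopTrace:
    """2-D centre-of-pressure trajectory.

    ``x`` is the medial-lateral and ``y`` the anterior-posterior CoP
    displacement in cm; ``t`` is in seconds and must be strictly increasing.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float = DEFAULT_COP_FS

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValidationError("CoP trace needs at least 2 samples")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class GyroTrace:
    """3-axis foot angular-velocity trajectory with walking-bout annotations.

    ``w`` has shape (n, 3) in rad/s.  ``bouts`` are half-open (start, end)
    sample-index ranges marking straight hallway bouts; ``exclusion_mask``
    flags samples judged non-stationary (e.g. the participant stopped).
    """

    t: np.ndarray
    w: np.ndarray
    fs: float = DEFAULT_GYRO_FS
    bouts: list[tuple[int, int]] = field(default_factory=list)
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[1] != 3:
            raise ValidationError("w must have shape (n, 3)")
        if len(self.t) != len(self.w):
            raise ValidationError("t and w must have equal length")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.exclusion_mask is None:
            self.exclusion_mask = np.zeros(len(self.t), dtype=bool)
        else:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
            if len(self.exclusion_mask) != len(self.t):
                raise ValidationError("exclusion_mask length mismatch")
        last_end = 0
        for s, e in self.bouts:
            if not (0 <= s < e <= len(self.t)):
                raise ValidationError(f"bout ({s}, {e}) out of range")
            if s < last_end:
                raise ValidationError("bouts must be ordered and non-overlapping")
            last_end = e

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class TriangleTrial:
    """One triangle-completion trial: guided path A->B->C, stop point P (cm)."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    P: np.ndarray
    direction: str = "clockwise"
    triangle_id: int = 1

    def __post_init__(self) -> None:
        for name in ("A", "B", "C", "P"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (2,):
                raise ValidationError(f"{name} must be a 2-D point")
            setattr(self, name, v)
        if self.direction not in ("clockwise", "counterclockwise"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        # non-collinearity of the guided path
        u, v = self.B - self.A, self.C - self.A
        cross = u[0] * v[1] - u[1] * v[0]
        if abs(cross) < 1e-9:
            raise ValidationError("A, B, C are collinear")


# ---------------------------------------------------------------------------
# participant-level records and the long-format cohort table
# ---------------------------------------------------------------------------

#: outcome attribute name -> (dv_name, condition) in the long-format table
DV_FIELD_MAP: dict[str, tuple[str, str]] = {
    "pea_bipedal_ec": ("pea", "bipedal_ec"),
    "pea_semitandem_ec": ("pea", "semitandem_ec"),
    "pea_bipedal_eo": ("pea", "bipedal_eo"),
    "pea_semitandem_eo": ("pea", "semitandem_eo"),
    "sls_time": ("sls_time", "ec"),
    "stride_time_sd_ec": ("stride_time_sd", "ec"),
    "stride_time_sd_eo": ("stride_time_sd", "eo"),
    "lle_ec": ("lle", "ec"),
    "lle_eo": ("lle", "eo"),
    "angle_error": ("angle_error", "ec"),
    "distance_error": ("distance_error", "ec"),
    "basic_activity": ("activity", "basic"),
    "exercise": ("activity", "exercise"),
}

#: eyes-closed conditions required per dv (eyes-open exists for sighted only
#: and missing eyes-open data never triggers removal)
_REQUIRED_EC_FIELDS: dict[str, tuple[str, ...]] = {
    "pea": ("pea_bipedal_ec", "pea_semitandem_ec"),
    "sls_time": ("sls_time",),
    "stride_time_sd": ("stride_time_sd_ec",),
    "lle": ("lle_ec",),
    "angle_error": ("angle_error",),
    "distance_error": ("distance_error",),
    "activity": ("basic_activity", "exercise"),
}


@dataclass
class ParticipantRecord:
    """All per-participant outcomes. ``None`` marks missing data.

    ``match_id`` links each blind/visually-impaired (BVI) participant with
    their age/gender-matched sighted control; matched-pair removal of missing
    sway data is keyed on it.
    """

    id: str
    group: str
    age: float | None = None
    match_id: str | None = None
    pea_bipedal_ec: float | None = None
    pea_semitandem_ec: float | None = None
    pea_bipedal_eo: float | None = None
    pea_semitandem_eo: float | None = None
    sls_time: float | None = None
    stride_time_sd_ec: float | None = None
    stride_time_sd_eo: float | None = None
    lle_ec: float | None = None
    lle_eo: float | None = None
    angle_error: float | None = None
    distance_error: float | None = None
    basic_activity: float | None = None
    exercise: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")
        for f in fields(self):
            if f.name in DV_FIELD_MAP:
                v = getattr(self, f.name)
                if v is not None and v < 0:
                    raise ValidationError(f"{f.name} must be nonnegative")


@dataclass
class CohortTable:
    """Long-format participant x condition outcome table.

    Columns: participant_id, match_id, group, condition, dv_name, value.
    Each (participant_id, condition, dv_name) combination is unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"participant_id", "group", "condition", "dv_name", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
        key = ["participant_id", "condition", "dv_name"]
        if self.data.duplicated(subset=key).any():
            dup = self.data[self.data.duplicated(subset=key, keep=False)]
            raise ValidationError(
                f"duplicate (participant, condition, dv) rows:\n{dup[key]}"
            )

    def __len__(self) -> int:
        return len(self.data)

    def dvs(self) -> list[str]:
        return sorted(self.data["dv_name"].unique())

    def subset(self, dv_name: str, conditions: Sequence[str] | None = None) -> pd.DataFrame:
        out = self.data[self.data["dv_name"] == dv_name]
        if conditions is not None:
            out = out[out["condition"].isin(conditions)]
        return out.copy()


def build_cohort(records: Iterable[ParticipantRecord]) -> CohortTable:
    """Assemble a long-format cohort table from participant records.

    Participants missing any eyes-closed value of a dependent variable lose
    all rows of that variable, and so does their matched partner — keeping
    the matched-pairs design intact.  Removals are logged.
    """
    records = list(records)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("participant ids must be unique")
    by_id = {r.id: r for r in records}

    # per dv: set of participant ids to drop (missing + matched partner)
    drop: dict[str, set[str]] = {dv: set() for dv in _REQUIRED_EC_FIELDS}
    for r in records:
        for dv, req in _REQUIRED_EC_FIELDS.items():
            if any(getattr(r, f) is None for f in req):
                drop[dv].add(r.id)
                partner = _find_partner(r, by_id)
                if partner is not None:
                    drop[dv].add(partner.id)
                    logger.info(
                        "dv %r: dropping %s (missing) and matched partner %s",
                        dv, r.id, partner.id,
                    )

    rows = []
    for r in records:
        for attr, (dv, condition) in DV_FIELD_MAP.items():
            if r.id in drop[dv]:
                continue
            v = getattr(r, attr)
            if v is None:
                continue
            rows.append(
                {
                    "participant_id": r.id,
                    "match_id": r.match_id,
                    "group": r.group,
                    "condition": condition,
                    "dv_name": dv,
                    "value": float(v),
                }
            )
    columns = ["participant_id", "match_id", "group", "condition", "dv_name", "value"]
    return CohortTable(pd.DataFrame(rows, columns=columns))


def _find_partner(r: ParticipantRecord, by_id: dict[str, ParticipantRecord]):
    if r.match_id is not None and r.match_id in by_id:
        return by_id[r.match_id]
    # reverse link: someone naming r as their match
    for other in by_id.values():
        if other.match_id == r.id:
            return other
    return None


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_COP_COLS = ("t_s", "cop_x_cm", "cop_y_cm")
_GYRO_COLS = ("t_s", "gyro_x_rad_s", "gyro_y_rad_s", "gyro_z_rad_s")
_TRIANGLE_COLS = ("trial_id", "ax", "ay", "bx", "by", "cx", "cy", "px", "py", "direction")


def read_cop_csv(path: str | Path, fs: float = DEFAULT_COP_FS) -> CopTrace:
    """Read a CoP trace from CSV with columns t_s, cop_x_cm, cop_y_cm."""
    df = pd.read_csv(path)
    for col in _COP_COLS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return CopTrace(t=df["t_s"].to_numpy(), x=df["cop_x_cm"].to_numpy(),
                    y=df["cop_y_cm"].to_numpy(), fs=fs)


def write_cop_csv(trace: CopTrace, path: str | Path) -> None:
    pd.DataFrame({"t_s": trace.t, "cop_x_cm": trace.x, "cop_y_cm": trace.y}).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_gyro_csv(path: str | Path, fs: float = DEFAULT_GYRO_FS) -> GyroTrace:
    """Read a gyro trace from CSV.

    Required columns: t_s, gyro_x_rad_s, gyro_y_rad_s, gyro_z_rad_s.
    Optional: bout_id (integer; consecutive equal values form bouts, negative
    means outside any bout) and excluded (0/1).
    """
    df = pd.read_csv(path)
    for col in _GYRO_COLS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    w = df[list(_GYRO_COLS[1:])].to_numpy()
    bouts: list[tuple[int, int]] = []
    if "bout_id" in df.columns:
        bid = df["bout_id"].to_numpy()
        start = None
        for i in range(len(bid)):
            if bid[i] >= 0 and (i == 0 or bid[i] != bid[i - 1]):
                if start is not None:
                    bouts.append((start, i))
                start = i
            elif bid[i] < 0 and start is not None:
                bouts.append((start, i))
                start = None
        if start is not None:
            bouts.append((start, len(bid)))
    mask = df["excluded"].to_numpy().astype(bool) if "excluded" in df.columns else None
    return GyroTrace(t=df["t_s"].to_numpy(), w=w, fs=fs, bouts=bouts, exclusion_mask=mask)


def write_gyro_csv(trace: GyroTrace, path: str | Path) -> None:
    bid = np.full(len(trace), -1, dtype=int)
    for k, (s, e) in enumerate(trace.bouts):
        bid[s:e] = k
    pd.DataFrame(
        {
            "t_s": trace.t,
            "gyro_x_rad_s": trace.w[:, 0],
            "gyro_y_rad_s": trace.w[:, 1],
            "gyro_z_rad_s": trace.w[:, 2],
            "bout_id": bid,
            "excluded": trace.exclusion_mask.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.12g")


def read_triangle_csv(path: str | Path) -> list[TriangleTrial]:
    df = pd.read_csv(path)
    for col in _TRIANGLE_COLS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    trials = []
    for _, row in df.iterrows():
        trials.append(
            TriangleTrial(
                A=(row["ax"], row["ay"]), B=(row["bx"], row["by"]),
                C=(row["cx"], row["cy"]), P=(row["px"], row["py"]),
                direction=row["direction"], triangle_id=int(row["trial_id"]),
            )
        )
    return trials


def write_triangle_csv(trials: Sequence[TriangleTrial], path: str | Path) -> None:
    rows = [
        {
            "trial_id": tr.triangle_id,
            "ax": tr.A[0], "ay": tr.A[1], "bx": tr.B[0], "by": tr.B[1],
            "cx": tr.C[0], "cy": tr.C[1], "px": tr.P[0], "py": tr.P[1],
            "direction": tr.direction,
        }
        for tr in trials
    ]
    pd.DataFrame(rows, columns=list(_TRIANGLE_COLS)).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_cohort_csv(path: str | Path) -> CohortTable:
    df = pd.read_csv(path)
    if "match_id" not in df.columns:
        df["match_id"] = None
    return CohortTable(df)


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# simple aggregations
# ---------------------------------------------------------------------------

SLS_TRIAL_CAP_S = 20.0  # single-leg stance trials are capped at 20 s


def aggregate_single_leg(times) -> float:
    """Mean single-leg stance time: average raters within trial, then trials.

    ``times`` is a (trials x raters) array of hold times in seconds, each in
    [0, 20] (the trial length cap).
    """
    arr = np.asarray(times, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValidationError("times must be a (trials x raters) matrix")
    if np.any(arr < 0) or np.any(arr > SLS_TRIAL_CAP_S):
        raise ValidationError(f"stance times must lie in [0, {SLS_TRIAL_CAP_S}] s")
    return float(arr.mean(axis=1).mean())


ACTIVITY_CATEGORIES = ("basic", "exercise")


def score_activity(entries: Iterable[tuple[str, float]]) -> tuple[float, float]:
    """Sum reported activity minutes/week per category (basic, exercise)."""
    totals = {c: 0.0 for c in ACTIVITY_CATEGORIES}
    for category, minutes in entries:
        if category not in totals:
            raise ValidationError(f"unknown activity category {category!r}")
        if minutes < 0:
            raise ValidationError("activity minutes must be nonnegative")
        totals[category] += float(minutes)
    return totals["basic"], totals["exercise"]
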