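"""Triangle-completion (path-integration) scoring.

A participant is guided along two legs of a triangle (A -> B -> C) and then
walks unaided from C back to where they believe A is, stopping at P.  The
homing response decomposes into a turning component and a path-length
component, scored at the turning point C:

* ``signed_angle_error`` — produced turn minus correct turn, where each turn
  is the signed angle from the incoming heading (B -> C) to the outgoing
  heading (C -> A ideal, C -> P produced), wrapped to (-180, 180] degrees.
* ``signed_distance_error`` — walked homing length |P - C| minus the correct
  homing length |A - C| (negative = underestimated path length).

Absolute values of both are the conventional dependent variables; the
Euclidean endpoint miss |P - A| is kept as an auxiliary metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DegenerateInputError, ValidationError
from .io_model import TriangleTrial

__all__ = [
    "TrialScore",
    "TriangleSpec",
    "score_trial",
    "summarize_trials",
    "make_reference_triangles",
    "standard_trial_sequence",
]


@dataclass
class TrialScore:
    angle_error: float            # degrees, [0, 180]
    signed_angle_error: float     # degrees, (-180, 180]
    distance_error: float         # cm, >= 0
    signed_distance_error: float  # cm
    endpoint_miss: float          # cm, |P - A|


def _cross2(u: np.ndarray, v: np.ndarray) -> float:
    return float(u[0] * v[1] - u[1] * v[0])


def _signed_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Signed angle (degrees) rotating u onto v, positive counterclockwise."""
    return float(np.degrees(np.arctan2(_cross2(u, v), np.dot(u, v))))


def _wrap_deg(a: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def score_trial(trial: TriangleTrial) -> TrialScore:
    """Score one trial against the ideal homing segment C -> A."""
    A, B, C, P = trial.A, trial.B, trial.C, trial.P
    if np.allclose(P, C):
        raise DegenerateInputError("stopping point coincides with the turning point")
    incoming = C - B
    correct = _signed_angle_deg(incoming, A - C)
    produced = _signed_angle_deg(incoming, P - C)
    signed_angle = _wrap_deg(produced - correct)
    signed_distance = float(np.linalg.norm(P - C) - np.linalg.norm(A - C))
    return TrialScore(
        angle_error=abs(signed_angle),
        signed_angle_error=signed_angle,
        distance_error=abs(signed_distance),
        signed_distance_error=signed_distance,
        endpoint_miss=float(np.linalg.norm(P - A)),
    )


def summarize_trials(scores: Sequence[TrialScore]) -> tuple[float, float]:
    """Mean absolute angle error (deg) and mean absolute distance error (cm)."""
    if len(scores) == 0:
        raise ValidationError("summarize_trials needs at least one score")
    return (
        float(np.mean([s.angle_error for s in scores])),
        float(np.mean([s.distance_error for s in scores])),
    )


@dataclass
class TriangleSpec:
    """Vertices of a guided triangle (counterclockwise layout, cm)."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    triangle_id: int

    def side_lengths(self) -> tuple[float, float, float]:
        """(|AB|, |BC|, |CA|) in cm."""
        return (
            float(np.linalg.norm(self.B - self.A)),
            float(np.linalg.norm(self.C - self.B)),
            float(np.linalg.norm(self.A - self.C)),
        )

    def angles(self) -> tuple[float, float, float]:
        """Interior angles at (A, B, C) in degrees."""
        out = []
        for v, p, q in ((self.A, self.B, self.C), (self.B, self.C, self.A),
                        (self.C, self.A, self.B)):
            out.append(abs(_signed_angle_deg(p - v, q - v)))
        return tuple(out)

    def as_trial(self, P, direction: str = "counterclockwise") -> TriangleTrial:
        """Materialise a trial, mirroring the layout for clockwise walks."""
        A, B, C, P = self.A, self.B, self.C, np.asarray(P, dtype=float)
        if direction == "clockwise":
            flip = np.array([1.0, -1.0])
            A, B, C, P = A * flip, B * flip, C * flip, P * flip
        return TriangleTrial(A=A, B=B, C=C, P=P, direction=direction,
                             triangle_id=self.triangle_id)


def make_reference_triangles() -> tuple[TriangleSpec, TriangleSpec]:
    """The two guided triangles used in testing.

    Triangle 1 is equilateral with 300 cm sides (all interior angles 60
    degrees).  Triangle 2 is a 30-60-90 right triangle with hypotenuse
    300 cm (legs 150 and 150*sqrt(3) cm); the hypotenuse is the homing
    segment C -> A.  All segments lie within the 150-300 cm design range.
    """
    t1 = TriangleSpec(
        A=np.array([0.0, 0.0]),
        B=np.array([300.0, 0.0]),
        C=np.array([150.0, 150.0 * np.sqrt(3.0)]),
        triangle_id=1,
    )
    # right angle at B, 30 deg at A, 60 deg at C; |AB| = 150*sqrt(3),
    # |BC| = 150, homing |CA| = 300
    t2 = TriangleSpec(
        A=np.array([0.0, 0.0]),
        B=np.array([150.0 * np.sqrt(3.0), 0.0]),
        C=np.array([150.0 * np.sqrt(3.0), 150.0]),
        triangle_id=2,
    )
    return t1, t2


def standard_trial_sequence() -> list[tuple[TriangleSpec, str]]:
    """Fixed 4-trial order: both triangles, clockwise and counterclockwise."""
    t1, t2 = make_reference_triangles()
    return [
        (t1, "clockwise"),
        (t2, "clockwise"),
        (t1, "counterclockwise"),
        (t2, "counterclockwise"),
    ]
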