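"""Circular-angle utilities for continuous-report error analysis.

All angles are radians internally. Errors and relative orientations live on
the full circle (−π, π]; positive values are counterclockwise. Recall
accuracy is defined as the reciprocal of the circular standard deviation
(Mardia definition, ``sqrt(-2 ln R)`` where ``R`` is the mean resultant
length of the error distribution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pingouin as pg

__all__ = [
    "CircularSummary",
    "wrap_angle",
    "signed_error",
    "circ_summary",
    "recall_accuracy",
    "rayleigh_test",
    "deg2rad",
    "rad2deg",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class CircularSummary:
    """First-moment summary of a sample of angles.

    Attributes
    ----------
    mean_direction : float
        Direction of the mean resultant vector, in (−π, π].
    resultant_length : float
        Modulus of the mean resultant vector, in [0, 1].
    circ_sd : float
        Circular standard deviation ``sqrt(-2 ln R)`` in radians;
        ``inf`` when the resultant length is 0.
    n : int
        Sample size.
    """

    mean_direction: float
    resultant_length: float
    circ_sd: float
    n: int


def wrap_angle(a):
    """Wrap angle(s) to the interval (−π, π].

    Accepts scalars or arrays; the boundary −π maps to +π so the interval
    is half-open at the clockwise end.
    """
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("wrap_angle requires finite input")
    wrapped = np.pi - np.mod(np.pi - a, _TWO_PI)
    return float(wrapped) if wrapped.ndim == 0 else wrapped


def signed_error(response, target):
    """Signed circular deviation response − target, wrapped to (−π, π].

    Positive values mean the response lies counterclockwise of the target.
    """
    return wrap_angle(np.asarray(response, dtype=float) - np.asarray(target, dtype=float))


def deg2rad(deg):
    return np.deg2rad(deg)


def rad2deg(rad):
    return np.rad2deg(rad)


def circ_summary(angles) -> CircularSummary:
    """Mean direction, resultant length and circular SD of a sample.

    Requires at least two angles. A perfectly balanced sample (resultant
    length 0) yields an infinite circular SD.
    """
    a = np.asarray(angles, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError(f"circ_summary needs a 1-d sample with n >= 2, got n = {a.size}")
    z = np.exp(1j * a).mean()
    r = min(float(np.abs(z)), 1.0)
    if r < 1e-12:  # numerically balanced sample
        r = 0.0
    mean_dir = float(wrap_angle(np.angle(z)))
    if r > 0.0:
        sd = float(np.sqrt(-2.0 * np.log(r)))
    else:
        sd = np.inf
    return CircularSummary(mean_direction=mean_dir, resultant_length=r, circ_sd=sd, n=a.size)


def recall_accuracy(errors) -> float:
    """Recall accuracy: 1 / circular SD of the signed errors (1/radian).

    Returns 0 (with a warning) for a sample whose resultant length is 0,
    keeping condition-level accuracy tables total.
    """
    s = circ_summary(errors)
    if s.resultant_length == 0.0:
        warnings.warn("zero resultant length: accuracy floored at 0", stacklevel=2)
        return 0.0
    if s.circ_sd == 0.0:
        return np.inf
    return 1.0 / s.circ_sd


def rayleigh_test(angles) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(z, p)`` where ``z = n * R²`` and ``p`` uses the standard
    small-sample corrected approximation
    ``p = exp(sqrt(1 + 4n + 4(n² − z n)) − (1 + 2n))``
    (Zar's correction, as implemented in pingouin).
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 10:
        raise ValueError(f"rayleigh_test needs n >= 10, got n = {a.size}")
    z, p = pg.circ_rayleigh(a)
    return float(z), float(p)
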