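"""Relative-orientation bias curves and the attraction/repulsion statistic.

A bias curve shows the mean signed recall error as a function of the
relative orientation Δ between the other relevant item in memory and the
currently probed item. Trials are assigned to 64 overlapping bins, each
holding the quarter of trials angularly closest to the bin centre. The
area-difference statistic contrasts the curve over positive Δ (the other
item counterclockwise) with negative Δ: a positive difference means recall
is attracted toward the other item, a negative one that it is repelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circstats import wrap_angle
from .inference import InferenceResult, one_sample_t

__all__ = [
    "BiasCurve",
    "BiasStatistic",
    "N_BINS",
    "relative_orientation",
    "sliding_bin_bias",
    "area_difference",
    "bias_group_test",
    "bin_centers",
]

N_BINS = 64


@dataclass(frozen=True)
class BiasCurve:
    """64-point bias curve.

    ``centers`` are radians in (−π, π], half-step offset so no centre sits
    at 0 or ±π and the positive/negative halves split 32/32. ``mean_bias``
    is the arithmetic mean signed error (radians) of the trials in each bin.
    """

    centers: np.ndarray
    mean_bias: np.ndarray
    occupancy: int
    n_trials: int


@dataclass(frozen=True)
class BiasStatistic:
    """Mean bias over positive Δ minus mean over negative Δ (radians).

    Positive = attraction toward the other item, negative = repulsion.
    """

    area_diff: float


def bin_centers(n_bins: int = N_BINS) -> np.ndarray:
    """Equally spaced centres −π + (j − 1/2)·2π/n for j = 1..n."""
    j = np.arange(1, n_bins + 1)
    return -np.pi + (j - 0.5) * (2.0 * np.pi / n_bins)


def relative_orientation(theta_other, theta_probed):
    """Orientation of the other item relative to the probed one, (−π, π].

    Negative values mean the other item lies clockwise of the probed item.
    """
    return wrap_angle(np.asarray(theta_other, float) - np.asarray(theta_probed, float))


def sliding_bin_bias(deltas, errors, n_bins: int = N_BINS) -> BiasCurve:
    """Overlapping quantile-bin bias curve.

    Each of the ``n_bins`` equally spaced centres collects the
    ``max(2, round(n/4))`` trials with smallest circular distance to it
    (ties broken by trial order) and averages their signed errors. A trial
    typically contributes to many bins; the curve is a smoothed estimate of
    E[error | Δ].
    """
    d = np.asarray(deltas, dtype=float)
    e = np.asarray(errors, dtype=float)
    if d.shape != e.shape or d.ndim != 1:
        raise ValueError("deltas and errors must be 1-d and paired")
    n = d.size
    if n < 8:
        raise ValueError(f"sliding_bin_bias needs n >= 8, got n = {n}")
    occupancy = max(2, round(n / 4))
    centers = bin_centers(n_bins)
    # (n_bins, n) circular distances; stable argsort keeps trial order on ties
    dist = np.abs(wrap_angle(d[None, :] - centers[:, None]))
    idx = np.argsort(dist, axis=1, kind="stable")[:, :occupancy]
    mean_bias = e[idx].mean(axis=1)
    return BiasCurve(centers=centers, mean_bias=mean_bias, occupancy=occupancy, n_trials=n)


def area_difference(curve: BiasCurve) -> BiasStatistic:
    """Contrast of the curve between the positive and negative half-domains.

    Computed as the mean of ``mean_bias`` over centres > 0 minus the mean
    over centres < 0 — proportional to the trapezoid integral for equally
    spaced centres, and scale-free across designs with different trial
    counts.
    """
    pos = curve.centers > 0
    neg = curve.centers < 0
    return BiasStatistic(area_diff=float(curve.mean_bias[pos].mean() - curve.mean_bias[neg].mean()))


def bias_group_test(area_diffs, effect: str = "bias area difference") -> InferenceResult:
    """One-sample t test (two-sided, with JZS BF10) of area differences vs 0."""
    v = np.asarray(area_diffs, dtype=float)
    if v.size < 3:
        raise ValueError(f"bias_group_test needs >= 3 subjects, got {v.size}")
    return one_sample_t(v, 0.0, effect=effect)
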