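"""Editing-rate estimation from time-course data.

With a constant per-hour editing rate r, the fraction of still-unedited
(wild-type) target Cs decays exponentially, W(t) = exp(-r t), anchored at
W(0) = 1.  The rate is estimated from sampled wild-type fractions by a
log-linear regression through the origin followed by nonlinear least-squares
refinement.  The experimentally determined value for the deaminase system is
about 0.06 edits per hour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares


@dataclass
class TimeCourse:
    """Sampled wild-type fractions; t = 0 with fraction 1 is implicit."""

    times: np.ndarray
    wildtype_fraction: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.wildtype_fraction, dtype=float)
        if t.shape != w.shape:
            raise ValueError("times and fractions must have equal length")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if np.any((w <= 0) | (w > 1)):
            raise ValueError("fractions must lie in (0, 1]")
        self.times, self.wildtype_fraction = t, w


@dataclass(frozen=True)
class RateFit:
    rate: float  # edits per unit time
    residual: float  # sum of squared fit errors


def fit_editing_rate(tc: TimeCourse) -> RateFit:
    """Least-squares fit of W(t) = exp(-r t).

    Requires >=3 time points.  Replicates may be pooled as independent
    points.  A non-decreasing fraction profile (no editing signal) triggers
    a warning but still returns the fit, which will be near rate 0.
    """
    t, w = tc.times, tc.wildtype_fraction
    if t.size < 3:
        raise ValueError("need >=3 time points")
    order = np.argsort(t, kind="stable")
    if np.all(np.diff(w[order]) >= 0) and np.any(t > 0):
        warnings.warn(
            "wild-type fraction does not decrease over time; "
            "estimated rate may be 0",
            stacklevel=2,
        )
    # log-linear initialisation: regression of log W on t through the origin
    denom = float((t * t).sum())
    r0 = max(0.0, -float((t * np.log(w)).sum()) / denom) if denom > 0 else 0.0

    def resid(params: np.ndarray) -> np.ndarray:
        return np.exp(-params[0] * t) - w

    sol = least_squares(resid, x0=[r0], bounds=([0.0], [np.inf]))
    rate = float(sol.x[0])
    residual = float(np.sum(resid(sol.x) ** 2))
    return RateFit(rate=rate, residual=residual)
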