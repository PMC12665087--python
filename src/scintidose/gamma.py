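"""1D gamma comparison of depth-dose curves.

The pass criterion is a *box*: a measured depth point passes the
``dose_tol%/dist_tol mm`` criterion if somewhere on the reference curve
within +/- dist_tol of its depth the reference dose differs from the
measured dose by no more than dose_tol.  Dose differences are global —
percentage points on curves normalized to 100 — which is the convention for
1D PDD comparison (a local mode is available behind a flag).  The classical
Low-style gamma value (an ellipse rather than a box) is also provided; the
box can never be stricter than the ellipse at equal tolerances, so
``gamma_value <= 1`` implies a box pass.

The reference is piecewise linear, so within the search window the minimum
absolute dose difference is attained at a reference knot, at a window
endpoint, or at an exact crossing (difference zero, which passes anyway).
The implementation therefore evaluates knots + window endpoints + a 0.01 mm
grid, making the box decision exact for sampled reference curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .curves import Curve
from .errors import ScintidoseError

__all__ = ["GammaCriteria", "GammaReport", "point_passes", "gamma_value", "pass_rate"]

_GRID_MM = 0.01


class GammaError(ScintidoseError, ValueError):
    """Gamma evaluation impossible (e.g. search window outside the reference)."""


@dataclass(frozen=True)
class GammaCriteria:
    """Dose tolerance (percentage points on 100-normalized curves), distance
    tolerance (mm), and a build-up exclusion threshold (0 = none)."""

    dose_tol: float
    dist_tol: float
    depth_min: float = 0.0
    local: bool = False  # dose_tol as % of the local reference dose instead

    def __post_init__(self) -> None:
        if self.dose_tol <= 0.0 or self.dist_tol <= 0.0:
            raise ValueError("dose and distance tolerances must be positive")
        if self.depth_min < 0.0:
            raise ValueError("depth_min must be non-negative")


@dataclass(frozen=True)
class GammaReport:
    """Per-point pass flags and the aggregate passing rate."""

    pass_rate: float            # percent
    n_points: int
    depths: np.ndarray          # evaluated measured depths, mm
    passed: np.ndarray          # bool per evaluated point
    gamma: Optional[np.ndarray] = None  # Low-style gamma values, if requested


def _window(reference: Curve, depth: float, dist_tol: float) -> tuple[float, float]:
    lo, hi = depth - dist_tol, depth + dist_tol
    r0, r1 = reference.span
    if hi < r0 or lo > r1:
        raise GammaError(
            f"search window [{lo:g}, {hi:g}] mm lies outside the reference "
            f"span [{r0:g}, {r1:g}] mm")
    return max(lo, r0), min(hi, r1)


def _candidates(reference: Curve, lo: float, hi: float) -> np.ndarray:
    x = reference.abscissa
    knots = x[(x > lo) & (x < hi)]
    grid = lo + _GRID_MM * np.arange(int((hi - lo) / _GRID_MM) + 1)
    return np.unique(np.concatenate([[lo, hi], knots, grid]))


def _dose_diff(ref_vals: np.ndarray, dose: float, crit: GammaCriteria) -> np.ndarray:
    """Dose difference in units of the tolerance (<= 1 means within tolerance)."""
    if crit.local:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.abs(ref_vals - dose) / (crit.dose_tol / 100.0 * np.abs(ref_vals))
    return np.abs(ref_vals - dose) / crit.dose_tol


def point_passes(depth: float, dose: float, reference: Curve,
                 crit: GammaCriteria) -> bool:
    """Box criterion: a reference point within +/- dist_tol whose dose is
    within +/- dose_tol of the measured dose."""
    lo, hi = _window(reference, depth, crit.dist_tol)
    r = _candidates(reference, lo, hi)
    return bool(np.min(_dose_diff(reference.interp(r), dose, crit)) <= 1.0)


def gamma_value(depth: float, dose: float, reference: Curve,
                crit: GammaCriteria) -> float:
    """Low-style gamma: min over the whole reference curve of
    sqrt((dr/dist_tol)^2 + (dD/dose_tol)^2)."""
    _window(reference, depth, crit.dist_tol)  # same validity requirement
    r = _candidates(reference, *reference.span)
    dist = (r - depth) / crit.dist_tol
    dd = _dose_diff(reference.interp(r), dose, crit)
    return float(np.min(np.hypot(dist, dd)))


def pass_rate(measured: Curve, reference: Curve, crit: GammaCriteria,
              *, compute_gamma: bool = False) -> GammaReport:
    """Fraction of measured points beyond the build-up exclusion that pass.

    The measured samples are the evaluation set; the reference is the curve
    searched.  Deterministic: no stochastic resampling anywhere.
    """
    sel = measured.abscissa > crit.depth_min
    depths = measured.abscissa[sel]
    doses = measured.values[sel]
    if depths.size == 0:
        raise GammaError("no measured points beyond the build-up exclusion")
    passed = np.array([point_passes(d, v, reference, crit)
                       for d, v in zip(depths, doses)])
    gamma = None
    if compute_gamma:
        gamma = np.array([gamma_value(d, v, reference, crit)
                          for d, v in zip(depths, doses)])
    rate = 100.0 * float(passed.sum()) / passed.size
    return GammaReport(rate, int(passed.size), depths, passed, gamma)
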