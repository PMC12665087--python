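"""Curve containers and scalar metrics for water-tank dosimetry.

A :class:`Curve` holds either a percentage depth dose (PDD: dose along the
beam central axis versus depth in water) or a lateral beam profile at a fixed
depth.  The metrics implemented here are the standard ones used when
commissioning small photon fields:

* PDD normalization to 100 at the depth of maximum dose (d_max);
* profile normalization to 100 at the central-axis (CAX) value;
* the 80%-20% penumbra per field edge (doses relative to the CAX value);
* the field width (distance between the 50% crossings, i.e. FWHM);
* linear resampling onto a uniform grid;
* volume averaging with a rectangular kernel, modelling the finite detector
  length along the scan axis.

All threshold crossings are located by linear interpolation between the
bracketing samples; when a level is crossed more than once on a side, the
outermost crossing is used (deterministic tie-break for noisy shoulders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CurveError

__all__ = [
    "Curve",
    "PenumbraResult",
    "level_crossings",
    "normalize_pdd",
    "normalize_profile",
    "penumbra_widths",
    "field_width",
    "resample",
    "volume_average",
]


@dataclass
class Curve:
    """A sampled dose curve.

    Parameters
    ----------
    abscissa:
        Depth (``kind="pdd"``) or lateral position (``kind="profile"``) in mm,
        strictly increasing.
    values:
        Dose values — raw signal (nC), absolute dose (cGy) or percent,
        depending on the processing stage; tracked via ``meta["normalized"]``.
    kind:
        ``"pdd"`` or ``"profile"``.
    meta:
        Free-form metadata; recognised keys are ``depth_mm`` (for profiles),
        ``normalized``, ``field_cm``, ``d_max_mm`` and ``center_mm``.
    """

    abscissa: np.ndarray
    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abscissa = np.atleast_1d(np.asarray(self.abscissa, dtype=float))
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.kind not in ("pdd", "profile"):
            raise CurveError(f"unknown curve kind {self.kind!r}")
        if self.abscissa.ndim != 1 or self.abscissa.shape != self.values.shape:
            raise CurveError("abscissa and values must be 1-D arrays of equal length")
        if self.abscissa.size == 0:
            raise CurveError("empty curve")
        if not (np.all(np.isfinite(self.abscissa)) and np.all(np.isfinite(self.values))):
            raise CurveError("curve contains non-finite samples")
        if self.abscissa.size > 1 and not np.all(np.diff(self.abscissa) > 0):
            raise CurveError("abscissa must be strictly increasing")

    def __len__(self) -> int:
        return int(self.abscissa.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.abscissa[0]), float(self.abscissa[-1])

    def interp(self, at):
        """Linear interpolation of the curve at ``at`` (no extrapolation)."""
        return np.interp(at, self.abscissa, self.values)


@dataclass(frozen=True)
class PenumbraResult:
    """80-20 penumbra per edge and the mean of the two edges, in mm."""

    left_mm: float
    right_mm: float
    mean_mm: float


def level_crossings(x, v, level: float) -> np.ndarray:
    """Positions where the sampled curve crosses ``level``, ascending.

    Crossings are linearly interpolated between bracketing samples; samples
    lying exactly on the level count as crossings.
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    d = v - level
    exact = x[d == 0.0]
    seg = np.flatnonzero(d[:-1] * d[1:] < 0.0)
    frac = d[seg] / (d[seg] - d[seg + 1])
    interp = x[seg] + frac * (x[seg + 1] - x[seg])
    return np.unique(np.concatenate([exact, interp]))


def normalize_pdd(curve: Curve) -> Curve:
    """Scale a PDD so its maximum is 100; records ``d_max_mm`` in meta.

    Idempotent, and invariant under uniform scaling of the raw values.
    """
    if curve.kind != "pdd":
        raise CurveError(f"normalize_pdd expects a pdd curve, got {curve.kind!r}")
    vmax = float(curve.values.max())
    if vmax <= 0.0:
        raise CurveError("cannot normalize: non-positive curve maximum")
    meta = dict(curve.meta)
    meta["normalized"] = True
    meta["d_max_mm"] = float(curve.abscissa[int(np.argmax(curve.values))])
    return Curve(curve.abscissa.copy(), curve.values * (100.0 / vmax), "pdd", meta)


def normalize_profile(curve: Curve, center: float) -> Curve:
    """Scale a profile to 100 at ``center`` and re-express positions
    relative to it (the CAX convention for FFF penumbra analysis)."""
    if curve.kind != "profile":
        raise CurveError(f"normalize_profile expects a profile, got {curve.kind!r}")
    lo, hi = curve.span
    if not (lo <= center <= hi):
        raise CurveError(f"center {center} mm outside abscissa span [{lo}, {hi}] mm")
    cax = float(curve.interp(center))
    if cax <= 0.0:
        raise CurveError("cannot normalize: non-positive value at the central axis")
    meta = dict(curve.meta)
    meta["normalized"] = True
    meta["center_mm"] = float(center)
    return Curve(curve.abscissa - center, curve.values * (100.0 / cax), "profile", meta)


def _outermost_crossing(curve: Curve, level: float, side: str) -> float:
    x_peak = curve.abscissa[int(np.argmax(curve.values))]
    crossings = level_crossings(curve.abscissa, curve.values, level)
    sel = crossings[crossings < x_peak] if side == "left" else crossings[crossings > x_peak]
    if sel.size == 0:
        raise CurveError(f"no {level:g}% crossing on the {side} side of the profile")
    return float(sel.min() if side == "left" else sel.max())


def penumbra_widths(profile: Curve) -> PenumbraResult:
    """80-20 penumbra of each field edge of a CAX-normalized profile.

    The penumbra is the lateral distance between the 80% and 20% isodose
    levels (doses as a percentage of the CAX value).  Outermost crossings are
    used if a level is crossed several times on one side.
    """
    if profile.values.max() < 80.0:
        raise CurveError("profile never reaches 80%: normalize to the CAX value first")
    left = _outermost_crossing(profile, 80.0, "left") - _outermost_crossing(profile, 20.0, "left")
    right = _outermost_crossing(profile, 20.0, "right") - _outermost_crossing(profile, 80.0, "right")
    return PenumbraResult(left, right, 0.5 * (left + right))


def field_width(profile: Curve) -> float:
    """Distance between the outermost 50%-of-maximum crossings (FWHM), mm."""
    level = float(profile.values.max()) / 2.0
    crossings = level_crossings(profile.abscissa, profile.values, level)
    if crossings.size < 2:
        raise CurveError("profile does not cross 50% on both sides: no field width")
    return float(crossings.max() - crossings.min())


def resample(curve: Curve, step: float) -> Curve:
    """Linearly resample onto a uniform grid of spacing ``step`` (mm),
    preserving both endpoints."""
    if step <= 0.0:
        raise CurveError("resample step must be positive")
    lo, hi = curve.span
    span = hi - lo
    if step > span:
        raise CurveError(f"resample step {step} mm exceeds curve span {span} mm")
    n = int(np.floor(span / step + 1e-9))
    grid = lo + step * np.arange(n + 1)
    if hi - grid[-1] > 1e-9 * max(1.0, abs(hi)):
        grid = np.append(grid, hi)
    else:
        grid[-1] = hi
    return Curve(grid, curve.interp(grid), curve.kind, dict(curve.meta))


def _integral_of_interpolant(x: np.ndarray, v: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Exact integral of the piecewise-linear interpolant of (x, v) from x[0] to q."""
    knots = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(x))])
    i = np.clip(np.searchsorted(x, q, side="right") - 1, 0, x.size - 2)
    vq = v[i] + (v[i + 1] - v[i]) * (q - x[i]) / (x[i + 1] - x[i])
    return knots[i] + 0.5 * (v[i] + vq) * (q - x[i])


def volume_average(curve: Curve, length_mm: float) -> Curve:
    """Convolve a curve with a rectangular kernel of width ``length_mm``.

    First-order model of a cylindrical detector's sensitive length along the
    scan axis: each sample becomes the mean of the linear interpolant over a
    window of ``length_mm`` centred on it.  At the curve ends the window
    shrinks to the available support (no padding).  Averaging can never
    increase the curve maximum and never sharpens a penumbra.
    """
    if length_mm <= 0.0:
        raise CurveError("kernel length must be positive")
    if len(curve) < 2:
        raise CurveError("volume averaging needs at least two samples")
    x, v = curve.abscissa, curve.values
    half = 0.5 * length_mm
    a = np.clip(x - half, x[0], x[-1])
    b = np.clip(x + half, x[0], x[-1])
    avg = (_integral_of_interpolant(x, v, b) - _integral_of_interpolant(x, v, a)) / (b - a)
    return Curve(x.copy(), avg, curve.kind, dict(curve.meta))
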