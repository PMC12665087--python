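"""Scan trajectories and beam-alignment procedures.

Water-tank scans move a detector at constant speed along one axis while the
acquisition timestamps pulses; a :class:`ScanTrajectory` maps time to the
scan coordinate.  Two alignment procedures mirror standard tank software:

* **pre-scan centering** — the beam axis is taken as the midpoint of the
  50%-of-maximum edge crossings of a lateral profile;
* **beam-inclination estimation** — the tilt of the beam axis relative to the
  tank vertical is obtained from profile centers at a shallow and a deep
  depth, and applied to subsequent depth scans so the detector tracks the
  true central axis.

Without the inclination correction, a vertical depth scan of a small field
drifts off-axis by ``depth * tan(theta)`` and the measured depth dose falls
off faster than the true central-axis curve — the failure mode the indirect
profile-peak method is designed to avoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .curves import Curve, level_crossings
from .errors import CurveError

__all__ = [
    "ScanTrajectory",
    "InclinationEstimate",
    "estimate_center",
    "estimate_inclination",
    "corrected_pdd_trajectory",
]

_AXES = ("crossline", "inline", "depth")


@dataclass(frozen=True)
class ScanTrajectory:
    """Constant-speed time-to-position mapping for one scan.

    For lateral scans (``axis`` in ``{"crossline", "inline"}``) the scan
    coordinate is the lateral position at ``fixed_depth``.  For depth scans
    the coordinate is the depth; the lateral position of the detector follows
    ``lateral_track(depth)`` (vertical at x=0 when omitted), which is how an
    inclination-corrected PDD scan is expressed.
    """

    axis: str
    start: float
    speed: float
    duration: float
    t0: float = 0.0
    fixed_depth: Optional[float] = None
    lateral_track: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}, got {self.axis!r}")
        if self.speed < 0.0:
            raise ValueError("scan speed must be non-negative")
        if self.duration <= 0.0:
            raise ValueError("trajectory duration must be positive")
        if self.axis != "depth":
            if self.fixed_depth is None or self.fixed_depth < 0.0:
                raise ValueError("lateral scans need a non-negative fixed_depth")

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def coordinate(self, t) -> np.ndarray:
        """Scan-axis coordinate (mm) at time ``t`` (s)."""
        return self.start + self.speed * (np.asarray(t, dtype=float) - self.t0)

    def position(self, t) -> tuple[np.ndarray, np.ndarray]:
        """(lateral x, depth) in mm at time ``t``."""
        c = self.coordinate(t)
        if self.axis == "depth":
            depth = c
            if self.lateral_track is not None:
                x = np.asarray(self.lateral_track(depth), dtype=float)
            else:
                x = np.zeros_like(depth)
        else:
            x = c
            depth = np.full_like(c, float(self.fixed_depth))
        return x, depth

    @classmethod
    def profile_scan(cls, start: float, stop: float, speed: float, depth: float,
                     t0: float = 0.0, axis: str = "crossline") -> "ScanTrajectory":
        if stop <= start:
            raise ValueError("profile scan requires stop > start")
        if speed <= 0.0:
            raise ValueError("zero or negative speed with a nonzero scan span")
        return cls(axis, start, speed, (stop - start) / speed, t0, fixed_depth=depth)

    @classmethod
    def depth_scan(cls, start: float, stop: float, speed: float,
                   lateral_track: Optional[Callable] = None,
                   t0: float = 0.0) -> "ScanTrajectory":
        if stop <= start:
            raise ValueError("depth scan requires stop > start")
        if speed <= 0.0:
            raise ValueError("zero or negative speed with a nonzero scan span")
        return cls("depth", start, speed, (stop - start) / speed, t0,
                   lateral_track=lateral_track)

    @classmethod
    def station(cls, position: float, depth: float, duration: float,
                t0: float = 0.0, axis: str = "crossline") -> "ScanTrajectory":
        """Stationary acquisition (output-factor readings)."""
        return cls(axis, position, 0.0, duration, t0, fixed_depth=depth)


@dataclass(frozen=True)
class InclinationEstimate:
    """Beam declination from profile centers at two depths."""

    theta: float        # radians, positive = beam axis drifts to +x with depth
    c_shallow: float    # mm
    c_deep: float       # mm
    d_shallow: float    # mm
    d_deep: float       # mm


def estimate_center(profile: Curve) -> float:
    """Midpoint of the outermost 50%-of-maximum crossings of a profile.

    The 50%-of-max convention (rather than 50%-of-CAX) stays well defined for
    unflattened and very small fields that have no flat top.  Raises
    :class:`CurveError` when the profile does not cross 50% on both sides
    (e.g. a monotone ramp with a single crossing).
    """
    level = float(profile.values.max()) / 2.0
    crossings = level_crossings(profile.abscissa, profile.values, level)
    if crossings.size < 2:
        raise CurveError("no field edges: profile must cross 50% of its maximum "
                         "on both sides")
    return float(0.5 * (crossings.min() + crossings.max()))


def estimate_inclination(p_shallow: Curve, p_deep: Curve,
                         d_shallow: Optional[float] = None,
                         d_deep: Optional[float] = None) -> InclinationEstimate:
    """Beam declination angle from profiles at two depths.

    ``theta = atan((c_deep - c_shallow) / (d_deep - d_shallow))`` where the
    centers come from :func:`estimate_center`.  Depths default to the curves'
    ``meta["depth_mm"]``; the customary choices are 50 and 280 mm.
    """
    if d_shallow is None:
        d_shallow = p_shallow.meta.get("depth_mm")
    if d_deep is None:
        d_deep = p_deep.meta.get("depth_mm")
    if d_shallow is None or d_deep is None:
        raise ValueError("profile depths not given and not present in curve meta")
    d_shallow, d_deep = float(d_shallow), float(d_deep)
    if d_deep <= d_shallow:
        raise ValueError("inclination estimation requires d_deep > d_shallow")
    c_shallow = estimate_center(p_shallow)
    c_deep = estimate_center(p_deep)
    theta = math.atan2(c_deep - c_shallow, d_deep - d_shallow)
    return InclinationEstimate(theta, c_shallow, c_deep, d_shallow, d_deep)


def corrected_pdd_trajectory(est: InclinationEstimate, surface_center: float = 0.0,
                             *, depth_start: float = 0.0, depth_stop: float = 280.0,
                             speed: float = 10.0, t0: float = 0.0) -> ScanTrajectory:
    """Depth-scan trajectory whose lateral track follows the tilted beam axis.

    ``lateral_track(depth) = surface_center + depth * tan(theta)`` — affine in
    depth, which is all a rigid beam tilt can produce.
    """
    if abs(est.theta) >= 0.1:
        raise ValueError("inclination correction only valid for |theta| < 0.1 rad")
    slope = math.tan(est.theta)

    def track(depth):
        return surface_center + np.asarray(depth, dtype=float) * slope

    return ScanTrajectory.depth_scan(depth_start, depth_stop, speed,
                                     lateral_track=track, t0=t0)
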