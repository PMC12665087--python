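"""Synthetic flattening-filter-free beam and water-tank scan simulator.

Ground truth against which every analysis stage is tested.  The beam model
is analytic, chosen for closed-form testability rather than physical
completeness:

* depth dose — a build-up rise times exponential attenuation,
  ``(1 - exp(-buildup_k * d)) * exp(-mu * max(0, d - d_max))``, rescaled so
  its maximum over depth is exactly 100;
* lateral profile — a double-erf field edge with Gaussian blur
  ``penumbra_sigma``, geometric divergence of the field width with depth
  (``w_d = w * (ssd + d)/ssd``), and a beam axis that may be tilted by
  ``tilt_theta`` and offset by ``offset_x0`` at the surface;
* detector — a 1 mm diameter x 1 mm long scintillating cylinder whose finite
  length volume-averages the lateral dose, plus a bare trailing fiber whose
  in-field length generates the Cerenkov stem charge.

``simulate_scan`` emits one two-channel pulse record per linac pulse with
seeded Gaussian pulse-to-pulse output fluctuation, the raw material for the
whole processing chain.  Head scatter, source occlusion and MLC effects are
deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .curves import Curve, normalize_pdd
from .geometry import ScanTrajectory
from .pulses import PulseTrain

__all__ = [
    "BeamModel",
    "DetectorModel",
    "PulseConfig",
    "pdd_model",
    "profile_model",
    "beam_axis_x",
    "field_width_at",
    "dose_at",
    "averaged_dose",
    "irradiated_fiber_length",
    "simulate_scan",
    "ground_truth_pdd",
    "ground_truth_profile",
    "beam_for_field",
]

_SQRT2 = math.sqrt(2.0)
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(16)


@dataclass(frozen=True)
class BeamModel:
    """Analytic stand-in for a 6 MV FFF beam at SSD 100 cm.

    Units: mm for lengths, radians for the tilt, cGy for the per-pulse CAX
    output at d_max.  Defaults approximate a TrueBeam 6XFFF: d_max 15 mm,
    ~0.4%/mm attenuation beyond d_max, ~2 mm edge blur.
    """

    field_width_w: float            # nominal square field side at the surface, mm
    penumbra_sigma: float = 2.0     # Gaussian edge blur sigma, mm
    d_max: float = 15.0             # depth of maximum dose, mm
    mu: float = 0.004               # effective attenuation beyond d_max, 1/mm
    buildup_k: float = 0.4          # build-up rise rate, 1/mm
    ssd: float = 1000.0             # source-to-surface distance, mm
    tilt_theta: float = 0.0         # beam inclination from vertical, rad
    offset_x0: float = 0.0          # lateral beam-axis offset at the surface, mm
    output_cGy_per_pulse: float = 0.05  # CAX dose per pulse at d_max, cGy

    def __post_init__(self) -> None:
        if self.field_width_w <= 0.0:
            raise ValueError("field_width_w must be positive")
        if self.penumbra_sigma <= 0.0:
            raise ValueError("penumbra_sigma must be positive")
        if self.d_max <= 0.0 or self.buildup_k <= 0.0 or self.ssd <= 0.0:
            raise ValueError("d_max, buildup_k and ssd must be positive")
        if self.mu < 0.0:
            raise ValueError("mu must be non-negative")
        if abs(self.tilt_theta) >= 0.1:
            raise ValueError("|tilt_theta| must be below 0.1 rad")


@dataclass(frozen=True)
class DetectorModel:
    """Scintillator + trailing bare fiber.

    ``fiber_cerenkov_coeff`` (nC per mm of irradiated fiber per cGy of pulse
    dose) couples the stem channel to geometry; ``acr_true`` and ``cr_true``
    are the ground-truth calibration constants the estimators must recover.
    The fiber trails the sensor along -x for ``fiber_length_mm``.
    """

    length_mm: float = 1.0
    diameter_mm: float = 1.0
    fiber_cerenkov_coeff: float = 0.05
    acr_true: float = 0.963
    cr_true: float = 1.0
    fiber_length_mm: float = 1000.0

    def __post_init__(self) -> None:
        if self.length_mm <= 0.0 or self.diameter_mm <= 0.0:
            raise ValueError("detector length and diameter must be positive")
        if self.fiber_cerenkov_coeff < 0.0 or self.fiber_length_mm <= 0.0:
            raise ValueError("fiber parameters out of range")
        if self.cr_true <= 0.0:
            raise ValueError("cr_true must be positive")

    @property
    def sensitive_volume_mm3(self) -> float:
        """Cylinder volume pi/4 * d^2 * L (0.785 mm^3 for the 1 mm x 1 mm default)."""
        return math.pi / 4.0 * self.diameter_mm ** 2 * self.length_mm


@dataclass(frozen=True)
class PulseConfig:
    """Linac pulse train: repetition frequency, output fluctuation, seed."""

    prf_hz: float = 360.0
    fluctuation_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prf_hz <= 0.0:
            raise ValueError("pulse repetition frequency must be positive")
        if self.fluctuation_cv < 0.0:
            raise ValueError("fluctuation_cv must be non-negative")


def _pdd_raw(depth: np.ndarray, beam: BeamModel) -> np.ndarray:
    rise = 1.0 - np.exp(-beam.buildup_k * depth)
    fall = np.exp(-beam.mu * np.clip(depth - beam.d_max, 0.0, None))
    return rise * fall


def _pdd_peak(beam: BeamModel) -> float:
    """Maximum of the un-normalized depth-dose over depth (closed form)."""
    if beam.mu == 0.0:
        return 1.0  # supremum as depth -> infinity
    d_star = math.log((beam.buildup_k + beam.mu) / beam.mu) / beam.buildup_k
    d_peak = max(beam.d_max, d_star)
    return float(_pdd_raw(np.asarray(d_peak), beam))


def pdd_model(depth, beam: BeamModel):
    """Central-axis depth dose in percent of the curve maximum."""
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("depth must be non-negative")
    return 100.0 * _pdd_raw(d, beam) / _pdd_peak(beam)


def beam_axis_x(depth, beam: BeamModel):
    """Lateral position of the (possibly tilted/offset) beam axis at depth."""
    return beam.offset_x0 + np.asarray(depth, dtype=float) * math.tan(beam.tilt_theta)


def field_width_at(depth, beam: BeamModel):
    """Field side at depth after divergence scaling: w * (ssd + d)/ssd."""
    return beam.field_width_w * (beam.ssd + np.asarray(depth, dtype=float)) / beam.ssd


def profile_model(x, depth, beam: BeamModel):
    """Lateral dose in percent of the central-axis value at the same depth."""
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("depth must be non-negative")
    u = np.asarray(x, dtype=float) - beam_axis_x(d, beam)
    half = field_width_at(d, beam) / 2.0
    s = beam.penumbra_sigma * _SQRT2
    g = 0.5 * (erf((half - u) / s) + erf((half + u) / s))
    g0 = erf(half / s)  # value on the beam axis (u = 0)
    return 100.0 * g / g0


def dose_at(x, depth, beam: BeamModel):
    """Point dose in cGy per pulse: output * PDD/100 * profile/100."""
    return (beam.output_cGy_per_pulse * pdd_model(depth, beam) / 100.0
            * profile_model(x, depth, beam) / 100.0)


def averaged_dose(x, depth, beam: BeamModel, detector: DetectorModel | None = None):
    """Point dose volume-averaged over the detector length along the scan axis.

    Gauss-Legendre quadrature (16 nodes) over a rectangular kernel of width
    ``detector.length_mm`` centred on ``x``; with ``detector=None`` this is
    the point dose.
    """
    if detector is None:
        return dose_at(x, depth, beam)
    x = np.asarray(x, dtype=float)
    d = np.asarray(depth, dtype=float)
    half = detector.length_mm / 2.0
    xs = x[..., np.newaxis] + half * _GL_NODES
    ds = np.broadcast_to(d[..., np.newaxis] if d.ndim else d, xs.shape)
    return dose_at(xs, ds, beam) @ (_GL_WEIGHTS / 2.0)


def irradiated_fiber_length(x, depth, beam: BeamModel, detector: DetectorModel):
    """In-field length (mm) of the straight fiber trailing the sensor along -x."""
    x = np.asarray(x, dtype=float)
    bx = beam_axis_x(depth, beam)
    half = field_width_at(depth, beam) / 2.0
    lo = np.maximum(x - detector.fiber_length_mm, bx - half)
    hi = np.minimum(x, bx + half)
    return np.clip(hi - lo, 0.0, None)


def simulate_scan(beam: BeamModel, detector: DetectorModel,
                  trajectory: ScanTrajectory, pulses: PulseConfig) -> PulseTrain:
    """Two-channel pulse train for one scan.

    One record per pulse at times ``t0 + k/prf``.  Per pulse the true dose is
    the volume-averaged dose at the detector position times ``(1 + eps_k)``
    with ``eps_k ~ N(0, fluctuation_cv)``; the Cerenkov charge is
    ``coeff * irradiated_fiber_length * dose`` and the sensor charge is
    ``dose/cr_true + acr_true * Rc``.  Identical ``PulseConfig`` (including
    the seed) reproduces the train bit for bit.
    """
    n = int(math.floor(trajectory.duration * pulses.prf_hz + 1e-9))
    if n == 0:
        raise ValueError("trajectory too short for a single pulse")
    t = trajectory.t0 + np.arange(n) / pulses.prf_hz
    x, depth = trajectory.position(t)
    base = averaged_dose(x, depth, beam, detector)
    rng = np.random.default_rng(pulses.seed)
    eps = rng.normal(0.0, pulses.fluctuation_cv, n) if pulses.fluctuation_cv > 0 \
        else np.zeros(n)
    dose = base * (1.0 + eps)
    rc = detector.fiber_cerenkov_coeff * irradiated_fiber_length(x, depth, beam, detector) * dose
    rs = dose / detector.cr_true + detector.acr_true * rc
    return PulseTrain(t, rs, rc)


def ground_truth_pdd(beam: BeamModel, depths,
                     detector: DetectorModel | None = None) -> Curve:
    """Oracle CAX depth dose at the given depths, normalized to 100.

    With a detector, this is the depth dose an ideal, perfectly tracked scan
    of that finite detector would read (volume-averaged on axis) — the fair
    reference for reconstructed PDDs from the same detector.
    """
    d = np.asarray(depths, dtype=float)
    vals = averaged_dose(beam_axis_x(d, beam), d, beam, detector)
    return normalize_pdd(Curve(d, vals, "pdd", {"normalized": False}))


def ground_truth_profile(beam: BeamModel, xs, depth: float,
                         detector: DetectorModel | None = None) -> Curve:
    """Oracle lateral dose samples at one depth, on the common (cGy) scale."""
    x = np.asarray(xs, dtype=float)
    vals = averaged_dose(x, np.full_like(x, float(depth)), beam, detector)
    return Curve(x, vals, "profile", {"depth_mm": float(depth), "normalized": False})


def beam_for_field(field_cm: float, *, ssd_mm: float = 1000.0, depth_mm: float = 0.0,
                   **overrides) -> BeamModel:
    """Beam whose nominal field side equals ``field_cm`` at ``ssd + depth``.

    Field sizes are conventionally stated at the measurement plane (e.g. the
    isocenter for output factors at SSD 95 cm / depth 5 cm); the surface
    width is back-projected accordingly.
    """
    if field_cm <= 0.0:
        raise ValueError("field size must be positive")
    w_surface = field_cm * 10.0 * ssd_mm / (ssd_mm + depth_mm)
    return BeamModel(field_width_w=w_surface, ssd=ssd_mm, **overrides)
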