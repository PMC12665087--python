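"""Small-field output factors (FOF).

The field output factor Omega of a small field is the ratio of absorbed dose
to water at the small field to that at the 10 x 10 cm^2 reference field,

    Omega = D_small / D_ref = (M_small / M_ref) * k,

where M are the detector readings and k is the detector- and field-specific
output correction factor (k_Qsmall,Qref).  k values are consumed as a
user-supplied table (TRS-483 style); for plastic scintillators k = 1 is the
accepted value, making Omega the pure reading ratio.  As a ratio, Omega is
invariant under any common rescaling of the readings (calibration-free).

Readings are the mean smoothed signal over a stationary acquisition
(default 10 s), not a moving scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .beam import DetectorModel, PulseConfig, beam_axis_x, beam_for_field, simulate_scan
from .geometry import ScanTrajectory
from .pulses import CalibrationSet, station_reading

__all__ = ["FofInputs", "FofResult", "compute_fof", "fof_table",
           "simulated_fof_inputs"]


@dataclass(frozen=True)
class FofInputs:
    """Paired readings for one field size at one geometry."""

    m_small: float            # reading at the small field
    m_ref: float              # reading at the 10 x 10 cm^2 reference field
    k: float = 1.0            # output correction factor k_Qsmall,Qref
    field_cm: float = float("nan")
    ssd_mm: float = float("nan")
    depth_mm: float = float("nan")
    detector: str = ""

    def __post_init__(self) -> None:
        if not (self.m_ref > 0.0):
            raise ValueError("reference reading must be positive")
        if not (self.k > 0.0):
            raise ValueError("output correction factor k must be positive")


@dataclass(frozen=True)
class FofResult:
    omega: float
    field_cm: float
    ssd_mm: float
    depth_mm: float
    detector: str = ""

    def __post_init__(self) -> None:
        if not (self.omega > 0.0):
            raise ValueError("output factor must be positive")


def compute_fof(inputs: FofInputs) -> FofResult:
    """Omega = (M_small / M_ref) * k; with k = 1 (scintillators) a pure ratio."""
    omega = inputs.m_small / inputs.m_ref * inputs.k
    return FofResult(omega, inputs.field_cm, inputs.ssd_mm, inputs.depth_mm,
                     inputs.detector)


def fof_table(readings: Sequence[FofInputs]) -> pd.DataFrame:
    """Output factors per field size and geometry, wide by detector.

    Each detector/geometry group must share a single reference reading.
    When several detector series are present, percent-difference columns
    against the first detector (in input order) are appended.
    """
    if not readings:
        raise ValueError("no readings")
    rows = []
    for r in readings:
        res = compute_fof(r)
        rows.append({"detector": r.detector, "field_cm": r.field_cm,
                     "ssd_mm": r.ssd_mm, "depth_mm": r.depth_mm,
                     "m_ref": r.m_ref, "omega": res.omega})
    df = pd.DataFrame(rows)
    for (det, ssd, depth), grp in df.groupby(["detector", "ssd_mm", "depth_mm"]):
        if grp["m_ref"].nunique() > 1:
            raise ValueError(
                f"detector {det!r} at SSD {ssd} mm / depth {depth} mm mixes "
                "different reference readings")
    wide = df.pivot_table(index=["field_cm", "ssd_mm", "depth_mm"],
                          columns="detector", values="omega").sort_index()
    detectors = [d for d in dict.fromkeys(r.detector for r in readings)]
    ref_det = detectors[0]
    for det in detectors[1:]:
        wide[f"pct_diff_{det}_vs_{ref_det}"] = \
            100.0 * (wide[det] - wide[ref_det]) / wide[ref_det]
    return wide.reset_index()


def simulated_fof_inputs(field_cm_list: Sequence[float], *,
                         ref_field_cm: float = 10.0, ssd_mm: float = 950.0,
                         depth_mm: float = 50.0,
                         detector: Optional[DetectorModel] = None,
                         detector_label: str = "psd", k: float = 1.0,
                         duration_s: float = 10.0, prf_hz: float = 360.0,
                         fluctuation_cv: float = 0.0, seed: int = 0,
                         window_ms: float = 40.0,
                         **beam_overrides) -> list[FofInputs]:
    """Station-scan readings from the simulator for a list of field sizes.

    Field sizes are defined at the measurement plane (ssd + depth); the
    detector sits on the beam axis.  One shared reference reading is
    acquired at ``ref_field_cm``.
    """
    if detector is None:
        detector = DetectorModel()
    cal = CalibrationSet(acr=detector.acr_true, cr=detector.cr_true)
    seeds = np.random.SeedSequence(seed).generate_state(len(field_cm_list) + 1) % (2 ** 31)

    def _reading(field_cm: float, s: int) -> float:
        beam = beam_for_field(field_cm, ssd_mm=ssd_mm, depth_mm=depth_mm,
                              **beam_overrides)
        x0 = float(beam_axis_x(depth_mm, beam))
        traj = ScanTrajectory.station(x0, depth_mm, duration_s)
        train = simulate_scan(beam, detector, traj,
                              PulseConfig(prf_hz, fluctuation_cv, int(s)))
        return station_reading(train, cal, window_ms)

    m_ref = _reading(ref_field_cm, int(seeds[-1]))
    return [FofInputs(m_small=_reading(f, int(s)), m_ref=m_ref, k=k,
                      field_cm=f, ssd_mm=ssd_mm, depth_mm=depth_mm,
                      detector=detector_label)
            for f, s in zip(field_cm_list, seeds[:-1])]
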