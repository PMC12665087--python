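#!/usr/bin/env python
"""Pulse-level processing: ACR calibration, smoothing, curve metrics.

Reads the raw trains from 01_simulate_beams.py, estimates the ACR from the
two wide-field station scans, converts every moving scan into a calibrated
curve (40 ms rolling smoothing), and reports the standard commissioning
metrics: effective spatial sampling, 80-20 penumbra and field width, plus
the scanning-speed effect on the penumbra.  Curves are resampled to a 0.5 mm
grid for compact storage under results/curves/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from scintidose import (CalibrationSet, ScanTrajectory, resample,
                        effective_sampling_interval_mm, estimate_acr,
                        estimate_center, field_width, normalize_pdd,
                        normalize_profile, penumbra_widths, process_scan,
                        read_pulse_csv, scenario_pair, write_curve_csv)

ROOT = Path(__file__).resolve().parents[1]
SIM, OUT = ROOT / "scratch" / "sim", ROOT / "results" / "curves"
OUT.mkdir(parents=True, exist_ok=True)

# ACR from the two equal-dose scenarios (true value in the simulator: 0.963)
pair = scenario_pair(read_pulse_csv(SIM / "acr_scenario_1.csv"),
                     read_pulse_csv(SIM / "acr_scenario_2.csv"))
acr = estimate_acr(pair)
print(f"ACR from the two-scenario method: {acr:.6f}")
cal = CalibrationSet(acr=acr, cr=1.0)

scans = {
    "pdd_10x10_20mms": ScanTrajectory.depth_scan(0.0, 298.0, 20.0),
    "profile_10x10_d13_20mms": ScanTrajectory.profile_scan(-90.0, 90.0, 20.0,
                                                           depth=13.0),
    "profile_3x3_d13_10mms": ScanTrajectory.profile_scan(-35.0, 35.0, 10.0,
                                                         depth=13.0),
    "profile_3x3_d13_20mms": ScanTrajectory.profile_scan(-35.0, 35.0, 20.0,
                                                         depth=13.0),
}

penumbras = {}
for name, traj in scans.items():
    curve = process_scan(read_pulse_csv(SIM / f"{name}.csv"), traj, cal)
    eff = effective_sampling_interval_mm(traj.speed, 40.0)
    if curve.kind == "pdd":
        curve = normalize_pdd(curve)
        print(f"{name}: {len(curve)} samples, effective sampling {eff:.1f} mm, "
              f"d_max {curve.meta['d_max_mm']:.1f} mm")
    else:
        center = estimate_center(curve)
        curve = normalize_profile(curve, center)
        pen = penumbra_widths(curve)
        penumbras[name] = pen.mean_mm
        print(f"{name}: center {center:+.2f} mm, field width "
              f"{field_width(curve):.2f} mm, penumbra {pen.mean_mm:.2f} mm, "
              f"effective sampling {eff:.1f} mm")
    write_curve_csv(resample(curve, 0.5), OUT / f"{name}.csv")

d10, d20 = penumbras["profile_3x3_d13_10mms"], penumbras["profile_3x3_d13_20mms"]
print(f"\nSpeed effect on the 3x3 penumbra: {d10:.2f} mm at 10 mm/s vs "
      f"{d20:.2f} mm at 20 mm/s (coarser effective sampling broadens the "
      f"measured edge by {d20 - d10:.2f} mm).")
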