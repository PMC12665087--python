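#!/usr/bin/env python
"""Simulate the raw water-tank acquisitions used by the downstream analyses.

Writes, under scratch/sim/ (bulky raw data, regenerated on demand):
  * a 10 x 10 cm^2 PDD depth scan and a crossline profile at 13 mm depth,
    scanned at 20 mm/s with 2% pulse-to-pulse output fluctuation;
  * 3 x 3 cm^2 profiles at 13 mm depth at both 10 and 20 mm/s (speed study);
  * the two wide-field ACR calibration station scans.

All pulse trains are seeded, so re-running reproduces the files byte for
byte.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from scintidose import (BeamModel, DetectorModel, PulseConfig, ScanTrajectory,
                        simulate_scan, write_pulse_csv)

OUT = Path(__file__).resolve().parents[1] / "scratch" / "sim"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260928

det = DetectorModel()
runs = []

beam10 = BeamModel(field_width_w=100.0)
runs.append(("pdd_10x10_20mms", beam10,
             ScanTrajectory.depth_scan(0.0, 298.0, 20.0)))
runs.append(("profile_10x10_d13_20mms", beam10,
             ScanTrajectory.profile_scan(-90.0, 90.0, 20.0, depth=13.0)))

beam3 = BeamModel(field_width_w=30.0)
for speed in (10.0, 20.0):
    runs.append((f"profile_3x3_d13_{speed:.0f}mms", beam3,
                 ScanTrajectory.profile_scan(-35.0, 35.0, speed, depth=13.0)))

for i, w in enumerate((40.0, 100.0)):
    runs.append((f"acr_scenario_{i + 1}", BeamModel(field_width_w=w),
                 ScanTrajectory.station(0.0, 15.0, duration=2.0)))

for i, (name, beam, traj) in enumerate(runs):
    cv = 0.0 if name.startswith("acr") else 0.02
    train = simulate_scan(beam, det, traj, PulseConfig(360.0, cv, SEED + i))
    write_pulse_csv(train, OUT / f"{name}.csv")
    print(f"{name}: {len(train)} pulses -> {OUT / (name + '.csv')}")

print("\nDone. Raw two-channel pulse data (t_s, Rs_nC, Rc_nC) ready for "
      "02_process_pulses.py.")
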