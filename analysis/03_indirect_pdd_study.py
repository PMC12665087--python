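#!/usr/bin/env python
"""Direct vs indirect PDD for a tilted 0.5 x 0.5 cm^2 field.

The headline study: a 0.01 rad beam inclination is imposed on the smallest
field, and three depth-dose measurements are compared with the ground-truth
central-axis curve of the same detector:

  1. an uncorrected vertical depth scan (what a detector that cannot talk to
     the tank's inclination correction delivers);
  2. a depth scan along the inclination-corrected lateral track, with the
     angle estimated from profiles at 50 and 280 mm;
  3. the indirect PDD reconstructed from the peaks of 31 profiles.

Writes the three curves and a deviation table under results/indirect/.
"""

import math
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from scintidose import (BeamModel, DetectorModel, build_indirect_pdd, resample,
                        corrected_pdd_trajectory, estimate_inclination,
                        ground_truth_pdd, simulated_direct_pdd,
                        simulated_profile_set, write_curve_csv)

OUT = Path(__file__).resolve().parents[1] / "results" / "indirect"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260928

beam = BeamModel(field_width_w=5.0, tilt_theta=0.01)
det = DetectorModel()

pset = simulated_profile_set(beam, det, seed=SEED)
res = build_indirect_pdd(pset)
print(f"31 profiles scanned at 10 mm/s; peak track slope {res.track_slope:.6f} "
      f"(imposed tan(tilt) = {math.tan(0.01):.6f})")

depths = list(res.depths)
est = estimate_inclination(pset.profiles[depths.index(50.0)],
                           pset.profiles[depths.index(280.0)])
print(f"Estimated inclination from 50/280 mm profiles: {est.theta:.6f} rad "
      f"({math.degrees(est.theta):.3f} deg)")

surface = est.c_shallow - est.d_shallow * math.tan(est.theta)
ctraj = corrected_pdd_trajectory(est, surface_center=surface)
direct_c = simulated_direct_pdd(beam, det, lateral_track=ctraj.lateral_track,
                                seed=SEED + 1)
direct_u = simulated_direct_pdd(beam, det, seed=SEED + 2)

rows = []
for d in res.depths:
    truth = float(ground_truth_pdd(beam, res.depths, det).interp(d))
    rows.append({
        "depth_mm": d,
        "truth_pct": truth,
        "indirect_pct": float(res.pdd.interp(d)),
        "direct_corrected_pct": float(np.interp(d, direct_c.abscissa,
                                                direct_c.values)),
        "direct_uncorrected_pct": float(np.interp(d, direct_u.abscissa,
                                                  direct_u.values)),
    })
tab = pd.DataFrame(rows)
for col in ("indirect", "direct_corrected", "direct_uncorrected"):
    tab[f"dev_{col}_pp"] = tab[f"{col}_pct"] - tab["truth_pct"]
tab.to_csv(OUT / "deviation_table.csv", index=False, float_format="%.4f")
write_curve_csv(res.pdd, OUT / "indirect_pdd.csv")
# direct scans carry ~10k per-pulse samples; store them on a 1 mm grid
write_curve_csv(resample(direct_c, 1.0), OUT / "direct_corrected_pdd.csv")
write_curve_csv(resample(direct_u, 1.0), OUT / "direct_uncorrected_pdd.csv")

beyond = tab[tab.depth_mm > 5.0]
print(f"\nMax |deviation| vs ground truth beyond build-up (depth > 5 mm):")
print(f"  indirect reconstruction : {beyond.dev_indirect_pp.abs().max():.3f} pp")
print(f"  corrected direct scan   : {beyond.dev_direct_corrected_pp.abs().max():.3f} pp")
print(f"  uncorrected direct scan : {beyond.dev_direct_uncorrected_pp.abs().max():.3f} pp"
      f" (grows monotonically with depth — the detector drifts off-axis)")
print(f"\nTable -> {OUT / 'deviation_table.csv'}")
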