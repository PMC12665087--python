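"""Independent brute-force gamma oracle and random depth-dose curve factory.

The oracle searches the reference on a dense uniform grid (default 1 um)
plus the exact window endpoints — deliberately naive, sharing no code with
the package's candidate-point search.
"""

import numpy as np

from scintidose import Curve


def brute_force_passes(depth, dose, reference, dose_tol, dist_tol, grid=0.001):
    lo = max(depth - dist_tol, reference.abscissa[0])
    hi = min(depth + dist_tol, reference.abscissa[-1])
    r = np.append(np.arange(lo, hi, grid), hi)
    vals = np.interp(r, reference.abscissa, reference.values)
    return bool(np.abs(vals - dose).min() <= dose_tol)


def random_pdd_like_curve(rng, n_knots=24, span=(0.0, 300.0), sample_step=3.0):
    """Smooth random depth-dose-like curve: a decaying trend plus gentle
    bumps, with slopes of at most a few percentage points per mm (realistic
    for PDDs outside build-up)."""
    knots = np.linspace(span[0], span[1], n_knots)
    vals = np.clip(100.0 * np.exp(-0.004 * knots) + rng.normal(0.0, 4.0, n_knots),
                   1.0, None)
    x = np.arange(span[0], span[1] + 1e-9, sample_step)
    return Curve(x, np.interp(x, knots, vals), "pdd", {"normalized": False})
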