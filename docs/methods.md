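# Methods

This note records the models behind `scintidose`, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not demonstrate about real measurements.

## The synthetic beam

The simulator supplies ground truth for every analysis stage. It is an
*analytic* stand-in for a 6 MV flattening-filter-free (FFF) beam chosen for
closed-form testability, not a transport calculation.

**Depth dose.** `pdd(d) ∝ (1 − e^{−k·d}) · e^{−μ·max(0, d−d_max)}`,
rescaled so its maximum over depth is exactly 100. Defaults: build-up rate
k = 0.4 /mm, d_max = 15 mm, effective attenuation μ = 0.004 /mm — PDD(10 cm)
≈ 71%, in the range of clinical 6 MV data. For the defaults the analytic
peak of the product lies below d_max, so the normalization constant is the
value at d_max (closed form, no grid search). The formula has zero surface
dose; real beams have 40–60% — see Limitations.

**Lateral profile.** A double-erf field edge,
`p(u) ∝ erf((w_d/2 − u)/σ√2) + erf((w_d/2 + u)/σ√2)`, normalized to 100 at
the beam axis `u = 0`. The field side diverges with depth,
`w_d = w·(ssd + d)/ssd`, and the axis may be tilted and offset:
`u = x − (x₀ + d·tanθ)`. Edge blur σ defaults to 2 mm, which together with
the detector kernel reproduces measured small-field penumbras of ~3.4 mm.
Because the profile is axis-normalized, the simulator carries **no output
factor physics** beyond volume averaging (see Output factors below).

**Detector.** A 1 mm ⌀ × 1 mm scintillating cylinder (sensitive volume
π/4 ≈ 0.785 mm³). Its finite length volume-averages the lateral dose: a
rectangular kernel of width L = 1 mm, evaluated by 16-node Gauss–Legendre
quadrature in the simulator and by exact piecewise-linear integration for
sampled curves. A rectangular kernel adds L²/12 to the edge variance, so
measured penumbras approach 1.6832·√(σ² + L²/12); the suite verifies this
to 0.5%. A bare fiber trails the sensor along −x; its in-field length times
the pulse dose times a coupling coefficient gives the Cerenkov channel.

**Pulses.** One record per pulse at 360 Hz with Gaussian per-pulse output
fluctuation (CV 2% by default) applied to both channels, everything driven
by a single seed (bit-identical reruns). The repetition rate and
fluctuation magnitude are plausible stand-ins — vendors do not publish
them — and both are configurable; none of the validated quantities depends
on their exact values.

## Processing chain

* **Stem correction** is the linear subtraction `Rs − ACR·Rc`. The ACR
  estimator averages each scenario's channels before forming the quotient
  (unbiased under symmetric noise). In the simulator the two equal-dose
  scenarios are two *wide* fields (40 and 100 mm): both leave the detector
  in the flat profile region, so the sensor dose matches to machine
  precision while the irradiated fiber length changes. A narrow field would
  break the equal-dose premise through volume averaging of its curved apex
  (~10⁻³ relative, which is exactly the bias the estimator then inherits).
* **Smoothing** is a centered, *time-based* 40 ms moving mean; windows
  shrink at the series ends rather than padding, so no data is fabricated
  beyond the scan span. Time-based means beam holds reduce averaging rather
  than stretching it. Whether a real acquisition system centers or trails
  its window is not observable from the outputs we model; centered is the
  symmetric choice and keeps profile centers unbiased.
* **Position mapping** is `x = start + v·(t − t₀)`; with the 40 ms window
  this yields the 0.4 mm (10 mm/s) and 0.8 mm (20 mm/s) effective sampling
  intervals.
* **Centering** uses 50%-of-*maximum* edge crossings (robust for FFF and
  small fields that have no flat top), linear interpolation, outermost
  crossing on ties. **Inclination** is atan of the center drift between 50
  and 280 mm. Both depths are configurable.

## Indirect PDD

Each profile is reduced to its peak: discrete argmax (lowest index on
ties) refined by the parabola through the three bracketing samples. The fit
is performed in coordinates relative to the discrete maximum, making the
refined peak *exactly* shift-invariant — the property behind the method's
alignment insensitivity, which the suite checks to 1e-9 under random ±2 mm
per-profile offsets. Parabolic refinement resolves the peak to ≪ 0.05 mm
on the 0.4 mm sampling grid of a 10 mm/s scan.

The default schedule is 31 depths: 1, 5, 10, 15, then every 10 mm to
280 mm. It includes d_max so that normalizing the sampled curve anchors at
the true maximum, and starts at 1 mm rather than 0 because the analytic
build-up gives exactly zero surface dose (a depth-0 profile is flat and is
correctly rejected as peakless).

The reconstruction requires all profiles on one common signal scale; the
`DepthProfileSet.common_scale` flag asserts this and the builder refuses to
run without it. Inter-acquisition machine output drift is *not* modelled or
corrected — on a real linac, output stability across the ~31 acquisitions
is a precondition of the method.

**Comparison reference.** Reconstructed and scanned PDDs are compared
against the *volume-averaged* CAX depth dose — what an ideal, perfectly
tracked scan of the same 1 mm detector would read — because comparing a
finite detector to a point dose would mix geometry errors with volume
averaging. Pipeline-level comparisons exclude depths ≤ 5 mm: at the scan
start the shrinking smoothing window is one-sided and biases samples on the
steep build-up slope. The pure-geometry claim (corrected track ≡ CAX truth
at *all* depths) is tested unsmoothed and noise-free, where it holds to
< 0.1 pp. For a tilted beam the uncorrected vertical scan's deviation is
asserted to grow monotonically with depth *beyond d_max*; below d_max the
shared normalization anchor forces the deviation through zero, so
monotonicity through build-up is not a meaningful claim.

## Gamma

The pass criterion is a box: within ±dist_tol of the measured depth there
must be a reference point whose dose differs by ≤ dose_tol. Dose
differences are global percentage points on 100-normalized curves (the
1D-PDD convention); a local mode is available behind a flag. Measured
samples are the evaluation set.

Numerics: the reference is piecewise linear, so within the window the
minimum |dose difference| is attained at a reference knot, a window
endpoint, or an exact crossing (which passes trivially). The search
therefore evaluates knots + window endpoints + a 0.01 mm grid — the box
decision is *exact* for sampled references, and the suite confirms
agreement with an independent 1 µm brute-force search on 100 random curve
comparisons. The Low-style elliptic `gamma_value` is also provided;
an ellipse pass implies a box pass at equal tolerances, never the reverse.

## Output factors

Ω = (M_small/M_ref)·k, with readings defined as the mean smoothed signal
over a 10 s stationary acquisition on the beam axis. k values are consumed
from a user-supplied table keyed by detector and field size (k = 1 for
scintillators); the package does not derive them. Field sizes are defined
at the measurement plane and back-projected to the surface. Being a ratio,
Ω is exactly invariant under common rescaling of the readings.

Because the synthetic profile is CAX-normalized and the simulator
deliberately omits source occlusion and loss of lateral charged-particle
equilibrium, simulated Ω varies only through volume averaging of the
narrowing apex (~0.6% at 0.5 × 0.5 cm²). The simulator validates the
*algebra* (ratio, k handling, scale cancellation, monotone shrinkage), not
the magnitude of clinical small-field output drops.

## File formats and determinism

Pulse CSV (`t_s,Rs_nC,Rc_nC`) and curve CSV (`abscissa_mm,value` + JSON
sidecar with kind/depth/normalization) are open text dialects; numbers are
written with 17 significant digits so round-trips are bit-exact, and all
writes are atomic (temp file + rename). Every stochastic component takes a
seed; identical configuration and seed reproduce identical files.

## Problem sizes

The validation studies are sized for desk-scale reruns: profile scans of
2–3 s at 360 Hz (~900 pulses each, 31 per PDD study), 28 s depth scans
(~10⁴ pulses), 50 random curve pairs for the gamma oracle, 10³ draws for
the algebraic property sweeps. The full suite runs in a few seconds.

## Known limitations

* Zero surface dose and a single-exponential tail; no electron
  contamination, head scatter, source occlusion, or MLC leaf effects — so
  absolute small-field output factors and build-up shapes are not
  realistic, only the processing chain around them.
* The Cerenkov model is proportional to in-field fiber length with a fixed
  coefficient; angular and spectral dependence of Cerenkov generation are
  not modelled.
* Detector volume averaging is one-dimensional (along the scan axis);
  the 1 mm diameter perpendicular to it is ignored.
* CR cross-calibration against an ion chamber is out of scope; calibration
  factors are configuration inputs.
* Passing the synthetic suite demonstrates correctness of the algorithms
  under the stated beam model, not detector physics (temperature, dose-rate
  or radiation-damage effects are assumed away, consistent with published
  PSD characterizations).
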