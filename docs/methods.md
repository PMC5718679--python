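# Methods

## The measurement model

A helical CT scan translates the table at steady speed
`v = pitch × W / t_rot`, where `W` is the total beam collimation (mm) and
`t_rot` the rotation time (s). Reconstruction needs data beyond both VOI
boundaries, so the exposed length exceeds the VOI by the over-ranging
length `L_over`. The direct estimator measures two times on the
dose-rate waveforms, both read at 10% of each trace's maximum:

* `T` — the bore dosimeter's above-threshold interval (beam-on time);
* `Δt` — the delay between the two table dosimeters' leading crossings,
  giving `v = d / Δt` for a known separation `d`.

Two length conventions are kept explicit because they differ by exactly
one collimation width and conflating them is a documented failure mode of
console-based estimates:

* **exposure** (default): total = `v·T + W`. Film confirms the beam
  exposes half a collimation width beyond each end of the translation.
* **translation**: total = `v·T`, the console-like displacement length.

`L_over = total − L_VOI`. Non-positive results are flagged
(`degenerate=True`) rather than raised so parameter sweeps do not abort.
The estimator raises only when the exposure cannot cover the declared
VOI at all (bore plateau too short), which indicates mismatched inputs
rather than a degenerate protocol.

## Ground-truth over-ranging law (simulator)

The simulator embeds
`L(pitch, st) = (a + b·pitch) × f(st)` with `f = 1` in the thin-slice
regime (cone-beam-corrected reconstruction) and, above the regime
boundary where the scanner switches to z-filtering,
`f(st) = [c·(1+j) + m·(st − st_b)] / c` — a jump by fraction `j`
followed by linear growth. Defaults (24 mm collimation):
`a = 33.75 mm`, `b = 20.1 mm` per pitch unit (i.e. 43.8 mm at pitch 0.5,
63.9 mm at pitch 1.5), boundary 4 mm, jump 77%, plateau normaliser
25.5 mm, slope reaching 52.5/25.5 of the plateau at 10 mm slices. The
12 mm defaults use plateau 11.1 mm (boundary 2 mm, jump 88%, 29.7 mm at
10 mm slices) with the same relative pitch law rescaled onto the plateau.

The joint pitch × slice-thickness dependence has not been measured
anywhere we know of; combining the two laws multiplicatively around the
reference configuration (pitch 1.0, thin-slice regime) is a simulator
convention. Consequently the default protocol reconstructs at 3 mm
(thin-slice regime), where the pitch-law anchor applies exactly. By
construction `L` is independent of rotation time and VOI length and is
strictly positive on the whole scanner menu (asserted by test).

## Simulator conventions

* **Beam profile**: trapezoid, linear penumbrae of width 10% of `W` per
  side, with the full width **at the 10% level** defined equal to `W`.
  This makes the timing convention self-consistent: a table trace's
  10%-level width is `W / v` and its leading crossing marks the instant
  the dosimeter sits `W/2` from the beam centre. Real penumbra widths
  are scanner-specific; the choice preserves well-defined crossings.
* **Beam-on envelope**: 50 ms linear edges positioned so the bore
  trace's 10% crossings fall exactly at beam-on/off. The envelope shape
  below/above 10% is unobservable by the method.
* **Geometry**: VOI at `[0, L_VOI]`; exposed region
  `[−L/2, L_VOI + L/2]` (the end-split is unobservable; only the total
  matters); beam centre travels `D = L_VOI + L − W` during `T`, so
  `v·T + W − L_VOI = L` identically for ramp-free scans.
* **Table dosimeters** default to 15 mm inside each VOI boundary. At low
  pitch the beam base already overlaps the VOI edge at turn-on, so
  boundary-mounted dosimeters would not record clean trapezoids; the
  simulator validates that every transit happens strictly inside the
  steady-speed beam-on window and raises otherwise. The VOI length is
  metadata (scout-defined), never inferred from the traces.
* **Noise**: multiplicative Gaussian per sample, default 1% (no
  published noise model for the hardware); **ripple**: optional ≤ 5%
  sinusoidal modulation at the rotation frequency with random phase;
  **ramps**: table acceleration defaults to 0 s (negligible on the
  modelled scanner; the dosimeters sit mid-scan), but a linear ramp is
  supported for robustness studies — it biases the direct estimate
  upward by at most `v·t_ramp/2`; **detector size**: optional boxcar
  average over the 0.5 mm scintillator extent, default off (point
  detector).
* All randomness flows from a single integer seed; a sweep derives one
  child seed per combination from the config seed, so identical configs
  produce byte-identical CSVs.

## Edge detection numerics

Threshold = fraction (default 0.10) of the trace maximum. The single
above-threshold run is located; multiple runs raise an error listing the
runs (an optional 3-sample median pre-filter suppresses isolated
spikes). Crossings are refined by linear interpolation between the two
straddling samples, which is exact when both lie on a penumbra ramp and
bounded by one sample period otherwise; sample-aligned mode
(`interpolate=False`) reproduces hardware that reports whole-sample
times. Ties at exactly the threshold resolve to the earliest sample on
the leading edge and the latest on the trailing edge.

Quantization dominates the error budget: one sample period maps to
`v × 10 ms` ≈ 0.5 mm of length at the fastest table speeds. The
acceptance property asserts noise-free recovery within that bound; in
practice interpolation keeps residuals near 0.1 of it.

## Comparators

* **Dose-slope**: unweighted OLS of DLP against number of rotations
  (no weighting scheme is published for the original method); the
  intercept at zero rotations is the over-ranging DLP and
  `intercept / CTDIvol` the length. The conversion assumes
  `DLP = CTDIvol × length` holds across the over-ranged region, which is
  only a first approximation at scan edges — the method's inherent bias.
  Fit diagnostics (R², intercept standard error) ride along.
* **Adjusted console**: console over-range minus `W/2`; over-corrected
  (non-positive) values warn instead of raising.

## Uncertainty budget

Quadrature of independent terms. Three-dosimeter mode: console distance
precision (0.5 mm) ⊕ timing term `v × 10 ms` → 0.71 mm at 50 mm/s.
One-dosimeter mode replaces the console precision with the console
co-dependence allowance (QC bound, worst case 2 mm) and reports a
relative error against the scan length (≈ 1.1% for a 19.1 cm scan).
The worst-case scintillator-extent term (0.5 mm) assumes uniform
response over the cylinder cross-section, which the geometry makes
unlikely; it is excluded by default and switchable on.

## Film analysis

The synthetic CR strip renders the exposure band (translation ⊛ beam
profile: flat top `D + W − 1.8p`, ramps `p`) so its 10%-level extent is
`D + W`; three fiducial markers are drawn, the calibration pair at the
VOI boundaries with known separation. Band measurement takes the mean
column profile (integrating across the strip width — the simplest
reproducible choice), thresholds at 10% of its maximum and interpolates
the crossings, making the length invariant to global intensity scaling.
Markers are kept small (3 rows) so their bump in the mean profile stays
below threshold outside the band; they bias the band measurement by
well under a pixel. Multi-image averaging reports mean ± sd in pixels.

## What the simulator does and does not emulate

Emulated: helical kinematics, trapezoidal beam passage, beam-on
plateau, sampling quantization, multiplicative noise, rotation ripple,
table-speed ramps, finite detector extent, the CR exposure pattern.

Not emulated: scatter (the real dosimeters hang free-in-air to suppress
it), energy spectra and bowtie filtration, tube-current modulation
(off on the modelled protocol), dynamic/adaptive collimation (the
method itself does not apply to such scanners), film sensitometry and
CR plate artifacts, patient/table sag or positioning error. Passing
recovery tests therefore demonstrates the correctness of the timing
arithmetic and its quantization behaviour, not robustness to those
physical effects.

## Problem sizes

Test and acceptance runs use trace lengths of a few hundred to a few
thousand 10 ms samples per scan, 100 random noise-free scans, 50 noisy
replicates, 5-point dose-slope series and 50 random film geometries —
sizes chosen so the whole suite exercises every code path in seconds
while leaving the quantization-dominated error regime intact.

## Known limitations

* The ground-truth law's absolute scale in the z-filtering regime
  follows the multiplicative convention above, not a measured joint
  dependence; recovered lengths there validate the estimator, not the
  scanner physics.
* The dose-slope comparator inherits the edge-region CTDI approximation.
* One-dosimeter mode is only as accurate as the console speed it is
  handed; the budget models this as a bounded allowance, not a
  distribution.
* The exposure-convention `+W` term assumes a symmetric beam; asymmetric
  collimator misalignment is not modelled.
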