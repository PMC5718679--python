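# overrange-kit

Tools for quantifying **over-ranging** in helical computed tomography: the
extra longitudinal length irradiated beyond the clinical volume of
interest (VOI) because the reconstruction algorithm needs projection data
from at least half a gantry rotation before the first slice and after the
last one. Over-ranging adds dose-length product (DLP) — typically around
10% extra dose on a routine abdominal scan — without appearing in the
VOI-only DLP that consoles traditionally report. The package is aimed at
medical physicists who want to measure and budget that cost.

## The method

Three point dosimeters with 10 ms time resolution observe the scan:

* a stationary **bore** dosimeter stays inside the fan beam and times the
  beam-on interval `T` (the span between its 10%-of-maximum threshold
  crossings);
* two **table** dosimeters, a known distance `d` apart on the moving
  table, time their own transit: the delay `Δt` between their leading
  10% crossings gives the table speed `v = d / Δt`.

The total exposed length is then `v·T + W` (the beam exposes one half of
the collimation width `W` beyond each end of the table translation — a
film-verified correction), and the over-ranging length is

```
L_over = v·T + W − L_VOI
```

with a quadrature uncertainty budget of the console distance precision
(0.5 mm) and the timing term `v × 10 ms` (≈ 0.5 mm), about 0.7 mm total.

Because the physical scanner is not part of this package, a **simulator**
generates the three traces (trapezoidal table peaks, bore plateau,
configurable noise/ripple/ramps) from a ground-truth over-ranging law —
linear in pitch, piecewise constant-then-linear in reconstruction slice
thickness — so every estimator is testable by parameter recovery. Two
literature methods are included for cross-validation: **dose-slope
extrapolation** (OLS intercept of DLP vs number of rotations at zero
rotations) and **adjusted console readings** (console over-range minus
half a collimation width).

## Worked example

```python
from overrange_kit import (ScanProtocol, SimulationSpec, default_layout,
                           simulate_scan, direct_overrange, dose_report)

prot = ScanProtocol(pitch=1.0, rotation_time=0.5, collimation=24.0,
                    slice_thickness=3.0, voi_length=251.0, ctdi_vol=13.0)
layout = default_layout(prot)
spec = SimulationSpec(protocol=prot, layout=layout, noise_sd=0.01, seed=7)

bore, t1, t2, truth = simulate_scan(spec)
res = direct_overrange(bore, t1, t2, layout, prot.voi_length, prot.collimation)
rep = dose_report(prot.ctdi_vol, prot.voi_length, res.length)
```

prints (via the obvious f-strings):

```
ground truth over-range : 53.85 mm
measured table speed    : 48.01 mm/s
beam-on time            : 5.851 s
total exposed length    : 304.9 mm
over-ranging length     : 53.93 +/- 0.69 mm
over-ranging DLP        : 70.1 mGy cm
extra dose fraction     : 21.5 %
```

The estimator sees only the traces, yet recovers the embedded 53.85 mm
ground truth to 0.08 mm — well inside one timing quantum
(48 mm/s × 10 ms ≈ 0.5 mm). The 70 mGy·cm over-ranging DLP is what a
VOI-only dose report would silently omit for this 25.1 cm scan at
13 mGy CTDIvol.

The same pipeline is scriptable from the shell:

```bash
overrange-kit simulate --noise 0.01 --seed 7 --out scan/
overrange-kit overrange direct --bore scan/bore.tsv --t1 scan/table_1.tsv \
    --t2 scan/table_2.tsv --sep-mm 221 --voi-mm 251 --collimation-mm 24 --ctdi 13
overrange-kit sweep --config run.yaml --out results/
```

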