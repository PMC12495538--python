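# mmskin

Millimeter-wave reflection and absorption modeling of human skin, for
tissue dosimetry and absorbed-power-density (APD) compliance work in the
5G/6G bands (10–110 GHz).

Exposure limits above 6 GHz are expressed as absorbed power density at the
body surface, so compliance testing needs skin models that reproduce — and
conservatively bound — how much of an incident field the skin absorbs. At
millimeter waves the outermost skin layer, the stratum corneum (SC), acts
as an impedance-matching layer: thin SC (~20 µm, most of the body) reflects
more than thick SC (200–300 µm, palms and fingers), and the spread across a
population sets how conservative a single model must be. `mmskin`
implements the full modeling chain behind such models:

- **`mmskin.dispersion`** — single-pole Cole–Cole/Debye complex
  permittivity, ε(f) = ε∞ + (εs − ε∞)/(1 + (jωτ)^(1−α)) − jσ/(ε₀ω), with
  conversion of Cole–Cole models to band-limited Debye fits;
- **`mmskin.layered`** — analytic plane-wave reflection Γ of stratified
  dispersive stacks by recursive impedance transformation (any incidence
  angle and polarization), plus the spectral-domain TE/TM admittance of a
  stack per transverse wavenumber;
- **`mmskin.waveguide`** — a mode-matching solver for the TE₁₀ reflection
  coefficient of flanged open-ended rectangular waveguide probes
  (WR42/WR28/WR15/WR10) pressed against a layered medium — the quantity a
  VNA actually measures on skin — including the aperture fringing fields;
- **`mmskin.fitting`** — constrained SQP recovery of layer parameters
  (inner-skin Debye parameters; thick-SC thickness and parameters) from
  dB-magnitude reflection spectra, with seeded multi-start;
- **`mmskin.stats`** — the cohort statistics used to derive
  population-coverage models: repeat/site/subject aggregation, Shapiro–Wilk
  dB-normality tests, paired thin/thick t-tests, Bartlett variance checks,
  frequency-wise normalization, and mean − k·σ coverage curves;
- **`mmskin.cohort`** — a seeded synthetic-cohort generator (44 subjects,
  age/sex strata, 17 sites, 3 repeats) whose thick-SC sites carry a
  lognormal thickness core plus a manual-labor mixture component, so the
  whole pipeline is testable end to end without volunteer data;
- **`mmskin.io`** — Touchstone 1.x `.s1p` and CSV spectra, YAML model
  registry (shipped gel-phantom and skin models).

## Worked example

```python
import numpy as np
from mmskin import reflectance_db, s11_spectrum, WAVEGUIDE_REGISTRY
from mmskin.io import default_registry

reg = default_registry()
p95 = reg.stack("skin_thin_p95")      # 20 µm SC over the 95%-coverage inner layer

print(round(reflectance_db(p95, 15e9), 2), round(reflectance_db(p95, 110e9), 2))
# -2.87 -5.98

spec = s11_spectrum(WAVEGUIDE_REGISTRY["WR28"], reg.stack("gel_ptfe100"),
                    np.array([30e9]))
print(round(float(spec.magnitude_db[0]), 2))
# -3.44
```

The first two numbers are the plane-wave reflectance of the conservative
95 %-population-coverage thin-skin model at the band edges: at 15 GHz the
skin returns −2.87 dB of the incident field (48 % of the power absorbed),
at 110 GHz −5.98 dB (75 % absorbed). The third number is the mode-matching
TE₁₀ reflection a WR28 probe would measure on the PTFE-coated gel
validation phantom at 30 GHz.

The `examples/` directory contains one short narrative script per
capability (dielectric models, coverage-curve reflectance, waveguide
probe, parameter fitting, cohort statistics); each prints the numbers it
computes together with a line on what they mean.

A thin CLI wraps the same functions:

```bash
mmskin planewave --stack skin_thin_p95 --fmin 10e9 --fmax 110e9 -n 201 --out curve.csv
mmskin wg-s11 --probe WR28 --stack gel_ptfe100 --fmin 24e9 --fmax 42e9 -n 51 --out meas.s1p
mmskin simulate --seed 1 --out cohort.csv --truth truth.json
mmskin stats --cohort cohort.csv --out-prefix results/run1
```

## Scope notes

The solvers model planar, macroscopic stacks: no skin microstructure
(sweat glands, layer roughness), no thermal response, no finite-flange or
probe-pressure effects, and no VNA calibration modeling. See
`docs/methods.md` for model assumptions, numerical choices, and
limitations.
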