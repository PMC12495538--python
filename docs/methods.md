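# Methods

This note documents the models implemented in `mmskin`, their assumptions,
the numerical choices behind the solvers, what the synthetic-cohort
generator does and does not emulate, and the known limitations. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Dielectric models

Materials are described by a single-pole Cole–Cole relaxation with a
static-conductivity term,

    eps_r(f) = eps_inf + (eps_s − eps_inf) / (1 + (j·2πf·τ)^(1−α)) − j·σ/(ε0·2πf),

with `eps_inf ≥ 1` (dimensionless), `eps_s` (dimensionless), `σ` in S/m,
`τ` in seconds (stored as picoseconds in model files), and `α ∈ [0, 1)`
(`α = 0` is the Debye model). One pole plus conductivity is adequate for
skin tissue and tissue simulants over 10–110 GHz; multi-pole forms are out
of scope.

The whole package uses the `e^{+jωt}` time convention: passive media have
`Im(eps) ≤ 0`, and wavenumbers take the branch `Re ≥ 0`, `Im ≤ 0` so waves
decay into lossy media. Physical constants are CODATA 2018 values held in
`mmskin.constants`. The complex power `(jωτ)^(1−α)` uses the principal
branch; since `ωτ > 0` the argument never approaches the branch cut.

`fit_debye_to_dispersion` converts a Cole–Cole model to a band-limited
Debye fit (for FDTD-style solvers that accept only Debye poles) by
least-squares over a logarithmic frequency grid (default 50 points), real
and imaginary parts weighted equally.

Shipped model files (`src/mmskin/data/`) hold the gel-phantom validation
models (Cole–Cole gel, PTFE films, the rigid foam spacer) and the
two-layer skin models: a stratum-corneum (SC) surface layer over an
effective semi-infinite inner layer ("Layer D"). The thin-SC layer is
fixed at 20 µm — reported SC thicknesses outside the palms range from
under 10 µm to a bit above 20 µm, and at λ/100 electrical thickness its
exact value barely moves the reflection coefficient. The foam spacer's
conductivity encodes its measured loss tangent (2.68×10⁻³ at ~30 GHz);
because probe calibration places the reference plane at the flange/sample
interface, the foam is not part of any default stack.

## Plane-wave reflection of stratified media

`plane_wave_reflection` computes the field reflection coefficient Γ at the
first interface by recursive transmission-line impedance transformation:
per layer, `Z_in = Zc (Z_L + j Zc tan(kz d)) / (Zc + j Z_L tan(kz d))`
with `kz = sqrt(eps k0² − kt²)` and TE/TM characteristic impedances
`ωμ0/kz` and `kz/(ωε0 eps)`. Layers attenuating by more than 300 nepers
are treated as half-spaces to avoid overflow in `tan`. The test suite
checks the recursion against an independently written 2×2 ABCD
transfer-matrix cascade on random stacks (agreement ~10⁻¹⁵ relative,
asserted < 10⁻¹⁰).

The dB convention is `20·log10 |Γ|` of the field coefficient (equal to
`10·log10` of the power reflectance), matching how probe measurements are
reported. `absorbed_power_fraction` returns `1 − |Γ|²`, which equals the
absorbed fraction when the incident medium is lossless and the stack is
terminated by a lossy half-space. Reflectance quantities are quoted at
normal incidence by default — the standard choice for APD compliance
surfaces, and TE/TM coincide there — with oblique angles and both
polarizations retained for generality. `reflectance_db` returns a `-inf`
sentinel for a perfectly matched stack.

## Open-ended waveguide probe (mode matching)

`te10_reflection` models what a flanged open-ended rectangular waveguide
probe measures: the complex TE₁₀ reflection coefficient referenced at the
flange/sample plane, with the flange assumed infinite and perfectly
conducting. The aperture electric field is expanded in the orthonormal
waveguide-mode basis; the exterior field is a 2-D spectrum of TE/TM plane
waves, each weighted by the layered stack's input admittance at its
transverse wavenumber; Galerkin projection of tangential-H continuity
yields `(Y_ext + diag(Y_g)) R = (diag(Y_g) − Y_g) e₁`-form dense linear
systems whose first unknown is S₁₁. Mode spectra reduce to closed-form
1-D sine/cosine transforms, so the only numerics are the polar spectral
integrals.

Numerical choices (all in `MMSettings`):

- **Mode set.** Only modes sharing the TE₁₀ symmetry (m odd, n even)
  couple; the default basis retains the 64 lowest-cutoff such modes.
  64 was frozen after a self-convergence sweep over the gel and skin
  fixtures: doubling both the mode count and the quadrature density then
  moves |S₁₁| by at most ~0.03 dB (recomputed by the acceptance script).
  A full-parity basis is available as a consistency check — the
  non-coupling modes must not change S₁₁ (asserted to 10⁻⁸).
- **Spectral integration.** Polar coordinates over one quadrant (×4 by
  symmetry); radial panels are fine up to 8 k0 (where the layered
  admittance varies fastest) and grow geometrically to a truncation
  radius of 30 k0 (raised automatically to 2.5× the largest retained
  cutoff wavenumber); Gauss–Legendre points per panel, with the angular
  count growing with the panel's electrical radius to track the
  oscillation of the mode spectra. Lossy terminations keep all branch
  points off the real axis, so no contour deformation is needed; the
  solver requires the terminal half-space to be lossy.
- **Sanity limits exercised in tests:** a σ → ∞ half-space returns
  S₁₁ → −1 (short circuit at the reference plane); a very dense lossy
  half-space approaches the plane-wave Fresnel value; |S₁₁| ≤ 1 on all
  passive fixtures.

`te10_transverse_resonance` implements the deliberately naive single-mode
shortcut (layered TE admittance at kt = π/a, no aperture coupling). Its
deviation from mode matching — several tenths of a dB for a 100 µm PTFE
cover on gel — quantifies the fringing-field contribution that must be
modeled for low-permittivity cover layers.

The probe registry uses EIA standard inner dimensions for WR42, WR28,
WR15, WR10. Quoted operating floors of 14 GHz (WR42) and 21 GHz (WR28)
sit at or below the air-filled TE₁₀ cutoffs (14.05 / 21.08 GHz); the
registry floors are therefore trimmed to 15 and 22 GHz.

## Layer-parameter fitting

Both fitters minimize the summed squared deviation of dB magnitude
between the forward model and a multi-band target, by SLSQP (an SQP
method) under box bounds and the constraint `eps_s ≥ eps_inf`, with
seeded multi-start (default 8 starts) against local minima. Fitting dB
magnitude only — not complex S₁₁ — is deliberate: population summaries
and coverage curves are dB-magnitude quantities, and phase is not
available for cohort means. All frequency points are weighted equally;
near-duplicate frequencies across overlapping bands are merged onto the
first band's grid point.

`fit_layer_d` frees the inner-layer Debye parameters under a fixed thin
SC; `fit_sc_thick` frees the thick-SC thickness (bounds 50–600 µm) and
its Debye parameters (σ fixed at 0 — the low-water SC is essentially
non-conducting) over a fixed inner layer. Optimization runs in scaled
units (τ in ps, thickness in µm) so SLSQP's step heuristics behave.
Bound-pinned optima are flagged in `FitResult.bounds_active`.

The forward model is either mode matching (the physically faithful
choice, since probe data are aperture quantities) or the normal-incidence
plane-wave solver as a fast approximation. The recovery harness and the
acceptance script use the fast mode with four probe-band grids spanning
15–110 GHz (14/21/16/15 points); at zero noise every shipped parameter
set is recovered with residuals at the numerical noise floor, which is
what makes the fast mode a valid screening tool. With 0.1 dB point noise
the eps_s/σ ridge of the dB-magnitude objective becomes noise-limited at
sparse grids; the noise-robustness test therefore uses VNA-density grids
(hundreds of points per band), where the mean eps_s bias stays below 5 %.

## Cohort statistics

All statistics operate on dB values (log-normal magnitude = normal dB).
The aggregation order is fixed: average the 3 repeats per site, then the
sites of one SC class within a subject, then form cross-subject mean/sd
per frequency. Shapiro–Wilk tests dB-normality per frequency (p > 0.05
read as compatible); the thin/thick contrast is a two-sided paired t-test
with a 95 % CI; factor comparisons (sex, age group) run on
frequency-normalized residuals with a pooled t-test plus Bartlett's
variance-homogeneity check (pooled rather than Welch because homogeneity
is tested alongside). No multiple-testing correction is applied across
frequencies — results are reported per frequency, as such cohort tables
conventionally are.

Coverage curves are `mean − k·sd` per frequency. The conventional labels
"68 %" and "95 %" for k = 1, 2 come from two-sided normal mass; as
one-sided exceedance bounds they actually cover ≈ 84 % and ≈ 97.7 % of a
normal population. The package keeps the conventional labels and
documents the discrepancy here (a test verifies the 97.7 % one-sided
figure empirically).

Degenerate inputs are contracts, not silent defaults: Shapiro–Wilk on
n < 3 or a zero-variance sample raises; missing repeats raise under the
default `strict` policy (`mean` averages what is present); a zero-sd
paired difference yields a degenerate CI at the constant.

## Synthetic-cohort generator

The generator emulates the structure of a waveguide-probe volunteer
study: 44 subjects in the tabulated age/sex strata (8 children, 27
adults, 9 elderly), 7 thin-SC and 10 thick-SC sites, 3 repeats, on the
five per-band test frequencies of WR42 and WR28 by default. Thin sites
share one two-layer model curve plus a per-subject normal dB offset
(default sd 0.10 dB, consistent with the scale of the reported paired-CI
half-widths) and repeat noise (0.05 dB). Thick sites draw a per-subject
SC thickness from a lognormal core (median 227 µm, σ_log 0.08) and, for
a manual-labor subpopulation (fraction 0.25 of subjects over 20,
mirroring the cohort's 11 manual laborers), multiply it by a lognormal
factor (median 1.4, σ_log 0.10). The reflection curve is evaluated
through the forward model at the sampled thickness.

This decomposition was chosen once, from the study conditions: the
227/262/295 µm mean/68 %/95 % thickness ladder constrains the *total*
thick-SC spread, and the labor factor places affected subjects about
0.5 dB below the normal-quantile line at the lower WR28 frequencies —
the reported magnitude of the palm outliers. The consequences (thick
cohorts fail dB-normality at p < 0.01 in ~98 % of replicates at 32 GHz,
thin cohorts pass at all five WR42 frequencies in ~90 %, thin-minus-thick
≈ 0.8 dB at 25 GHz) are measured by the acceptance script, not assumed.

What the generator does **not** emulate: per-site anatomical differences
beyond the thin/thick dichotomy, within-subject site correlation
structure, frequency-dependent between-subject spread (the offset is flat
in frequency), instrument drift or calibration error, and any phase
information. Passing tests therefore demonstrate that the pipeline is
correct and calibrated under these idealized conditions — not that real
measured cohorts have exactly these spreads. An optional elderly offset
(≤ 0.2 dB) can be injected for power studies; it defaults to zero.

Reproducibility is mandatory: generation without a seed raises, and a
given config + seed is bit-identical.

## Problem sizes

Default problem sizes were chosen for desk-scale iteration: fit grids of
14–21 points per band, 5 test frequencies per probe for convergence
sweeps, 200 replicate cohorts for the normality rates, 1000 replicates
for type-I calibration. The full test suite runs in about two minutes,
the acceptance script in about one.

## Known limitations

- Single-pole dispersion only; no temperature dependence.
- The mode-matching model assumes an infinite flange, a perfectly planar
  sample in contact with it, and a lossy terminal half-space; finite
  flanges, probe–skin gaps, and pressure effects are not modeled.
- Modal convergence at the aperture is slow (~1/N, no edge-singularity
  basis functions); accuracy is managed by the self-convergence criterion
  rather than extrapolation.
- The fitters are local optimizers with multi-start, not global solvers;
  dB-magnitude-only objectives leave an eps_s/σ trade-off that only
  bandwidth and point density pin down.
- The statistics mirror a per-frequency reporting workflow; no
  mixed-effects modeling of repeats/sites and no continuous-age
  regression.
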