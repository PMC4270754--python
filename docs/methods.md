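# Methods

## Model and assumptions

The package implements the absorbed-dose-to-water determination for an HDR
¹⁹²Ir source by Fricke dosimetry as a deterministic chain of algebraic
conversions. The Fricke dosimeter is treated as linear in dose over its
5–400 Gy operating band (values outside warn but process), with no fading
term: daily re-reads of the solutions used to calibrate the defaults showed
no measurable decay, so none is modelled. All geometry (spherical PMMA
vessel, source centred, 1 cm reference distance) is absorbed into four
calibrated multiplicative correction factors carried as constants with
standard uncertainties; no particle transport is performed.

### Optical density

The dose-induced absorbance increase at 304 nm is the irradiated minus
control reading, referred to 25 °C by two multiplicative factors — one for
the solution temperature during irradiation (ferric yield dependence), one
for the reading temperature (molar absorptivity dependence):

    dOD = (OD_i − OD_c) / [(1 + c_irr (T_i − 25)) (1 + c_read (T_r − 25))]

`c_irr` and `c_read` are required configuration; the packaged defaults are
the literature values 0.0012 /°C and 0.0069 /°C. Replicates are corrected
individually and averaged; the Type A estimator is the n−1 sample standard
deviation of the mean, expressed as a percentage of the mean (zero spread
gives 0%, a single replicate gives no Type A value). A non-positive
corrected mean is flagged and carried through, never clamped, so a swapped
irradiated/control pair is visible downstream.

### Dose chain

With ε in L mol⁻¹ cm⁻¹, L in cm, ρ in g cm⁻³ (numerically kg L⁻¹) and G in
mol J⁻¹, the Fricke dose D_F = dOD/(ρ L ε G) is in Gy with no hidden
conversion constant; the packaged defaults (ε = 2174, ρ = 1.023,
G = 1.555×10⁻⁶) give 289.15 Gy per unit dOD per cm. The water dose is the
product D_F · f · p_wall · F_h · k_dd; with the default factors the net
multiplier is 0.998984 with a 0.61% relative quadrature uncertainty. The
ionometric reference is the point conversion S_k Λ Δt (cGy → Gy), with
Λ = 1.108 cGy h⁻¹ U⁻¹ configurable.

### Ferric yield from LET

Each primary species yield (H, OH, H₂O₂) is a quartic in ln(LET, keV/µm)
whose coefficients are stored in the constants file on their published
column scales (α₁–α₃ ×10⁻², α₄ ×10⁻³) and expanded at load time — the
expansion is itself under test to prevent silent scale bugs. The ferric
combination is the aerated-Fricke stoichiometry 3G_H + G_OH + 2G_H₂O₂.
This reproduces 15.124 and 15.144 molecules/100 eV at the packaged LET
values 1.28 and 1.237 keV/µm (first- and second-order energy→LET fits for
the ¹⁹²Ir mean energy), i.e. 1.567×10⁻⁶ / 1.570×10⁻⁶ mol J⁻¹ — within
0.8–1.0% of the energy-weighted constant, which is why the constant is the
default sensitivity. The parameterisation is trusted on
LET ∈ [0.2, 10] keV/µm; evaluation outside warns rather than fails, since
extrapolation is occasionally legitimate and always the user's decision.
The LET anchors and the literature G(E) curve behind the energy-weighted
average are not shipped as data — the fitted endpoints (1.28, 1.237 keV/µm
and 1.555×10⁻⁶ mol J⁻¹) are packaged constants, user-overridable; users
with their own anchors use `fit_let_curve`/`interpolate_let` and
`weighted_g_value` (nearest-bin energy matching, default tolerance half a
50 keV grid step).

### Uncertainty budget

The budget is declarative: labelled sources with Type A and/or Type B
relative (%) components, unit sensitivity coefficients, no correlation
terms. Combination is plain quadrature over every component (the packaged
16-row default combines to 1.4237%); `inject_type_a` substitutes a measured
replicate repeatability into the dose-determination row, which the pipeline
does automatically per run. Two conventions coexist deliberately:
`expand(cu, k)` is exact (k × combined, full precision), while
`report(ndigits=2, k=2)` follows the typeset-table convention of rounding
the combined value half-up to two decimals first and scaling that — giving
the conventional pair (1.42, 2.84); the exact k=2 value is 2.847, which
would round to 2.85.

## Synthetic data generator

`simulate_run` inverts the chain: true water dose → Fricke dose (divide out
the factor product) → noiseless dOD per cm, then re-applies the temperature
factors at sampled temperatures and emits per-cuvette readings. Noise
enters at the reading level so downstream Type A statistics are exercised
honestly: a shared per-run control baseline (batch variation 0.002 AU
around 0.050 AU) that cancels in the subtraction except through the
per-reading repeatability (0.0003 AU, ≈0.45% of the 20 Gy signal — chosen
to match the ~0.5% dose-determination repeatability a real campaign
budgets), cuvette paths sampled at 1.0 ± 0.0005 cm, and temperatures
25 ± 0.2 °C. The irradiation time is set so the ionometric pairing
reproduces the true dose exactly, making the zero-noise Fricke/ionometric
ratio an identity check.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: thermometer error (recorded temperatures are exact,
so temperature drift exercises the correction code but cancels in
recovery), impurity scavenging and the non-linearity it causes, oxygen
depletion at high dose, vessel-wall chemistry, positioning errors, and any
systematic error in ε, G or the correction factors themselves. Recovery
tests therefore validate the pipeline's algebra and statistics, not the
physical accuracy of the constants.

Randomness uses one `numpy` `SeedSequence` per campaign with per-run
substreams derived from the run index; equal seeds give byte-identical
output files.

## Numerical choices

- Correction denominators ≤ 0 (unphysical temperature/coefficient
  combinations) raise; non-positive doses and dOD warn and flag instead.
- Budget reporting rounds half-up (`decimal`), not banker's rounding.
- Polynomial fits use `numpy.polynomial.polyfit`; with degree+1 distinct
  anchors the result interpolates exactly (asserted to ~1e-9).
- Test problem sizes: the noisy-recovery check uses 500 runs at 20 Gy and a
  4-dose × 10-run grid for the linearity fit, sizes at which the whole
  suite runs in a few seconds while the standard-error bands are already
  sub-0.1%.
- QC thresholds default to the spectrophotometer's 0.010 AU photometric
  accuracy; the blank check is strict (a value equal to the threshold
  fails), and the control-drift check runs only when a reference absorbance
  is supplied, because a control's absolute absorbance is dominated by the
  acid matrix.

## Known limitations

- Single-wavelength (304 nm) processing only; no scan data.
- The TG-43 side is the point conversion only — no radial dose function,
  anisotropy, or 2D formalism.
- Uncertainty combination is tabulated quadrature, not derivative-based GUM
  propagation through the chain; correlated components are not modelled.
- The energy-weighted G constant and LET endpoints are shipped values, not
  re-derived from their source curves.
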