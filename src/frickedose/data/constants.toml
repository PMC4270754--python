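# Packaged defaults for the Fricke -> absorbed-dose-to-water chain (HDR Ir-192).
# Every value here is user-overridable by passing an alternative file to
# frickedose.config.load_constants().

[gvalue]
# Energy-weighted radiation chemical yield of ferric ions for the Ir-192
# photon spectrum, in mol/J (standard uncertainty alongside).
value = 1.555e-6
uncertainty = 1.7e-8

[let]
# Interpolated LET of the Ir-192 mean photon energy, keV/um:
# first-order and second-order fits of literature energy-LET anchors.
linear_fit = 1.28
quadratic_fit = 1.237

[fricke]
epsilon = 2174.0  # molar linear absorption coefficient of Fe3+ at 304 nm, L/(mol.cm)
rho = 1.023       # Fricke solution density at 25 C, g/cm^3 (numerically kg/L)

[temperature]
# Two-factor multiplicative correction referencing 25 C: one factor for the
# solution temperature during irradiation, one during the reading.
coeff_irradiation = 0.0012  # per degC
coeff_reading = 0.0069      # per degC
reference_c = 25.0

[correction_factors]
# value, standard uncertainty (dimensionless)
f = [1.004, 0.003]      # Fricke-solution -> water dose conversion
p_wall = [0.999, 0.004] # PMMA vessel wall correction
f_h = [0.996, 0.003]    # volume-averaging (homogeneity) correction
k_dd = [1.000, 0.002]   # dose-profile non-uniformity correction

[tg43]
lambda_cgy_per_h_per_u = 1.108  # dose rate constant, cGy/(h.U), microSelectron HDR
lambda_rel_u_percent = 0.13

[qc]
blank_threshold_au = 0.01  # photometric accuracy of the spectrophotometer

# Quartic ln(LET) coefficients of the primary-species yields in aerated
# 0.4 M H2SO4, molecules per 100 eV.  `alpha` holds the values on their
# printed column scales; `scale` expands them (alpha_i * scale_i) at load.
[[yield_coefficients]]
species = "H"
alpha = [3.601, -13.53, -5.974, -1.929, -4.979]
scale = [1.0, 1e-2, 1e-2, 1e-2, 1e-3]

[[yield_coefficients]]
species = "OH"
alpha = [2.766, -18.80, -8.239, -2.127, -4.637]
scale = [1.0, 1e-2, 1e-2, 1e-2, 1e-3]

[[yield_coefficients]]
species = "H2O2"
alpha = [0.8438, 5.682, 2.169, 0.6284, 1.988]
scale = [1.0, 1e-2, 1e-2, 1e-2, 1e-3]
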