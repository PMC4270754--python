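# Default uncertainty budget for the Fricke determination of absorbed dose to
# water at a 20 Gy nominal dose.  All components are relative standard
# uncertainties (%) of D_w with unit sensitivity coefficients; type_a and
# type_b contribute independently in quadrature.

coverage_k = 1.0

[[entry]]
label = "Dummy/real source position"
group = "Irradiation Procedure"
type_b = 0.1

[[entry]]
label = "Transit time"
group = "Irradiation Procedure"
type_b = 0.016

[[entry]]
label = "Molar extinction coefficient"
group = "Solution Specification"
type_b = 0.35
reference = "literature"

[[entry]]
label = "Density"
group = "Solution Specification"
type_a = 0.100
type_b = 0.100
reference = "manufacture"

[[entry]]
label = "Source-solution distance"
group = "Solution Specification"
type_a = 0.01
type_b = 0.02
reference = "manufacture"

[[entry]]
label = "Dose determination"
group = "Reading Process"
type_a = 0.48
reference = "manufacture"

[[entry]]
label = "Cuvette-light path"
group = "Reading Process"
type_a = 0.05
type_b = 0.06
reference = "manufacture"

[[entry]]
label = "Instrument stability"
group = "Reading Process"
type_b = 0.10

[[entry]]
label = "Instrument repeatability"
group = "Reading Process"
type_b = 0.10

[[entry]]
label = "Wavelength bandwidth"
group = "Reading Process"
type_b = 0.01
reference = "literature"

[[entry]]
label = "Solution temperature"
group = "Reading Process"
type_a = 0.010
type_b = 0.15
reference = "manufacture"

[[entry]]
label = "G(Fe3+) value"
group = "Correction Factors"
type_b = 1.12
reference = "literature"

[[entry]]
label = "p_wall"
group = "Correction Factors"
type_a = 0.3
type_b = 0.2
reference = "literature"

[[entry]]
label = "Volume averaging"
group = "Correction Factors"
type_a = 0.2
type_b = 0.2
reference = "literature"

[[entry]]
label = "k_dd"
group = "Correction Factors"
type_a = 0.1
type_b = 0.2
reference = "literature"

[[entry]]
label = "Dose conversion factor for Fricke to water f"
group = "Correction Factors"
type_a = 0.2
type_b = 0.2
reference = "literature"
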