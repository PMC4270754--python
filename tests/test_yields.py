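"""Ferric-yield model: quartic ln(LET) polynomials, unit conversion,
energy->LET interpolation and spectrum weighting."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from frickedose.yields import (
    LET_SUPPORTED_RANGE,
    MOL_PER_JOULE_PER_MOLEC_100EV,
    DomainError,
    GValue,
    LetEnergyAnchor,
    LetValue,
    RadiolysisCoefficients,
    SpectrumWeight,
    ferric_yield,
    fit_let_curve,
    from_mol_per_joule,
    interpolate_let,
    primary_yield,
    to_mol_per_joule,
    weighted_g_value,
)


class TestCoefficientLoading:
    def test_scale_expansion_matches_published_columns(self, coeffs):
        # alpha1..alpha3 are published x1e-2, alpha4 x1e-3.
        assert coeffs["H"].alpha == pytest.approx(
            (3.601, -0.1353, -0.05974, -0.01929, -0.004979)
        )
        assert coeffs["OH"].alpha == pytest.approx(
            (2.766, -0.1880, -0.08239, -0.02127, -0.004637)
        )
        assert coeffs["H2O2"].alpha == pytest.approx(
            (0.8438, 0.05682, 0.02169, 0.006284, 0.001988)
        )

    def test_exactly_five_coefficients_required(self):
        with pytest.raises(ValueError):
            RadiolysisCoefficients("H", (1.0, 2.0, 3.0))

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            RadiolysisCoefficients("He", (1.0,) * 5)


class TestPrimaryYield:
    def test_unit_let_reduces_to_constant_term(self, coeffs):
        # ln(1) = 0 leaves only alpha0 for every species.
        for sp, expected in (("H", 3.601), ("OH", 2.766), ("H2O2", 0.8438)):
            assert primary_yield(sp, 1.0, coeffs[sp]) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "species, expected",
        [("H", 3.5636), ("OH", 2.7144)],  # hand-evaluated quartic at ln(1.28)
    )
    def test_hand_evaluated_quartic_at_iridium_let(self, species, expected, coeffs):
        assert primary_yield(species, 1.28, coeffs[species]) == pytest.approx(
            expected, abs=5e-4
        )

    def test_species_coefficient_mismatch_rejected(self, coeffs):
        with pytest.raises(ValueError, match="species"):
            primary_yield("H", 1.0, coeffs["OH"])

    def test_nonpositive_let_is_domain_error(self, coeffs):
        with pytest.raises(DomainError):
            primary_yield("H", 0.0, coeffs["H"])
        with pytest.raises(DomainError):
            primary_yield("H", -1.0, coeffs["H"])

    def test_positive_over_supported_range(self, coeffs):
        lets = np.linspace(*LET_SUPPORTED_RANGE, 50)
        for sp in coeffs:
            assert all(primary_yield(sp, let, coeffs[sp]) > 0 for let in lets)

    def test_outside_supported_range_warns(self, coeffs):
        with pytest.warns(UserWarning, match="supported range"):
            primary_yield("H", 20.0, coeffs["H"])


class TestFerricYield:
    def test_reproduces_published_iridium_values(self, coeffs):
        assert ferric_yield(1.28, coeffs) == pytest.approx(15.123, abs=1e-3)
        assert ferric_yield(1.237, coeffs) == pytest.approx(15.144, abs=1e-3)

    def test_unit_let_combination_of_constant_terms(self, coeffs):
        # 3*3.601 + 2.766 + 2*0.8438
        assert ferric_yield(1.0, coeffs) == pytest.approx(15.2566, abs=1e-12)

    def test_strictly_decreasing_over_low_let_photon_range(self, coeffs):
        g = [ferric_yield(let, coeffs) for let in np.linspace(0.5, 5.0, 200)]
        assert all(a > b for a, b in zip(g, g[1:]))

    def test_incomplete_species_set_rejected(self, coeffs):
        with pytest.raises(ValueError, match="cover"):
            ferric_yield(1.0, {s: coeffs[s] for s in ("H", "OH")})


class TestUnitConversion:
    @pytest.mark.parametrize(
        "g100ev, printed",
        [(15.123, 1.567e-6), (15.144, 1.569e-6)],
    )
    def test_published_side_by_side_values(self, g100ev, printed):
        # agreement to one unit in the last printed digit (the published
        # second value truncates 1.56956e-6)
        assert to_mol_per_joule(g100ev) == pytest.approx(printed, abs=1e-9)

    def test_zero_maps_to_zero(self):
        assert to_mol_per_joule(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            to_mol_per_joule(-1.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_round_trip_identity(self, g):
        assert from_mol_per_joule(to_mol_per_joule(g)) == pytest.approx(g, rel=1e-12)

    def test_conversion_constant_is_inverse_of_100_e_na(self):
        assert MOL_PER_JOULE_PER_MOLEC_100EV == pytest.approx(
            1.0 / (100 * 1.602176634e-19 * 6.02214076e23), rel=1e-12
        )


class TestLetCurve:
    def test_two_anchor_line_interpolates_exactly(self):
        anchors = [LetEnergyAnchor(1.0, LetValue(2.0)), LetEnergyAnchor(3.0, LetValue(4.0))]
        model = fit_let_curve(anchors, degree=1)
        assert interpolate_let(model, 2.0).value == pytest.approx(3.0, abs=1e-12)
        for a in anchors:
            assert model(a.energy) == pytest.approx(a.let.value, abs=1e-10)

    def test_collinear_anchors_give_degenerate_quadratic(self):
        anchors = [LetEnergyAnchor(e, LetValue(2 * e + 1)) for e in (1.0, 2.0, 3.0)]
        model = fit_let_curve(anchors, degree=2)
        assert model.coefficients[2] == pytest.approx(0.0, abs=1e-9)
        assert model(1.5) == pytest.approx(4.0, abs=1e-9)

    def test_three_noncollinear_anchors_interpolated_by_quadratic(self):
        # Oracle: solving the 3x3 Vandermonde system for (E, LET) anchors
        # (0.08, 3.2), (0.662, 1.7), (1.25, 0.9) gives
        # a0 = 3.428..., verified via exact interpolation below.
        pts = [(0.08, 3.2), (0.662, 1.7), (1.25, 0.9)]
        anchors = [LetEnergyAnchor(e, LetValue(l)) for e, l in pts]
        model = fit_let_curve(anchors, degree=2)
        for e, l in pts:
            assert interpolate_let(model, e).value == pytest.approx(l, abs=1e-9)

    def test_constant_model_returns_constant(self):
        anchors = [LetEnergyAnchor(1.0, LetValue(1.5)), LetEnergyAnchor(2.0, LetValue(1.5))]
        model = fit_let_curve(anchors, degree=1)
        assert interpolate_let(model, 1.7).value == pytest.approx(1.5, abs=1e-12)

    def test_too_few_or_duplicate_anchors_rejected(self):
        a = LetEnergyAnchor(1.0, LetValue(2.0))
        with pytest.raises(ValueError, match="anchors"):
            fit_let_curve([a], degree=1)
        with pytest.raises(ValueError, match="distinct"):
            fit_let_curve([a, LetEnergyAnchor(1.0, LetValue(3.0))], degree=1)

    def test_extrapolation_warns(self):
        anchors = [LetEnergyAnchor(1.0, LetValue(2.0)), LetEnergyAnchor(3.0, LetValue(4.0))]
        model = fit_let_curve(anchors, degree=1)
        with pytest.warns(UserWarning, match="extrapolating"):
            interpolate_let(model, 10.0)

    def test_nonpositive_prediction_is_domain_error(self):
        anchors = [LetEnergyAnchor(1.0, LetValue(2.0)), LetEnergyAnchor(2.0, LetValue(1.0))]
        model = fit_let_curve(anchors, degree=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(DomainError, match="non-positive"):
                interpolate_let(model, 5.0)


class TestWeightedGValue:
    def test_uniform_weights_give_arithmetic_mean(self):
        table = [(0.1, 1.5e-6), (0.2, 1.6e-6), (0.3, 1.7e-6)]
        weights = [SpectrumWeight(e, 1.0) for e, _ in table]
        assert weighted_g_value(table, weights).value == pytest.approx(1.6e-6, rel=1e-12)

    def test_point_mass_selects_single_energy(self):
        table = [(0.1, 1.5e-6), (0.2, 1.6e-6)]
        weights = [SpectrumWeight(0.1, 0.0), SpectrumWeight(0.2, 7.0)]
        assert weighted_g_value(table, weights).value == pytest.approx(1.6e-6, rel=1e-12)

    def test_hand_computed_weighted_mean(self):
        table = [(0.1, 1.5e-6), (0.2, 1.6e-6)]
        weights = [SpectrumWeight(0.1, 1.0), SpectrumWeight(0.2, 3.0)]
        out = weighted_g_value(table, weights)
        assert out.value == pytest.approx(1.575e-6, rel=1e-12)
        assert out.method == "energy_weighted"

    def test_nearest_bin_matching_within_half_grid_step(self):
        table = [(0.10, 1.5e-6), (0.15, 1.6e-6)]
        assert weighted_g_value(table, [SpectrumWeight(0.16, 1.0)]).value == pytest.approx(
            1.6e-6
        )
        with pytest.raises(ValueError, match="no table energy"):
            weighted_g_value(table, [SpectrumWeight(0.30, 1.0)])

    def test_degenerate_inputs_rejected(self):
        table = [(0.1, 1.5e-6)]
        with pytest.raises(ValueError):
            weighted_g_value([], [SpectrumWeight(0.1, 1.0)])
        with pytest.raises(ValueError):
            weighted_g_value(table, [])
        with pytest.raises(ValueError, match="zero"):
            weighted_g_value(table, [SpectrumWeight(0.1, 0.0)])


class TestGValueType:
    def test_validation(self):
        with pytest.raises(ValueError):
            GValue(-1e-6)
        with pytest.raises(ValueError):
            GValue(1e-6, uncertainty=-1.0)
        with pytest.raises(ValueError):
            GValue(1e-6, method="guess")
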