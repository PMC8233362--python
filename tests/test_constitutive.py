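"""Closed-form equation of state: examples, domain guards, invariants."""

from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import brushmech as bm
from brushmech.constitutive import stiffening_denominator

admissible_beta = st.floats(min_value=0.01, max_value=0.9)
admissible_E = st.floats(min_value=0.1, max_value=100.0)


def decimal_stress(lam: str, E: str, beta: str) -> float:
    """Arbitrary-precision evaluation of the printed stress formula,
    independent of the library's numpy routine."""
    getcontext().prec = 50
    lam_d, E_d, beta_d = Decimal(lam), Decimal(E), Decimal(beta)
    denom = 1 - beta_d * (lam_d**2 + 2 / lam_d) / 3
    return float(E_d / 9 * (lam_d**2 - 1 / lam_d) * (1 + 2 / denom**2))


class TestTrueStress:
    def test_undeformed_state_is_stress_free(self):
        for E, beta in [(1.0, 0.05), (15.3, 0.23), (100.0, 0.9)]:
            assert bm.true_stress(1.0, bm.MaterialParams(E, beta)) == 0.0

    def test_neo_hookean_limit_closed_form(self):
        # beta = 0 reduces to (E/3)(lambda^2 - 1/lambda)
        p = bm.MaterialParams(9.0, 0.0)
        assert bm.true_stress(2.0, p) == pytest.approx(10.5, abs=1e-12)
        lam = np.linspace(0.3, 5.0, 200)
        np.testing.assert_allclose(bm.true_stress(lam, p), 3.0 * (lam**2 - 1 / lam), rtol=1e-15)

    def test_against_high_precision_oracle(self):
        oracle = decimal_stress("1.5", "15.3", "0.23")
        assert oracle == pytest.approx(12.925598734703363, rel=1e-14)
        got = bm.true_stress(1.5, bm.MaterialParams(15.3, 0.23))
        assert got == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("lam", [0.0, -1.0, float("nan")])
    def test_nonpositive_lambda_rejected(self, lam):
        with pytest.raises(bm.DomainError):
            bm.true_stress(lam, bm.MaterialParams(5.0, 0.1))

    def test_beyond_finite_extensibility_rejected(self):
        p = bm.MaterialParams(5.0, 0.25)
        lam_sing = bm.lambda_singular(0.25)
        with pytest.raises(bm.DomainError):
            bm.true_stress(lam_sing * 1.01, p)
        # compressive singular side is guarded too
        with pytest.raises(bm.DomainError):
            bm.true_stress(1e-3, p)

    @given(beta=admissible_beta, E=admissible_E)
    @settings(max_examples=50, deadline=None)
    def test_sign_matches_deformation_direction(self, beta, E):
        p = bm.MaterialParams(E, beta)
        lam_sing = bm.lambda_singular(beta)
        lam_t = 1.0 + 0.5 * (min(lam_sing, 5.0) - 1.0)
        assert bm.true_stress(lam_t, p) > 0
        assert bm.true_stress(0.95, p) < 0

    @given(beta=admissible_beta, E=admissible_E)
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_up_to_singularity(self, beta, E):
        p = bm.MaterialParams(E, beta)
        lam_sing = bm.lambda_singular(beta)
        lam = np.linspace(1.0, 0.999 * lam_sing, 400)
        sigma = bm.true_stress(lam, p)
        assert np.all(np.diff(sigma) > 0)

    @given(beta=admissible_beta)
    @settings(max_examples=50, deadline=None)
    def test_divergence_near_singular_elongation(self, beta):
        p = bm.MaterialParams(1.0, beta)
        lam_sing = bm.lambda_singular(beta)
        near = bm.true_stress(0.999 * lam_sing, p)
        mid = bm.true_stress(0.5 * (1 + lam_sing), p)
        assert near > 100.0 * mid


class TestYoungModulus:
    @pytest.mark.parametrize(
        "E,beta,expected",
        [(15.3, 0.23, 22.3), (4.8, 0.06, 5.2)],
    )
    def test_reference_rows_one_decimal(self, E, beta, expected):
        assert round(bm.young_modulus(bm.MaterialParams(E, beta)), 1) == expected

    def test_reduces_to_structural_modulus_at_beta_zero(self):
        assert bm.young_modulus(bm.MaterialParams(5.0, 0.0)) == pytest.approx(5.0)

    @given(beta=admissible_beta, E=admissible_E)
    @settings(max_examples=50, deadline=None)
    def test_equals_initial_slope(self, beta, E):
        p = bm.MaterialParams(E, beta)
        h = 1e-6
        slope = (bm.true_stress(1 + h, p) - bm.true_stress(1 - h, p)) / (2 * h)
        assert slope == pytest.approx(bm.young_modulus(p), rel=1e-6)


class TestLambdaMax:
    @pytest.mark.parametrize(
        "beta,expected", [(0.25, 2.0), (0.08, 3.5), (0.06, 4.1)]
    )
    def test_reference_values_one_decimal(self, beta, expected):
        assert round(bm.lambda_max_theo(beta), 1) == expected

    @pytest.mark.parametrize("beta", [0.0, -0.1, 1.0, 1.5])
    def test_out_of_range_beta_rejected(self, beta):
        with pytest.raises(bm.DomainError):
            bm.lambda_max_theo(beta)

    def test_singular_elongation_bounds_theoretical_break(self):
        # verified numerically on a dense beta grid, not assumed
        for beta in np.linspace(0.01, 0.99, 197):
            assert bm.lambda_singular(beta) >= bm.lambda_max_theo(beta)

    def test_singularity_root_solves_cubic_condition(self):
        for beta in (0.05, 0.23, 0.6):
            lam = bm.lambda_singular(beta)
            assert stiffening_denominator(lam, beta) == pytest.approx(0.0, abs=1e-8)


class TestScalingLaw:
    def test_side_chain_ratio_on_printed_exponent(self):
        k = bm.ScalingConstants(prefactor_mode="calibrated", C=1000.0)
        r = bm.structural_modulus_predicted(0.1, 14, k) / bm.structural_modulus_predicted(0.1, 70, k)
        assert r == pytest.approx((71 / 15) ** 1.5, rel=1e-12)
        assert r == pytest.approx(10.30, abs=0.01)

    def test_proportional_through_origin_and_linear_in_beta(self):
        k = bm.ScalingConstants(prefactor_mode="calibrated", C=4500.0)
        assert bm.structural_modulus_predicted(0.0, 14, k) == 0.0
        one = bm.structural_modulus_predicted(0.1, 14, k)
        assert bm.structural_modulus_predicted(0.2, 14, k) == pytest.approx(2 * one, rel=1e-14)

    def test_analytic_mode_requires_monomer_volume(self):
        with pytest.raises(ValueError):
            bm.ScalingConstants(prefactor_mode="analytic", v=None)

    def test_calibrated_mode_requires_slope(self):
        with pytest.raises(ValueError):
            bm.ScalingConstants(prefactor_mode="calibrated", C=None)

    def test_analytic_mode_unit_conversion(self):
        # kT/v sets the modulus scale: with l = v^(1/3) the prefactor is
        # 3 kT / v exactly; at T ~ 293 K and v = 1 nm^3, kT/v ~ 4.05 kPa
        k = bm.ScalingConstants(prefactor_mode="analytic", l=1.0, v=1.0, temperature=293.15)
        e = bm.structural_modulus_predicted(0.5, 0, k)
        assert e == pytest.approx(3 * 1.380649e-23 * 293.15 * 1e24 * 0.5, rel=1e-12)


class TestStressConventions:
    def test_engineering_to_true_is_lambda_scaling(self):
        assert bm.engineering_to_true(1.0, 5.0) == 5.0
        assert bm.engineering_to_true(2.0, 3.0) == 6.0

    @given(lam=st.floats(min_value=0.1, max_value=10), s=st.floats(min_value=-50, max_value=50))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, lam, s):
        assert bm.true_to_engineering(lam, bm.engineering_to_true(lam, s)) == pytest.approx(s, rel=1e-15, abs=1e-12)


class TestMaterialParams:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            bm.MaterialParams(-1.0, 0.1)
        with pytest.raises(ValueError):
            bm.MaterialParams(1.0, 1.0)
        with pytest.raises(ValueError):
            bm.MaterialParams(1.0, -0.2)

    def test_derived_properties(self):
        p = bm.MaterialParams(4.2, 0.10)
        assert p.E0 == pytest.approx(bm.young_modulus(p))
        assert p.lambda_max == pytest.approx(0.10**-0.5)
        assert bm.MaterialParams(1.0, 0.0).lambda_max == float("inf")


class TestArchitecture:
    def test_valid_triple(self):
        a = bm.Architecture(n_x=200, n_sc=14, n_bb=889, chemistry="NCO:OH", ratio="1:4")
        assert a.n_g == 1

    def test_crosslink_spacing_cannot_exceed_backbone(self):
        with pytest.raises(ValueError):
            bm.Architecture(n_x=1000, n_sc=14, n_bb=889)

    def test_nonpositive_dp_rejected(self):
        with pytest.raises(ValueError):
            bm.Architecture(n_x=0, n_sc=14, n_bb=889)
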