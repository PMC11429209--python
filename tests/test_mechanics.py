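"""Closed-form mechanics: worked examples, unit conversions, scaling laws."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from monofil import (
    CLAMPED_PINNED,
    CLAMPED_PINNED_SLIDING,
    BoundaryCondition,
    Environment,
    MaterialProperties,
    MonofilamentGeometry,
    critical_buckling_force,
    effective_length,
    estimate_young_modulus,
    gramforce_to_newton,
    modulus_at_environment,
    modulus_at_humidity,
    modulus_at_temperature,
    newton_to_gramforce,
    second_moment_area,
    self_weight,
    tip_deflection,
)
from monofil.exceptions import (
    ConfigurationError,
    DomainError,
    EulerSlendernessWarning,
)

# strategies covering realistic monofilament scales with headroom
diameters_mm = st.floats(0.1, 2.0)
lengths_mm = st.floats(10.0, 100.0)
moduli_gpa = st.floats(0.5, 10.0)
densities = st.floats(900.0, 1500.0)


# ------------------------------------------------------------ domain types

class TestTypes:
    def test_geometry_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            MonofilamentGeometry(diameter=0.0, length=0.038)
        with pytest.raises(DomainError):
            MonofilamentGeometry(diameter=0.00061, length=-1.0)

    def test_from_mm_stores_si(self):
        g = MonofilamentGeometry.from_mm(0.61, 38.0)
        assert g.diameter == pytest.approx(0.00061)
        assert g.length == pytest.approx(0.038)
        assert g.diameter_mm == pytest.approx(0.61)
        assert g.length_mm == pytest.approx(38.0)

    def test_boundary_presets_pin_their_k(self):
        assert CLAMPED_PINNED.k_factor == 0.7
        assert CLAMPED_PINNED_SLIDING.k_factor == 2.0
        with pytest.raises(DomainError):
            BoundaryCondition("clamped_pinned", 0.8)
        with pytest.raises(DomainError):
            BoundaryCondition("free_free", 1.0)
        assert BoundaryCondition.custom(1.0).k_factor == 1.0

    def test_material_coefficient_needs_reference(self):
        with pytest.raises(ConfigurationError):
            MaterialProperties(young_modulus_ref=2e9, temp_coefficient=0.005)
        with pytest.raises(ConfigurationError):
            MaterialProperties(young_modulus_ref=2e9, humidity_coefficient=0.004)

    def test_environment_humidity_bounds(self):
        with pytest.raises(DomainError):
            Environment(temperature=20.0, humidity=101.0)
        Environment(temperature=20.0, humidity=0.0)


# --------------------------------------------------------- worked examples

class TestSecondMomentArea:
    @pytest.mark.parametrize(
        "d_mm, expected_m4",
        [(0.61, 6.797e-15), (0.46, 2.198e-15)],
    )
    def test_bench_device_sections(self, d_mm, expected_m4):
        g = MonofilamentGeometry.from_mm(d_mm, 38.0)
        assert second_moment_area(g) == pytest.approx(expected_m4, rel=1e-3)

    def test_fourth_power_scaling(self):
        g1 = MonofilamentGeometry.from_mm(0.4, 38.0)
        g2 = MonofilamentGeometry.from_mm(0.8, 38.0)
        assert second_moment_area(g2) / second_moment_area(g1) == pytest.approx(16.0)


class TestEffectiveLength:
    def test_clamped_pinned_38mm(self):
        g = MonofilamentGeometry.from_mm(0.61, 38.0)
        assert effective_length(g, CLAMPED_PINNED) == pytest.approx(0.02660)

    def test_identity_at_k1_and_sliding(self):
        g = MonofilamentGeometry.from_mm(0.5, 41.0)
        assert effective_length(g, BoundaryCondition.custom(1.0)) == pytest.approx(g.length)
        assert effective_length(g, CLAMPED_PINNED_SLIDING) == pytest.approx(0.082)


class TestCriticalForce:
    def test_ten_gf_worked_example(self):
        """Typical 10 gf device: 0.18961 N, i.e. 19.33 gf, at E = 2 GPa."""
        g = MonofilamentGeometry.from_mm(0.61, 38.0)
        fc = critical_buckling_force(g, 2e9, CLAMPED_PINNED)
        assert fc == pytest.approx(0.18961, abs=2e-5)
        assert newton_to_gramforce(fc) == pytest.approx(19.33, abs=0.01)

    def test_thin_long_device(self):
        g = MonofilamentGeometry.from_mm(0.46, 41.0)
        fc_gf = newton_to_gramforce(critical_buckling_force(g, 3.65e9, CLAMPED_PINNED))
        assert fc_gf == pytest.approx(9.80, abs=0.01)

    def test_nonpositive_modulus_rejected(self):
        g = MonofilamentGeometry.from_mm(0.61, 38.0)
        with pytest.raises(DomainError):
            critical_buckling_force(g, 0.0, CLAMPED_PINNED)

    def test_slenderness_warning_for_stubby_column(self):
        stubby = MonofilamentGeometry.from_mm(10.0, 40.0)  # Le/(d/4) = 11.2
        with pytest.warns(EulerSlendernessWarning):
            fc = critical_buckling_force(stubby, 2e9, CLAMPED_PINNED)
        assert fc > 0  # value still returned


class TestUnitConversions:
    @pytest.mark.parametrize(
        "newton, gf",
        [(0.18961, 19.33), (0.0, 0.0), (0.0980665, 10.0)],
    )
    def test_newton_to_gramforce(self, newton, gf):
        assert newton_to_gramforce(newton) == pytest.approx(gf, abs=5e-3)

    @given(st.floats(-1e3, 1e3))
    def test_round_trip_identity(self, force):
        assert gramforce_to_newton(newton_to_gramforce(force)) == pytest.approx(
            force, abs=1e-12
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(DomainError):
            newton_to_gramforce(float("nan"))


class TestEstimateModulus:
    @pytest.mark.parametrize(
        "d_mm, l_mm, fc_gf, e_gpa",
        [(0.46, 41.0, 9.80, 3.65), (0.71, 38.0, 29.81, 1.68)],
    )
    def test_bench_device_estimates(self, d_mm, l_mm, fc_gf, e_gpa):
        g = MonofilamentGeometry.from_mm(d_mm, l_mm)
        e = estimate_young_modulus(g, gramforce_to_newton(fc_gf), CLAMPED_PINNED)
        assert e / 1e9 == pytest.approx(e_gpa, abs=0.005)

    @given(diameters_mm, lengths_mm, moduli_gpa)
    def test_exact_inverse_of_forward_formula(self, d_mm, l_mm, e_gpa):
        g = MonofilamentGeometry.from_mm(d_mm, l_mm)
        fc = critical_buckling_force(g, e_gpa * 1e9, CLAMPED_PINNED)
        assert estimate_young_modulus(g, fc, CLAMPED_PINNED) == pytest.approx(
            e_gpa * 1e9, rel=1e-12
        )

    def test_nonpositive_force_rejected(self):
        g = MonofilamentGeometry.from_mm(0.61, 38.0)
        with pytest.raises(DomainError):
            estimate_young_modulus(g, -0.1, CLAMPED_PINNED)


# -------------------------------------------------- environmental corrections

class TestEnvironmentalCorrections:
    @pytest.fixture
    def nylon(self):
        return MaterialProperties(
            young_modulus_ref=2e9,
            temp_coefficient=0.005,
            ref_temperature=20.0,
            humidity_coefficient=0.004,
            ref_humidity=50.0,
        )

    def test_identity_at_reference_conditions(self, nylon):
        assert modulus_at_temperature(nylon, 20.0) == pytest.approx(2e9)
        assert modulus_at_humidity(nylon, 50.0) == pytest.approx(2e9)
        env = Environment(temperature=20.0, humidity=50.0)
        assert modulus_at_environment(nylon, env) == pytest.approx(2e9)

    def test_linear_drop_with_temperature(self, nylon):
        # E0 (1 - 0.005 * 10) = 1.9 GPa
        assert modulus_at_temperature(nylon, 30.0) == pytest.approx(1.9e9)

    def test_linear_drop_with_humidity(self):
        mat = MaterialProperties(
            young_modulus_ref=3e9, humidity_coefficient=0.004, ref_humidity=50.0
        )
        assert modulus_at_humidity(mat, 75.0) == pytest.approx(2.7e9)

    def test_zero_coefficient_is_inert(self):
        mat = MaterialProperties(
            young_modulus_ref=2e9, temp_coefficient=0.0, ref_temperature=20.0
        )
        for t in (-10.0, 20.0, 60.0):
            assert modulus_at_temperature(mat, t) == pytest.approx(2e9)

    def test_multiplicative_composition(self, nylon):
        env = Environment(temperature=30.0, humidity=75.0)
        # 2 GPa * (1 - 0.05) * (1 - 0.1) = 1.71 GPa
        assert modulus_at_environment(nylon, env) == pytest.approx(1.71e9)

    def test_composition_reduces_to_single_correction(self):
        mat = MaterialProperties(
            young_modulus_ref=2e9,
            temp_coefficient=0.005,
            ref_temperature=20.0,
            humidity_coefficient=0.0,
            ref_humidity=50.0,
        )
        env = Environment(temperature=35.0, humidity=90.0)
        assert modulus_at_environment(mat, env) == pytest.approx(
            modulus_at_temperature(mat, 35.0)
        )

    def test_missing_coefficients_fail_loudly(self):
        bare = MaterialProperties(young_modulus_ref=2e9)
        with pytest.raises(ConfigurationError):
            modulus_at_temperature(bare, 30.0)
        with pytest.raises(ConfigurationError):
            modulus_at_humidity(bare, 70.0)
        with pytest.raises(ConfigurationError):
            modulus_at_environment(bare, Environment(30.0, 70.0))

    def test_correction_outside_validity_raises(self):
        mat = MaterialProperties(
            young_modulus_ref=2e9, temp_coefficient=0.01, ref_temperature=20.0
        )
        with pytest.raises(DomainError):
            modulus_at_temperature(mat, 150.0)  # factor would go negative

    @given(st.floats(0.0, 0.008), st.floats(0.0, 40.0))
    def test_decreasing_in_temperature_excess(self, alpha, dt):
        mat = MaterialProperties(
            young_modulus_ref=2e9, temp_coefficient=alpha, ref_temperature=20.0
        )
        assert modulus_at_temperature(mat, 20.0 + dt) <= 2e9 + 1e-6


# ------------------------------------------------------ self-weight deflection

class TestSelfWeightDeflection:
    def test_weight_of_thin_long_device(self):
        g = MonofilamentGeometry.from_mm(0.46, 41.0)
        assert self_weight(g, 1140.0) == pytest.approx(7.62e-5, rel=1e-3)

    def test_zero_density_weightless(self):
        g = MonofilamentGeometry.from_mm(0.46, 41.0)
        assert self_weight(g, 0.0) == 0.0

    def test_weight_linear_in_length(self):
        g1 = MonofilamentGeometry.from_mm(0.46, 20.0)
        g2 = MonofilamentGeometry.from_mm(0.46, 40.0)
        assert self_weight(g2, 1140.0) / self_weight(g1, 1140.0) == pytest.approx(2.0)

    def test_thin_long_device_deflection(self):
        """Longest/thinnest bench device droops 81.81 um = 17.8% of d."""
        g = MonofilamentGeometry.from_mm(0.46, 41.0)
        res = tip_deflection(g, 3.65e9, 1140.0)
        assert res.deflection_um == pytest.approx(81.81, abs=0.01)
        assert res.percent_of_diameter == pytest.approx(17.8, abs=0.05)
        assert res.small_deflection_valid

    def test_short_thick_device_deflection(self):
        g = MonofilamentGeometry.from_mm(0.71, 38.0)
        res = tip_deflection(g, 1.68e9, 1140.0)
        assert res.deflection_um == pytest.approx(55.0, abs=0.5)
        assert res.percent_of_diameter == pytest.approx(7.8, abs=0.1)

    @given(diameters_mm, lengths_mm, moduli_gpa, densities, st.floats(1.1, 2.0))
    def test_scaling_laws(self, d_mm, l_mm, e_gpa, rho, s):
        g = MonofilamentGeometry.from_mm(d_mm, l_mm)
        base = tip_deflection(g, e_gpa * 1e9, rho).deflection
        longer = MonofilamentGeometry.from_mm(d_mm, l_mm * s)
        thicker = MonofilamentGeometry.from_mm(d_mm * s, l_mm)
        assert tip_deflection(longer, e_gpa * 1e9, rho).deflection == pytest.approx(
            base * s ** 4, rel=1e-9
        )
        assert tip_deflection(thicker, e_gpa * 1e9, rho).deflection == pytest.approx(
            base / s ** 2, rel=1e-9
        )
        assert tip_deflection(g, e_gpa * 1e9, rho * s).deflection == pytest.approx(
            base * s, rel=1e-9
        )
        assert tip_deflection(g, e_gpa * 1e9 * s, rho).deflection == pytest.approx(
            base / s, rel=1e-9
        )


# ------------------------------------------------------------ scaling laws

class TestBucklingScalingLaws:
    @given(diameters_mm, lengths_mm, moduli_gpa, st.floats(1.1, 3.0))
    def test_proportionalities(self, d_mm, l_mm, e_gpa, s):
        g = MonofilamentGeometry.from_mm(d_mm, l_mm)
        e = e_gpa * 1e9
        base = critical_buckling_force(g, e, CLAMPED_PINNED)
        assert critical_buckling_force(g, e * s, CLAMPED_PINNED) == pytest.approx(
            base * s, rel=1e-9
        )
        thicker = MonofilamentGeometry.from_mm(d_mm * s, l_mm)
        assert critical_buckling_force(thicker, e, CLAMPED_PINNED) == pytest.approx(
            base * s ** 4, rel=1e-9
        )
        longer = MonofilamentGeometry.from_mm(d_mm, l_mm * s)
        assert critical_buckling_force(longer, e, CLAMPED_PINNED) == pytest.approx(
            base / s ** 2, rel=1e-9
        )

    @given(diameters_mm, lengths_mm, moduli_gpa)
    def test_sliding_over_pinned_ratio_is_0_1225(self, d_mm, l_mm, e_gpa):
        g = MonofilamentGeometry.from_mm(d_mm, l_mm)
        e = e_gpa * 1e9
        ratio = critical_buckling_force(g, e, CLAMPED_PINNED_SLIDING) / (
            critical_buckling_force(g, e, CLAMPED_PINNED)
        )
        assert ratio == pytest.approx((0.7 / 2.0) ** 2, rel=1e-12)
        assert ratio == pytest.approx(0.1225, rel=1e-12)
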