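"""Cutting-force model: lower bound, sharpness number, regimes, propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cutmech.core_model import (
    BladeGeometry,
    CutModelConfig,
    MaterialProperties,
    SheetSpec,
    classify_sharpness,
    critical_radius,
    lower_bound_force,
    material_from_dict,
    material_length_scale,
    omega,
    predict_cutting_force,
)
from cutmech.errors import InvalidInputError

positive = st.floats(min_value=1e-3, max_value=1e3)


def mat(Gc, sigma_c, E=4.1e6, **kw):
    return MaterialProperties(name="m", Gc=Gc, sigma_c=sigma_c, E=E, **kw)


class TestLowerBound:
    def test_thin_tough_film_minimum(self, pdms_10):
        # Gc = 197 J/m^2 on a 200 um sheet: the ~40 mN physical minimum.
        F, _ = lower_bound_force(pdms_10, SheetSpec(200e-6))
        assert F * 1e3 == pytest.approx(39.4)

    def test_propagated_uncertainty_hand_oracle(self):
        # sqrt((210e-6*9)^2 + (98*10e-6)^2) = 2.129 mN, by hand.
        m = mat(98.0, 6.0e6, Gc_sd=9.0)
        F, sd = lower_bound_force(m, SheetSpec(210e-6, thickness_sd=10e-6))
        assert F * 1e3 == pytest.approx(20.58)
        assert sd * 1e3 == pytest.approx(2.1290, rel=1e-4)

    def test_zero_toughness_rejected_and_limit(self):
        with pytest.raises(InvalidInputError):
            mat(0.0, 6.0e6)
        F, _ = lower_bound_force(mat(1e-9, 6.0e6), SheetSpec(200e-6))
        assert F == pytest.approx(0.0, abs=1e-10)

    def test_propagated_sd_matches_monte_carlo(self, rng, pdms_4, pdms_10):
        """First-order sd agrees with a 1e5-draw Gaussian simulation within 5%."""
        for m in (pdms_4, pdms_10):
            sheet = SheetSpec(400e-6, thickness_sd=15e-6)
            _, sd = lower_bound_force(m, sheet)
            draws = rng.normal(m.Gc, m.Gc_sd, 100_000) * rng.normal(
                sheet.thickness, sheet.thickness_sd, 100_000
            )
            assert sd == pytest.approx(draws.std(), rel=0.05)


class TestOmega:
    @pytest.mark.parametrize(
        "sigma_MPa, R_nm, Gc, expected",
        [
            (6.0, 162, 98.0, 0.0198),  # pristine on the brittle sheet
            (5.5, 162, 197.0, 0.00905),  # pristine on the tough sheet
        ],
    )
    def test_pristine_blades_are_ideally_sharp(
        self, model_config, sigma_MPa, R_nm, Gc, expected
    ):
        om = omega(model_config, mat(Gc, sigma_MPa * 1e6), BladeGeometry(R_nm * 1e-9))
        assert om == pytest.approx(expected, rel=5e-3)
        assert classify_sharpness(om, model_config) == "ideally_sharp"

    def test_zero_radius_blade(self, model_config, pdms_4):
        assert omega(model_config, pdms_4, BladeGeometry(0.0)) == 0.0

    @given(
        sigma=positive, R=positive, Gc=positive,
        f=st.floats(min_value=1e-2, max_value=1e2),
        l=st.floats(min_value=1e-2, max_value=1e2),
    )
    @settings(deadline=None, derandomize=True)
    def test_invariant_under_unit_rescaling(self, sigma, R, Gc, f, l):
        """Omega is dimensionless: rescaling force (f) and length (l) units
        maps sigma_c -> sigma_c*f/l^2, R -> R*l, Gc -> Gc*f/l."""
        cfg = CutModelConfig()
        base = omega(cfg, mat(Gc, sigma), BladeGeometry(R))
        scaled = omega(
            cfg, mat(Gc * f / l, sigma * f / l**2), BladeGeometry(R * l)
        )
        assert scaled == pytest.approx(base, rel=1e-9)


class TestPrediction:
    def test_most_worn_blade_on_brittle_sheet(self, model_config, pdms_4):
        # The ~100 mN prediction: worn blade (R = 11712 nm) on a 400 um sheet.
        p = predict_cutting_force(
            model_config, pdms_4, BladeGeometry(11712e-9), SheetSpec(400e-6)
        )
        assert p.omega == pytest.approx(1.434, rel=1e-3)
        assert p.F_pred * 1e3 == pytest.approx(95.4, rel=1e-2)
        assert p.regime == "geometry_dominated"

    def test_worn_blade_on_tough_sheet_hand_oracle(self, model_config, pdms_10):
        p = predict_cutting_force(
            model_config, pdms_10, BladeGeometry(11712e-9), SheetSpec(200e-6)
        )
        assert p.omega == pytest.approx(0.654, rel=1e-3)
        assert p.F_pred * 1e3 == pytest.approx(65.2, rel=1e-3)

    def test_sharp_limit_reduces_to_lower_bound(self, model_config, pdms_4):
        sheet = SheetSpec(300e-6, thickness_sd=5e-6)
        p = predict_cutting_force(model_config, pdms_4, BladeGeometry(0.0), sheet)
        F_min, F_min_sd = lower_bound_force(pdms_4, sheet)
        assert p.F_pred == F_min
        assert (p.F_min, p.F_min_sd) == (F_min, F_min_sd)
        assert p.regime == "ideally_sharp"

    def test_normalized_force_consistency_and_monotonicity(self, model_config):
        """F_pred strictly increases in Gc, t, R and sigma_c; and
        normalized_force - 1 == omega at machine precision."""
        base = dict(Gc=98.0, sigma=6.0e6, t=200e-6, R=500e-9)

        def F(Gc, sigma, t, R):
            p = predict_cutting_force(
                model_config, mat(Gc, sigma), BladeGeometry(R), SheetSpec(t)
            )
            assert p.normalized_force - 1.0 == pytest.approx(p.omega, rel=1e-12)
            return p.F_pred

        f0 = F(base["Gc"], base["sigma"], base["t"], base["R"])
        assert F(base["Gc"] * 1.1, base["sigma"], base["t"], base["R"]) > f0
        assert F(base["Gc"], base["sigma"] * 1.1, base["t"], base["R"]) > f0
        assert F(base["Gc"], base["sigma"], base["t"] * 1.1, base["R"]) > f0
        assert F(base["Gc"], base["sigma"], base["t"], base["R"] * 1.1) > f0


class TestRegimes:
    @pytest.mark.parametrize(
        "om, regime",
        [
            (0.02, "ideally_sharp"),
            (0.05, "transitional"),  # threshold is exclusive
            (0.7, "transitional"),
            (1.0, "geometry_dominated"),
            (1.4, "geometry_dominated"),
        ],
    )
    def test_classification(self, model_config, om, regime):
        assert classify_sharpness(om, model_config) == regime

    def test_negative_omega_rejected(self, model_config):
        with pytest.raises(InvalidInputError):
            classify_sharpness(-0.1, model_config)


class TestCriticalRadius:
    def test_inverted_omega_hand_oracle(self, model_config, pdms_4):
        assert critical_radius(model_config, pdms_4, 0.05) * 1e9 == pytest.approx(
            408.3, rel=1e-3
        )

    def test_median_tropical_leaf(self, model_config):
        # sigma_c = 3 N/mm^2, Gc = 0.4 N/mm: 5% elevation at R = 3.33 um.
        leaf = mat(400.0, 3.0e6)
        assert critical_radius(model_config, leaf, 0.05) * 1e6 == pytest.approx(
            3.333, rel=1e-3
        )

    def test_zero_tolerance(self, model_config, pdms_4):
        assert critical_radius(model_config, pdms_4, 0.0) == 0.0


class TestMaterialLengthScale:
    def test_characterized_sheets(self, pdms_4, pdms_10):
        L4, sd4 = material_length_scale(pdms_4)
        L10, sd10 = material_length_scale(pdms_10)
        assert L4 * 1e6 == pytest.approx(16.3, abs=0.05)
        assert sd4 * 1e6 == pytest.approx(5.6, abs=0.1)
        assert L10 * 1e6 == pytest.approx(35.8, abs=0.05)
        assert sd10 * 1e6 == pytest.approx(13.8, abs=0.1)

    def test_infinite_strength_limit(self):
        assert material_length_scale(mat(98.0, 1e30))[0] == pytest.approx(0.0, abs=1e-25)


def test_material_from_unit_tagged_dict():
    m = material_from_dict(
        {"name": "x", "Gc_J_per_m2": 98, "sigma_c_MPa": 6.0, "E_MPa": 4.1,
         "Gc_sd_J_per_m2": 9}
    )
    assert (m.Gc, m.sigma_c, m.Gc_sd) == (98.0, 6.0e6, 9.0)
    assert m.E == pytest.approx(4.1e6, rel=1e-12)


def test_type_invariants_rejected():
    with pytest.raises(InvalidInputError):
        BladeGeometry(-1e-9)
    with pytest.raises(InvalidInputError):
        BladeGeometry(1e-9, wedge_angle=180.0)
    with pytest.raises(InvalidInputError):
        SheetSpec(0.0)
    with pytest.raises(InvalidInputError):
        CutModelConfig(C=0.0)
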