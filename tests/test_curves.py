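"""Growth-curve evaluation, asymptotes, parameter draws and the registry."""

import math

import numpy as np
import pandas as pd
import pytest

from moorburn import (GrowthCurve, builtin_sites, curve_asymptote,
                      draw_curve_sample, evaluate_curve, load_registry,
                      save_registry)
from moorburn.curves import registry_from_frame, registry_to_frame

from conftest import DATA_DIR


class TestEvaluate:
    @pytest.mark.parametrize("site,fraction,age,expected,tol", [
        # direct hand evaluation of a * exp(-b * c**age)
        ("Kerloch", "calluna", 8, 7.2119, 1e-3),
        # asymptote reached: Moor House canopy saturates near 8 t/ha
        ("Moor House", "calluna", 50, 7.94, 1e-2),
        # exp(3.86 + 1.1 ln 51) g/m2 converted to t/ha
        ("Howden", "litter", 50, 35.868, 1e-2),
        ("Kerloch", "calluna", 20, 17.886, 1e-2),
    ])
    def test_known_values(self, registry, site, fraction, age, expected, tol):
        curve = getattr(registry[site], f"{fraction}_curve")
        assert evaluate_curve(curve, age) == pytest.approx(expected, abs=tol)

    def test_zero_shape_is_flat_at_asymptote(self):
        curve = GrowthCurve("gompertz", a=5.0, b=0.0, c=0.5, unit_scale=2.0)
        for age in (0, 3, 50, 120):
            assert evaluate_curve(curve, age) == pytest.approx(10.0)

    def test_ages_above_valid_range_are_capped(self, howden):
        c = howden.calluna_curve
        assert evaluate_curve(c, 120) == evaluate_curve(c, 50)

    def test_negative_age_rejected(self, kerloch):
        with pytest.raises(ValueError):
            evaluate_curve(kerloch.calluna_curve, -1)

    def test_vectorised_evaluation_matches_scalar(self, kerloch):
        ages = np.arange(0, 51)
        vec = evaluate_curve(kerloch.litter_curve, ages)
        assert vec == pytest.approx(
            [evaluate_curve(kerloch.litter_curve, a) for a in ages])

    def test_gompertz_monotone_and_bounded(self, registry):
        ages = np.arange(0, 201)
        for site in registry.values():
            for curve in (site.calluna_curve, site.litter_curve):
                if curve.form != "gompertz":
                    continue
                y = evaluate_curve(curve, ages)
                assert np.all(np.diff(y) >= -1e-12)
                assert np.all(y <= curve.unit_scale * curve.a + 1e-12)
                # the uncapped form is numerically at the asymptote by age 200
                from dataclasses import replace
                free = replace(curve, valid_age_range=(2.0, 1000.0))
                assert abs(evaluate_curve(free, 200)
                           - curve.unit_scale * curve.a) < 1e-3


class TestAsymptote:
    @pytest.mark.parametrize("site,fraction,expected", [
        ("Moor House", "litter", 8.90),
        ("Dorset", "litter", 28.38),
        ("Kerloch", "calluna", 22.96),
    ])
    def test_gompertz_asymptote_is_scaled_a(self, registry, site, fraction,
                                            expected):
        curve = getattr(registry[site], f"{fraction}_curve")
        assert curve_asymptote(curve) == pytest.approx(expected)

    def test_power_law_unbounded(self, howden):
        assert curve_asymptote(howden.calluna_curve) is None


class TestParameterDraws:
    def test_zero_se_draw_equals_point_curve(self, moor_house):
        from dataclasses import replace
        curve = replace(moor_house.calluna_curve, se_a=0.0, se_b=0.0, se_c=0.0)
        rng = np.random.default_rng(0)
        ages = np.arange(0, 51)
        for age in ages:
            assert draw_curve_sample(curve, age, np.random.default_rng(1)) \
                == evaluate_curve(curve, age)

    def test_draw_mean_near_plugin_value(self, kerloch):
        rng = np.random.default_rng(42)
        draws = [draw_curve_sample(kerloch.calluna_curve, 20, rng)
                 for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(17.886, rel=0.02)

    def test_same_seed_reproduces_draw(self, dorset):
        d1 = draw_curve_sample(dorset.litter_curve, 30, np.random.default_rng(7))
        d2 = draw_curve_sample(dorset.litter_curve, 30, np.random.default_rng(7))
        assert d1 == d2

    def test_draws_never_negative(self, moor_house):
        # Moor House litter has huge shape/rate SEs; draws stay feasible
        rng = np.random.default_rng(3)
        draws = [draw_curve_sample(moor_house.litter_curve, 10, rng)
                 for _ in range(2_000)]
        assert min(draws) >= 0.0


class TestRegistry:
    def test_contains_four_sites_with_expected_forms(self, registry):
        assert set(registry) == {"Kerloch", "Moor House", "Howden", "Dorset"}
        assert registry["Kerloch"].calluna_curve.a == 22.96
        assert registry["Howden"].calluna_curve.form == "loglinear"
        assert registry["Howden"].litter_curve.unit_scale == 0.01

    def test_matches_published_parameters_digit_for_digit(self, registry):
        expected = pd.read_csv(DATA_DIR / "site_parameters.csv")
        actual = registry_to_frame(registry)
        merged = expected.merge(actual, on=["site", "fraction"],
                                suffixes=("_exp", "_act"))
        assert len(merged) == 8
        for col in ("a", "b", "c", "se_a", "se_b", "se_c", "unit_scale"):
            exp, act = merged[f"{col}_exp"], merged[f"{col}_act"]
            ok = np.isclose(exp, act, rtol=0, atol=1e-12) | (exp.isna() & act.isna())
            assert ok.all(), col
        assert (merged["form_exp"] == merged["form_act"]).all()

    def test_carbon_constants(self, registry):
        carbon = registry["Kerloch"].carbon
        assert (carbon.c_frac_calluna, carbon.c_frac_litter) == (0.483, 0.490)
        assert (carbon.cc_calluna, carbon.cc_litter) == (0.714, 0.545)
        assert carbon.cc_wildfire == 1.0

    @pytest.mark.parametrize("suffix", [".csv", ".json"])
    def test_round_trip_serialisation(self, registry, tmp_path, suffix):
        path = tmp_path / f"registry{suffix}"
        save_registry(registry, path)
        loaded = load_registry(path)
        assert registry_to_frame(loaded).equals(
            registry_to_frame(registry).reset_index(drop=True)) or np.allclose(
            registry_to_frame(loaded).select_dtypes(float),
            registry_to_frame(registry).select_dtypes(float), equal_nan=True)
        assert set(loaded) == set(registry)


class TestValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(form="gompertz", a=-1.0, b=1.0, c=0.5),
        dict(form="gompertz", a=1.0, b=1.0, c=1.5),
        dict(form="gompertz", a=1.0, b=-0.1, c=0.5),
        dict(form="loglinear", a=1.0, b=-0.1, c=None),
        dict(form="gompertz", a=1.0, b=1.0, c=0.5, unit_scale=0.0),
        dict(form="spline", a=1.0, b=1.0, c=0.5),
    ])
    def test_invalid_curves_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GrowthCurve(**kwargs)
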