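"""Basal-mixture correction, difference method and ratio chaining."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swinecal.difference_method import (
    DietFormulation,
    basal_mixture_energy,
    dm_fractions,
    ingredient_by_difference,
    ingredient_energy,
    ratio_chain,
)

BASAL = DietFormulation(
    inclusions={"corn": 72.5, "soybean meal": 25.0, "minerals": 2.5},
    energy_free=("minerals",),
)
TEST = DietFormulation(
    inclusions={"corn": 58.0, "soybean meal": 20.0, "rsm": 19.5, "minerals": 2.5},
    test_ingredient="rsm",
    energy_free=("minerals",),
)


class TestBasalMixture:
    @pytest.mark.parametrize(
        "value, expected", [(0.0, 0.0), (12.05, 12.359), (16.08, 16.492)]
    )
    def test_division_by_mixture_fraction(self, value, expected):
        assert basal_mixture_energy(value) == pytest.approx(expected, abs=5e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            basal_mixture_energy(-1.0)


class TestDmFractions:
    def test_basal_diet(self):
        f_mix, f_test = dm_fractions(BASAL)
        assert f_mix == pytest.approx(0.975)
        assert f_test == 0.0

    def test_test_diet_as_fed_fallback(self):
        f_mix, f_test = dm_fractions(TEST)
        assert f_mix == pytest.approx(0.78)
        assert f_test == pytest.approx(0.195)

    def test_equal_dm_contents_match_fallback(self):
        with_dm = DietFormulation(
            inclusions=dict(TEST.inclusions),
            test_ingredient="rsm",
            energy_free=("minerals",),
            ingredient_dm={k: 89.0 for k in TEST.inclusions},
        )
        assert dm_fractions(with_dm) == pytest.approx(dm_fractions(TEST))

    def test_dm_contents_shift_fractions(self):
        wet_rsm = DietFormulation(
            inclusions=dict(TEST.inclusions),
            test_ingredient="rsm",
            energy_free=("minerals",),
            ingredient_dm={"corn": 88.0, "soybean meal": 88.0, "rsm": 93.5, "minerals": 99.0},
        )
        _, f_test = dm_fractions(wet_rsm)
        assert f_test > 0.195  # drier test ingredient carries a larger DM share

    def test_inclusions_must_sum_to_100(self):
        with pytest.raises(ValueError, match="sum to 100"):
            DietFormulation(inclusions={"corn": 50.0, "rsm": 40.0}, test_ingredient="rsm")


class TestDifference:
    def test_homogeneous_diet_recovers_mixture_value(self):
        # diet identical to the mixture: ingredient value equals mixture value
        v = ingredient_by_difference(12.0, 12.0, 0.8, 0.2)
        assert v == pytest.approx(12.0)

    @pytest.mark.parametrize(
        "diet, mixture, expected",
        [(11.59, 12.359, 10.00), (15.94, 16.492, 15.776)],
    )
    def test_worked_examples(self, diet, mixture, expected):
        assert ingredient_by_difference(diet, mixture, 0.78, 0.195) == pytest.approx(
            expected, abs=0.01
        )

    @pytest.mark.filterwarnings("ignore:negative ingredient value")
    @settings(max_examples=100, derandomize=True)
    @given(
        diet=st.floats(5.0, 20.0),
        mixture=st.floats(5.0, 20.0),
        delta=st.floats(0.01, 5.0),
    )
    def test_linearity_in_diet_value(self, diet, mixture, delta):
        f_mix, f_test = 0.78, 0.195
        lo = ingredient_by_difference(diet, mixture, f_mix, f_test)
        hi = ingredient_by_difference(diet + delta, mixture, f_mix, f_test)
        assert hi - lo == pytest.approx(delta / f_test, rel=1e-9)

    def test_zero_test_fraction_rejected(self):
        with pytest.raises(ValueError):
            ingredient_by_difference(10.0, 10.0, 1.0, 0.0)

    def test_negative_result_warns(self):
        with pytest.warns(UserWarning, match="negative ingredient value"):
            ingredient_by_difference(5.0, 12.0, 0.78, 0.195)


class TestRatioChain:
    def test_unit_ratios(self):
        r = ratio_chain(20.0, 20.0, 20.0, 20.0, 20.0)
        assert (r.de_final, r.me_final, r.ne_final) == (20.0, 20.0, 20.0)

    def test_plain_arithmetic(self):
        r = ratio_chain(20.0, 20.0, 15.0, 13.5, 9.72)
        assert r.de_final == pytest.approx(15.0)
        assert r.me_final == pytest.approx(13.5)
        assert r.ne_final == pytest.approx(9.72)

    def test_expeller_meal_headline_values(self):
        # measured GE 21.35 chained through 73.9% x 88.97% x 72.21%
        r = ratio_chain(21.35, 21.35, 21.35 * 0.739, 21.35 * 0.739 * 0.8897,
                        21.35 * 0.739 * 0.8897 * 0.7221)
        assert r.de_final == pytest.approx(15.78, abs=0.01)
        assert r.me_final == pytest.approx(14.04, abs=0.01)
        assert r.ne_final == pytest.approx(10.14, abs=0.01)

    def test_reconstruction_invariant(self):
        r = ratio_chain(21.35, 20.9, 15.5, 13.9, 10.2)
        assert r.de_final == pytest.approx(r.ge_measured_mj_per_kg_dm * r.de_ge_pct / 100, rel=1e-12)
        assert r.me_final == pytest.approx(r.de_final * r.me_de_pct / 100, rel=1e-12)
        assert r.ne_final == pytest.approx(r.me_final * r.ne_me_pct / 100, rel=1e-12)

    def test_non_positive_denominator_rejected(self):
        with pytest.raises(ValueError, match="de_raw"):
            ratio_chain(20.0, 20.0, 0.0, 10.0, 8.0)


class TestEndToEnd:
    def test_known_composition_recovered_exactly(self):
        # compose a test diet from known mixture and ingredient values, then invert
        mixture = {"ge": 18.6, "de": 16.5, "me": 15.9, "ne": 12.4}
        ingredient = {"ge": 21.0, "de": 15.5, "me": 14.0, "ne": 10.0}
        basal = {k: v * 0.975 for k, v in mixture.items()}
        diet = {k: 0.78 * mixture[k] + 0.195 * ingredient[k] for k in mixture}
        res = ingredient_energy(ingredient["ge"], basal, diet, TEST)
        assert res.ge_raw == pytest.approx(ingredient["ge"], rel=1e-10)
        assert res.de_final == pytest.approx(ingredient["de"], rel=1e-10)
        assert res.me_final == pytest.approx(ingredient["me"], rel=1e-10)
        assert res.ne_final == pytest.approx(ingredient["ne"], rel=1e-10)
        assert not res.flagged

    def test_noisy_negative_raw_flags_sample(self):
        basal = {"ge": 18.0, "de": 16.0, "me": 15.5, "ne": 12.0}
        diet = {"ge": 14.0, "de": 11.0, "me": 3.0, "ne": 2.0}  # implausible ME
        with pytest.warns(UserWarning):
            res = ingredient_energy(21.0, basal, diet, TEST)
        assert res.flagged
        assert math.isnan(res.ne_final)
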