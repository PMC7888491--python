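"""Ingredient energy values by the difference method with ratio chaining.

A test ingredient's GE/DE/ME/NE is obtained from a basal diet and a test
diet in which the ingredient replaces part of the basal mixture:

1. the basal diet's value is divided by the basal mixture's DM fraction
   (0.975 when 2.5% of the diet is energy-free mineral/premix) to give the
   energy value of the corn-soybean mixture itself;
2. the mixture's contribution is subtracted from the test diet's value and
   the remainder divided by the ingredient's inclusion fraction,
   value = (diet - f_mix * mixture) / f_test;
3. the resulting raw GE/DE/ME/NE values give DE/GE, ME/DE and NE/ME ratios
   that are chained onto the ingredient's bomb-calorimetry GE to yield the
   final (headline) DE, ME and NE values.

All calculations are on a dry-matter basis; inclusion fractions can be
converted with explicit ingredient DM contents or taken as-fed when DM
contents are not supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "BASAL_MIXTURE_FRACTION",
    "DietFormulation",
    "IngredientEnergyResult",
    "basal_mixture_energy",
    "dm_fractions",
    "ingredient_by_difference",
    "ratio_chain",
    "ingredient_energy",
]

#: DM fraction of the corn + soybean-meal mixture in the basal diet
#: (the remaining 2.5% is mineral/vitamin premix, treated as energy-free).
BASAL_MIXTURE_FRACTION = 0.975

ENERGIES = ("ge", "de", "me", "ne")


@dataclass(frozen=True)
class DietFormulation:
    """Ingredient inclusions of one diet, as-fed percent.

    ``energy_free`` names the mineral/premix ingredients that contribute no
    energy; every other non-test ingredient belongs to the basal mixture.
    ``ingredient_dm`` (percent DM per ingredient) enables exact DM-basis
    fractions; without it the as-fed inclusions are used directly, which is
    exact when all ingredients have equal DM content.
    """

    inclusions: Mapping[str, float]
    test_ingredient: str | None = None
    energy_free: tuple[str, ...] = ()
    ingredient_dm: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        total = sum(self.inclusions.values())
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"inclusions must sum to 100 +- 0.01, got {total!r}")
        if self.test_ingredient is not None:
            if self.inclusions.get(self.test_ingredient, 0.0) <= 0:
                raise ValueError(
                    f"test ingredient {self.test_ingredient!r} has no positive inclusion"
                )
        for name in self.energy_free:
            if name not in self.inclusions:
                raise ValueError(f"energy-free ingredient {name!r} not in the formulation")


def basal_mixture_energy(
    basal_diet_value: float, mixture_fraction: float = BASAL_MIXTURE_FRACTION
) -> float:
    """Energy value of the basal mixture from the basal diet's value.

    Dividing by the mixture's DM fraction attributes the whole of the
    diet's energy to the mixture, the mineral fraction being energy-free.
    """
    if basal_diet_value < 0:
        raise ValueError(f"basal_diet_value must be non-negative, got {basal_diet_value!r}")
    if not 0 < mixture_fraction <= 1:
        raise ValueError(f"mixture_fraction must lie in (0, 1], got {mixture_fraction!r}")
    return basal_diet_value / mixture_fraction


def dm_fractions(formulation: DietFormulation) -> tuple[float, float]:
    """(f_mix, f_test): DM-basis fractions of the basal mixture and test ingredient.

    With ingredient DM contents, each inclusion is weighted by its DM and
    normalised over the whole diet; otherwise as-fed inclusions are used
    (the two coincide when all DM contents are equal).
    """
    dm = formulation.ingredient_dm
    weights = {
        name: incl * (dm[name] if dm is not None else 1.0)
        for name, incl in formulation.inclusions.items()
    }
    if dm is not None and any(name not in dm for name in formulation.inclusions):
        missing = [n for n in formulation.inclusions if n not in dm]
        raise ValueError(f"ingredient_dm missing entries for {missing}")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("formulation has non-positive total DM weight")
    f_test = (
        weights[formulation.test_ingredient] / total
        if formulation.test_ingredient is not None
        else 0.0
    )
    f_mix = (
        sum(
            w
            for name, w in weights.items()
            if name != formulation.test_ingredient and name not in formulation.energy_free
        )
        / total
    )
    for name, f in (("f_mix", f_mix), ("f_test", f_test)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} outside [0, 1]: {f!r}")
    return f_mix, f_test


def ingredient_by_difference(
    diet_value: float, mixture_value: float, f_mix: float, f_test: float
) -> float:
    """Raw ingredient energy value (MJ/kg DM) from a test diet's value.

    The mixture's weighted contribution is removed from the diet value and
    the remainder attributed to the test ingredient's fraction.  A negative
    result (possible under measurement noise) is returned with a warning.
    """
    if f_test <= 0:
        raise ValueError(f"f_test must be strictly positive, got {f_test!r}")
    value = (diet_value - f_mix * mixture_value) / f_test
    if value < 0:
        warnings.warn(
            f"negative ingredient value by difference ({value:.3f} MJ/kg DM)", stacklevel=2
        )
    return value


@dataclass
class IngredientEnergyResult:
    """Raw difference-method values, ratios, and ratio-chained final values."""

    ingredient: str
    ge_measured_mj_per_kg_dm: float
    ge_raw: float
    de_raw: float
    me_raw: float
    ne_raw: float
    de_ge_pct: float
    me_de_pct: float
    ne_me_pct: float
    de_final: float
    me_final: float
    ne_final: float
    flagged: bool = False  # True when a raw value was non-positive


def ratio_chain(
    ge_measured: float,
    ge_raw: float,
    de_raw: float,
    me_raw: float,
    ne_raw: float,
    ingredient: str = "",
) -> IngredientEnergyResult:
    """Chain DE/GE, ME/DE and NE/ME ratios onto the measured GE.

    de_final = GE_measured * (DE/GE); me_final = de_final * (ME/DE);
    ne_final = me_final * (NE/ME).  The chained finals equal the raw values
    whenever ge_raw equals ge_measured.
    """
    for name, v in (("ge_raw", ge_raw), ("de_raw", de_raw), ("me_raw", me_raw)):
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive for ratio chaining, got {v!r}")
    de_ge = de_raw / ge_raw
    me_de = me_raw / de_raw
    ne_me = ne_raw / me_raw
    de_final = ge_measured * de_ge
    me_final = de_final * me_de
    ne_final = me_final * ne_me
    return IngredientEnergyResult(
        ingredient=ingredient,
        ge_measured_mj_per_kg_dm=ge_measured,
        ge_raw=ge_raw,
        de_raw=de_raw,
        me_raw=me_raw,
        ne_raw=ne_raw,
        de_ge_pct=100.0 * de_ge,
        me_de_pct=100.0 * me_de,
        ne_me_pct=100.0 * ne_me,
        de_final=de_final,
        me_final=me_final,
        ne_final=ne_final,
    )


def ingredient_energy(
    ge_measured: float,
    basal_values: Mapping[str, float],
    test_diet_values: Mapping[str, float],
    formulation: DietFormulation,
    mixture_fraction: float = BASAL_MIXTURE_FRACTION,
) -> IngredientEnergyResult:
    """End-to-end difference method for one test diet.

    ``basal_values`` and ``test_diet_values`` map 'ge'/'de'/'me'/'ne' to
    MJ/kg DM diet-level values.  The basal values are converted to mixture
    values, raw ingredient values obtained by difference, and the finals
    ratio-chained onto ``ge_measured``.  If any raw value needed for
    chaining is non-positive the raw values are reported unchained and the
    result flagged.
    """
    for key in ENERGIES:
        if key not in basal_values or key not in test_diet_values:
            raise ValueError(f"missing energy key {key!r} in diet values")
    f_mix, f_test = dm_fractions(formulation)
    mixture = {k: basal_mixture_energy(basal_values[k], mixture_fraction) for k in ENERGIES}
    raw = {
        k: ingredient_by_difference(test_diet_values[k], mixture[k], f_mix, f_test)
        for k in ENERGIES
    }
    name = formulation.test_ingredient or ""
    if raw["ge"] <= 0 or raw["de"] <= 0 or raw["me"] <= 0:
        warnings.warn(
            f"{name or 'ingredient'}: non-positive raw value; ratios not chained", stacklevel=2
        )
        nan = float("nan")
        return IngredientEnergyResult(
            ingredient=name,
            ge_measured_mj_per_kg_dm=ge_measured,
            ge_raw=raw["ge"],
            de_raw=raw["de"],
            me_raw=raw["me"],
            ne_raw=raw["ne"],
            de_ge_pct=nan,
            me_de_pct=nan,
            ne_me_pct=nan,
            de_final=nan,
            me_final=nan,
            ne_final=nan,
            flagged=True,
        )
    return ratio_chain(ge_measured, raw["ge"], raw["de"], raw["me"], raw["ne"], ingredient=name)
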