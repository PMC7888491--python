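"""Indirect-calorimetry primitives.

Heat production of a pig in an open-circuit respiration chamber is computed
from gas exchange (O2 consumed, CO2 and CH4 produced, in litres) and urinary
nitrogen excretion with the Brouwer equation,

    THP (kJ) = 16.18*O2 + 5.02*CO2 - 2.17*CH4 - 5.99*urinary N,

with volumes in L and N in g.  Fasting heat production (FHP) is the same
computation on a short window measured after feed deprivation, extrapolated
linearly to a 24-h basis.  Energy intake and heat are scaled by metabolic
body weight, BW^0.6, throughout.

The module also provides the inverse computation (gas volumes from a target
heat production at a given respiratory quotient), which the synthetic-data
generator uses to emit chamber records that are exactly energy-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "BrouwerCoefficients",
    "GasExchangeWindow",
    "HeatProduction",
    "brouwer_thp",
    "respiratory_quotient",
    "methane_energy",
    "metabolic_weight",
    "fasting_heat_production",
    "gas_from_heat",
]


@dataclass(frozen=True)
class BrouwerCoefficients:
    """Energy-equivalence coefficients for indirect calorimetry.

    ``o2``/``co2``/``ch4`` are kJ per litre of gas exchanged and
    ``urinary_n`` is kJ per g of urinary nitrogen in the heat-production
    equation; ``methane_ge`` is the gross energy of methane (kJ/L) used to
    account for energy lost as CH4 when computing metabolizable energy.
    """

    o2: float = 16.18
    co2: float = 5.02
    ch4: float = 2.17
    urinary_n: float = 5.99
    methane_ge: float = 39.54

    def __post_init__(self) -> None:
        for name in ("o2", "co2", "ch4", "urinary_n", "methane_ge"):
            if getattr(self, name) <= 0:
                raise ValueError(f"coefficient {name!r} must be strictly positive")


#: Module-wide default coefficient set.
BROUWER = BrouwerCoefficients()


@dataclass(frozen=True)
class GasExchangeWindow:
    """Gas exchange totals over one measurement window.

    Volumes are litres accumulated over the window; ``urinary_n_g`` is the
    urinary nitrogen excretion (g) attributable to the window.  ``state``
    records whether the pig was fed or fasted during the window.
    """

    o2_l: float
    co2_l: float
    ch4_l: float
    duration_h: float
    state: Literal["fed", "fasted"] = "fed"
    urinary_n_g: float = 0.0

    def __post_init__(self) -> None:
        for name in ("o2_l", "co2_l", "ch4_l", "urinary_n_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)!r}")
        if not 0 < self.duration_h <= 24:
            raise ValueError(f"duration_h must lie in (0, 24], got {self.duration_h!r}")
        if self.state not in ("fed", "fasted"):
            raise ValueError(f"state must be 'fed' or 'fasted', got {self.state!r}")


@dataclass(frozen=True)
class HeatProduction:
    """Daily heat production, optionally scaled by metabolic body weight."""

    thp_kj_per_d: float
    rq: float
    per_mbw: float | None = None  # kJ/kg BW^0.6/d when BW supplied


def brouwer_thp(window: GasExchangeWindow, coeffs: BrouwerCoefficients = BROUWER) -> float:
    """Heat production (kJ) over a gas-exchange window, Brouwer equation."""
    return (
        coeffs.o2 * window.o2_l
        + coeffs.co2 * window.co2_l
        - coeffs.ch4 * window.ch4_l
        - coeffs.urinary_n * window.urinary_n_g
    )


def respiratory_quotient(co2_l: float, o2_l: float) -> float:
    """RQ: litres of CO2 produced per litre of O2 consumed."""
    if o2_l <= 0:
        raise ValueError(f"o2_l must be strictly positive, got {o2_l!r}")
    return co2_l / o2_l


def methane_energy(ch4_l: float, coeffs: BrouwerCoefficients = BROUWER) -> float:
    """Energy lost as methane (kJ) from the CH4 volume produced (L)."""
    if ch4_l < 0:
        raise ValueError(f"ch4_l must be non-negative, got {ch4_l!r}")
    return coeffs.methane_ge * ch4_l


def metabolic_weight(bw_kg: float) -> float:
    """Metabolic body weight BW^0.6 (kg^0.6)."""
    if bw_kg <= 0:
        raise ValueError(f"bw_kg must be strictly positive, got {bw_kg!r}")
    return bw_kg**0.6


def fasting_heat_production(
    window: GasExchangeWindow,
    bw_kg: float,
    coeffs: BrouwerCoefficients = BROUWER,
) -> HeatProduction:
    """FHP on a 24-h basis from a fasted-state window.

    The window's Brouwer heat is scaled linearly by ``24 / duration_h``
    (x3 for the usual terminal 8-h nocturnal window).  The window should
    carry the share of the 24-h fasting urinary N proportional to its
    duration; the linear rescaling then reproduces the value obtained from
    the full daily excretion.
    """
    if window.state != "fasted":
        raise ValueError("fasting_heat_production requires a fasted-state window")
    scale = 24.0 / window.duration_h
    fhp = brouwer_thp(window, coeffs) * scale
    rq = respiratory_quotient(window.co2_l, window.o2_l) if window.o2_l > 0 else math.nan
    return HeatProduction(
        thp_kj_per_d=fhp,
        rq=rq,
        per_mbw=fhp / metabolic_weight(bw_kg),
    )


def gas_from_heat(
    thp_kj: float,
    rq: float,
    ch4_l: float = 0.0,
    urinary_n_g: float = 0.0,
    coeffs: BrouwerCoefficients = BROUWER,
) -> tuple[float, float]:
    """Invert the Brouwer equation: (O2, CO2) volumes for a target heat.

    Given a heat production over a window, a respiratory quotient, and the
    window's CH4 and urinary N, solve

        thp = o2*(c_o2 + c_co2*rq) - c_ch4*ch4 - c_n*n,    co2 = rq*o2.

    Used by the synthetic generator so that ``brouwer_thp`` applied to the
    emitted window returns ``thp_kj`` exactly (to float round-off).
    """
    if thp_kj < 0:
        raise ValueError(f"thp_kj must be non-negative, got {thp_kj!r}")
    if not 0.6 < rq < 1.3:
        raise ValueError(f"rq must lie in (0.6, 1.3), got {rq!r}")
    if ch4_l < 0 or urinary_n_g < 0:
        raise ValueError("ch4_l and urinary_n_g must be non-negative")
    denom = coeffs.o2 + coeffs.co2 * rq
    if denom <= 0:
        raise ValueError("non-positive Brouwer denominator; check coefficients")
    o2 = (thp_kj + coeffs.ch4 * ch4_l + coeffs.urinary_n * urinary_n_g) / denom
    return o2, rq * o2
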