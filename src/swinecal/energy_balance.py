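"""Per-pig and per-diet nutrient digestibility, nitrogen balance and energy partition.

One ``PigPeriodRecord`` holds everything measured on one pig in one
collection period: dry-matter and gross-energy intake, fecal and urinary
outputs with their energies and nitrogen, methane production, per-nutrient
intake/output masses, the fed-state gas-exchange windows and the terminal
fasted window.  From it the module computes

* apparent total-tract digestibility (ATTD), 100*(intake - fecal)/intake;
* nitrogen balance and retained protein energy, N_ret * 6.25 * 23.86 kJ/g;
* DE = (GE intake - fecal E)/DMI and ME = DE - (urinary E + CH4 E)/DMI;
* total heat production from the fed windows (Brouwer) and fasting heat
  production from the fasted window;
* retained energy RE = ME intake - THP, split into protein (RE_P) and lipid
  (RE_L = RE - RE_P) fractions;
* net energy NE = (RE + FHP)/DMI, by default with each pig's own FHP.

Diet-level results are unweighted arithmetic means of the per-pig values;
mixed-model standard errors and significance testing are out of scope.
Energies are carried in kJ internally and converted to MJ/kg DM only in the
reported diet values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from statistics import fmean
from typing import Literal, Mapping, Sequence

from .calorimetry import (
    BROUWER,
    BrouwerCoefficients,
    GasExchangeWindow,
    brouwer_thp,
    fasting_heat_production,
    metabolic_weight,
    methane_energy,
    respiratory_quotient,
)

__all__ = [
    "NUTRIENTS",
    "PigPeriodRecord",
    "PigEnergyBalance",
    "DietEnergyResult",
    "attd",
    "nitrogen_balance",
    "retained_protein_energy",
    "diet_energy_values",
    "retained_energy",
    "diet_ne",
    "pig_energy_balance",
    "summarize_diet",
]

#: Nutrients tracked for digestibility, in reporting order.
NUTRIENTS = ("DM", "CP", "OM", "NDF", "ADF", "EE")

#: kJ of protein energy per g of retained N (N x 6.25 g protein x 23.86 kJ/g).
PROTEIN_PER_N = 6.25
PROTEIN_ENERGY_KJ_PER_G = 23.86

FhpPolicy = Literal["per-pig", "diet-mean", "fixed"]


@dataclass
class PigPeriodRecord:
    """All measurements on one pig over one balance period (daily basis)."""

    pig_id: str
    diet_id: str
    period: int
    bw_kg: float
    dm_intake_kg_per_d: float
    ge_intake_kj_per_d: float
    fecal_energy_kj_per_d: float
    urinary_energy_kj_per_d: float
    ch4_l_per_d: float
    n_intake_g_per_d: float
    fecal_n_g_per_d: float
    urinary_n_g_per_d: float
    nutrient_intakes: Mapping[str, float] = field(default_factory=dict)  # g/d
    fecal_outputs: Mapping[str, float] = field(default_factory=dict)  # g/d
    fed_windows: Sequence[GasExchangeWindow] = field(default_factory=tuple)
    fasted_window: GasExchangeWindow | None = None

    def __post_init__(self) -> None:
        if self.bw_kg <= 0:
            raise ValueError(f"bw_kg must be strictly positive, got {self.bw_kg!r}")
        if self.dm_intake_kg_per_d <= 0:
            raise ValueError(
                f"dm_intake_kg_per_d must be strictly positive, got {self.dm_intake_kg_per_d!r}"
            )
        for w in self.fed_windows:
            if w.state != "fed":
                raise ValueError("fed_windows must contain only fed-state windows")
        if self.fasted_window is not None and self.fasted_window.state != "fasted":
            raise ValueError("fasted_window must be a fasted-state window")


def attd(intake_g_per_d: float, fecal_g_per_d: float) -> float:
    """Apparent total-tract digestibility, percent of intake."""
    if intake_g_per_d <= 0:
        raise ValueError(f"intake must be strictly positive, got {intake_g_per_d!r}")
    if fecal_g_per_d < 0:
        raise ValueError(f"fecal output must be non-negative, got {fecal_g_per_d!r}")
    return 100.0 * (intake_g_per_d - fecal_g_per_d) / intake_g_per_d


def nitrogen_balance(n_intake: float, fecal_n: float, urinary_n: float) -> float:
    """N retention (g/d) = intake - fecal - urinary; negative values are kept."""
    for name, v in (("n_intake", n_intake), ("fecal_n", fecal_n), ("urinary_n", urinary_n)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v!r}")
    retention = n_intake - fecal_n - urinary_n
    if retention < 0:
        warnings.warn(f"negative N retention ({retention:.2f} g/d)", stacklevel=2)
    return retention


def retained_protein_energy(n_retention_g_per_d: float, bw_kg: float) -> float:
    """Protein-retention energy, kJ/kg BW^0.6/d."""
    return (
        n_retention_g_per_d * PROTEIN_PER_N * PROTEIN_ENERGY_KJ_PER_G / metabolic_weight(bw_kg)
    )


def diet_energy_values(
    record: PigPeriodRecord, coeffs: BrouwerCoefficients = BROUWER
) -> tuple[float, float, float]:
    """(DE, ME) in MJ/kg DM and urinary energy as % of DE, for one pig.

    DE removes fecal energy from the gross-energy intake; ME additionally
    removes urinary energy and the energy of the methane produced.
    """
    if record.dm_intake_kg_per_d <= 0:
        raise ValueError("dm_intake_kg_per_d must be strictly positive")
    de_kj_per_d = record.ge_intake_kj_per_d - record.fecal_energy_kj_per_d
    ch4_kj_per_d = methane_energy(record.ch4_l_per_d, coeffs)
    me_kj_per_d = de_kj_per_d - record.urinary_energy_kj_per_d - ch4_kj_per_d
    de = de_kj_per_d / record.dm_intake_kg_per_d / 1000.0
    me = me_kj_per_d / record.dm_intake_kg_per_d / 1000.0
    urinary_pct = 100.0 * record.urinary_energy_kj_per_d / de_kj_per_d if de_kj_per_d else math.nan
    return de, me, urinary_pct


def retained_energy(me_intake_kj_per_d: float, thp_kj_per_d: float) -> float:
    """RE (kJ/d) = ME intake - total heat production; negative values kept."""
    re = me_intake_kj_per_d - thp_kj_per_d
    if re < 0:
        warnings.warn(f"negative retained energy ({re:.0f} kJ/d)", stacklevel=2)
    return re


def diet_ne(re_kj_per_d: float, fhp_kj_per_d: float, dmi_kg_per_d: float) -> float:
    """Diet net energy, MJ/kg DM: (RE + FHP) / DM intake."""
    if dmi_kg_per_d <= 0:
        raise ValueError(f"dmi_kg_per_d must be strictly positive, got {dmi_kg_per_d!r}")
    return (re_kj_per_d + fhp_kj_per_d) / dmi_kg_per_d / 1000.0


@dataclass
class PigEnergyBalance:
    """Computed balance for one pig-period (daily and per-mbw bases)."""

    pig_id: str
    diet_id: str
    period: int
    bw_kg: float
    mbw: float
    dmi_kg_per_d: float
    attd: dict[str, float]
    n_retention_g_per_d: float
    de_mj_per_kg_dm: float
    me_mj_per_kg_dm: float
    ne_mj_per_kg_dm: float
    me_intake_kj_per_d: float
    thp_kj_per_d: float
    fhp_kj_per_d: float
    re_kj_per_d: float
    re_p_kj_per_d: float
    re_l_kj_per_d: float
    urinary_e_pct_of_de: float
    rq_fed: float
    rq_fasted: float

    @property
    def per_mbw(self) -> dict[str, float]:
        """THP/FHP/RE/RE_P/RE_L on the kJ/kg BW^0.6/d basis."""
        return {
            "thp": self.thp_kj_per_d / self.mbw,
            "fhp": self.fhp_kj_per_d / self.mbw,
            "re": self.re_kj_per_d / self.mbw,
            "re_p": self.re_p_kj_per_d / self.mbw,
            "re_l": self.re_l_kj_per_d / self.mbw,
        }


def _daily_thp(windows: Sequence[GasExchangeWindow], coeffs: BrouwerCoefficients) -> float:
    # each window is scaled to 24 h, then days are averaged
    if not windows:
        raise ValueError("at least one fed-state window is required")
    return fmean(brouwer_thp(w, coeffs) * 24.0 / w.duration_h for w in windows)


def pig_energy_balance(
    record: PigPeriodRecord,
    coeffs: BrouwerCoefficients = BROUWER,
    fhp_kj_per_d: float | None = None,
) -> PigEnergyBalance:
    """Full energy and nitrogen balance for one pig-period.

    ``fhp_kj_per_d`` overrides the pig's own fasted-window FHP (used by the
    diet-mean and fixed FHP policies); by default the pig's own fasted
    window is required and used.
    """
    mbw = metabolic_weight(record.bw_kg)
    thp = _daily_thp(record.fed_windows, coeffs)
    rq_fed = fmean(respiratory_quotient(w.co2_l, w.o2_l) for w in record.fed_windows)

    if fhp_kj_per_d is None:
        if record.fasted_window is None:
            raise ValueError(f"pig {record.pig_id}: no fasted window and no FHP override")
        fhp_kj_per_d = fasting_heat_production(record.fasted_window, record.bw_kg, coeffs).thp_kj_per_d
    rq_fasted = (
        respiratory_quotient(record.fasted_window.co2_l, record.fasted_window.o2_l)
        if record.fasted_window is not None
        else math.nan
    )

    de, me, urinary_pct = diet_energy_values(record, coeffs)
    me_intake = me * 1000.0 * record.dm_intake_kg_per_d
    re = retained_energy(me_intake, thp)
    n_ret = nitrogen_balance(
        record.n_intake_g_per_d, record.fecal_n_g_per_d, record.urinary_n_g_per_d
    )
    re_p = n_ret * PROTEIN_PER_N * PROTEIN_ENERGY_KJ_PER_G
    re_l = re - re_p
    ne = diet_ne(re, fhp_kj_per_d, record.dm_intake_kg_per_d)

    digestibility = {
        nut: attd(record.nutrient_intakes[nut], record.fecal_outputs.get(nut, 0.0))
        for nut in record.nutrient_intakes
    }
    digestibility["GE"] = attd(record.ge_intake_kj_per_d, record.fecal_energy_kj_per_d)

    return PigEnergyBalance(
        pig_id=record.pig_id,
        diet_id=record.diet_id,
        period=record.period,
        bw_kg=record.bw_kg,
        mbw=mbw,
        dmi_kg_per_d=record.dm_intake_kg_per_d,
        attd=digestibility,
        n_retention_g_per_d=n_ret,
        de_mj_per_kg_dm=de,
        me_mj_per_kg_dm=me,
        ne_mj_per_kg_dm=ne,
        me_intake_kj_per_d=me_intake,
        thp_kj_per_d=thp,
        fhp_kj_per_d=fhp_kj_per_d,
        re_kj_per_d=re,
        re_p_kj_per_d=re_p,
        re_l_kj_per_d=re_l,
        urinary_e_pct_of_de=urinary_pct,
        rq_fed=rq_fed,
        rq_fasted=rq_fasted,
    )


@dataclass
class DietEnergyResult:
    """Diet-level means across pigs (mirrors a diet column of a balance table)."""

    diet_id: str
    n_pigs: int
    bw_kg: float
    dmi_kg_per_d: float
    attd: dict[str, float]  # percent, per nutrient + "GE"
    n_balance: dict[str, float]  # intake/fecal/urinary/retention g/d
    de_mj_per_kg_dm: float
    me_mj_per_kg_dm: float
    ne_mj_per_kg_dm: float
    me_intake_per_mbw: float
    thp_per_mbw: float
    fhp_per_mbw: float
    re_per_mbw: float
    re_p_per_mbw: float
    re_l_per_mbw: float
    ratios: dict[str, float]  # urinaryE_pct_of_DE, me_de_pct, ne_me_pct
    rq_fed: float
    rq_fasted: float


def summarize_diet(
    records: Sequence[PigPeriodRecord],
    coeffs: BrouwerCoefficients = BROUWER,
    fhp_policy: FhpPolicy = "per-pig",
    fixed_fhp_per_mbw: float | None = None,
) -> DietEnergyResult:
    """Mean energy balance over the pigs fed one diet.

    FHP policy: ``per-pig`` uses each pig's own fasted window in its NE
    (the default, minimising the impact of FHP measurement variation);
    ``diet-mean`` applies the diet's mean FHP per mbw to every pig;
    ``fixed`` applies ``fixed_fhp_per_mbw`` to every pig.
    """
    if not records:
        raise ValueError("summarize_diet requires at least one record")
    diet_ids = {r.diet_id for r in records}
    if len(diet_ids) != 1:
        raise ValueError(f"records span multiple diets: {sorted(diet_ids)}")

    if fhp_policy == "per-pig":
        balances = [pig_energy_balance(r, coeffs) for r in records]
    elif fhp_policy == "diet-mean":
        own = [pig_energy_balance(r, coeffs) for r in records]
        mean_fhp_per_mbw = fmean(b.per_mbw["fhp"] for b in own)
        balances = [
            pig_energy_balance(r, coeffs, fhp_kj_per_d=mean_fhp_per_mbw * metabolic_weight(r.bw_kg))
            for r in records
        ]
    elif fhp_policy == "fixed":
        if fixed_fhp_per_mbw is None:
            raise ValueError("fixed FHP policy requires fixed_fhp_per_mbw")
        balances = [
            pig_energy_balance(r, coeffs, fhp_kj_per_d=fixed_fhp_per_mbw * metabolic_weight(r.bw_kg))
            for r in records
        ]
    else:
        raise ValueError(f"unknown FHP policy {fhp_policy!r}")

    nut_names = sorted({k for b in balances for k in b.attd}, key=str)
    mean_attd = {n: fmean(b.attd[n] for b in balances if n in b.attd) for n in nut_names}
    mean_per_mbw = {
        k: fmean(b.per_mbw[k] for b in balances) for k in ("thp", "fhp", "re", "re_p", "re_l")
    }
    de = fmean(b.de_mj_per_kg_dm for b in balances)
    me = fmean(b.me_mj_per_kg_dm for b in balances)
    ne = fmean(b.ne_mj_per_kg_dm for b in balances)
    return DietEnergyResult(
        diet_id=records[0].diet_id,
        n_pigs=len(balances),
        bw_kg=fmean(r.bw_kg for r in records),
        dmi_kg_per_d=fmean(r.dm_intake_kg_per_d for r in records),
        attd=mean_attd,
        n_balance={
            "intake": fmean(r.n_intake_g_per_d for r in records),
            "fecal": fmean(r.fecal_n_g_per_d for r in records),
            "urinary": fmean(r.urinary_n_g_per_d for r in records),
            "retention": fmean(b.n_retention_g_per_d for b in balances),
        },
        de_mj_per_kg_dm=de,
        me_mj_per_kg_dm=me,
        ne_mj_per_kg_dm=ne,
        me_intake_per_mbw=fmean(b.me_intake_kj_per_d / b.mbw for b in balances),
        thp_per_mbw=mean_per_mbw["thp"],
        fhp_per_mbw=mean_per_mbw["fhp"],
        re_per_mbw=mean_per_mbw["re"],
        re_p_per_mbw=mean_per_mbw["re_p"],
        re_l_per_mbw=mean_per_mbw["re_l"],
        ratios={
            "urinaryE_pct_of_DE": fmean(b.urinary_e_pct_of_de for b in balances),
            "me_de_pct": fmean(100.0 * b.me_mj_per_kg_dm / b.de_mj_per_kg_dm for b in balances),
            "ne_me_pct": fmean(100.0 * b.ne_mj_per_kg_dm / b.me_mj_per_kg_dm for b in balances),
        },
        rq_fed=fmean(b.rq_fed for b in balances),
        rq_fasted=fmean(b.rq_fasted for b in balances),
    )
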