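"""End-to-end orchestration: simulate or load, balance, difference, predict.

``run_pipeline`` ties the stages together in protocol order — gas exchange
to heat production, energy partition to diet DE/ME/NE, difference method to
ingredient values, and panel correlation/regression to NE prediction
equations — and emits report tables (diet balance, ingredient energy
values, correlation matrix, fitted equations) plus a machine-readable run
log.  Outputs are tab-separated text; reruns with the same configuration
and seed are byte-identical.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from . import __version__
from .difference_method import (
    BASAL_MIXTURE_FRACTION,
    DietFormulation,
    IngredientEnergyResult,
    ingredient_energy,
)
from .energy_balance import (
    DietEnergyResult,
    FhpPolicy,
    PigPeriodRecord,
    summarize_diet,
)
from .io import read_panel, read_pig_periods, write_pig_periods
from .ne_prediction import (
    RegressionModel,
    SamplePanelRow,
    fit_equation_families,
    pearson_matrix,
)
from .synthetic_data import (
    NoiseConfig,
    TruthConfig,
    generate_experiment,
    reference_study_config,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "reference_panel", "rank_equations"]


def reference_panel() -> list[SamplePanelRow]:
    """The five in-study rapeseed-meal samples shipped with the package.

    The published equations rest on eight samples; the remaining three come
    from companion studies and can be appended from a user-supplied panel
    file (see ``data/rsm_panel_template.tsv``).
    """
    ref = importlib.resources.files("swinecal.data").joinpath("rsm_panel.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_panel(path)


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source plus policies."""

    seed: int | None = None
    simulate: bool = True
    noise: NoiseConfig | None = None
    truth: TruthConfig | None = None  # overrides the reference preset
    periods_path: str | Path | None = None
    windows_path: str | Path | None = None
    formulations: Mapping[str, DietFormulation] | None = None
    ge_measured: Mapping[str, float] | None = None
    basal_diet_id: str = "basal"
    mixture_fraction: float = BASAL_MIXTURE_FRACTION
    fhp_policy: FhpPolicy = "per-pig"
    fixed_fhp_per_mbw: float | None = None
    panel_path: str | Path | None = None  # extra samples for the regression stage
    alpha_enter: float = 0.15
    alpha_stay: float = 0.15
    units: Literal["MJ", "kJ"] = "MJ"
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        file_input = self.periods_path is not None or self.windows_path is not None
        if self.simulate and file_input:
            raise ValueError("choose exactly one input source: simulate or input tables")
        if not self.simulate and not file_input and self.truth is None:
            raise ValueError("no input source: set simulate=True or provide input tables")
        if self.units not in ("MJ", "kJ"):
            raise ValueError(f"units must be 'MJ' or 'kJ', got {self.units!r}")


@dataclass
class ReportBundle:
    diet_results: dict[str, DietEnergyResult]
    ingredient_results: dict[str, IngredientEnergyResult]
    diet_table: pd.DataFrame
    ingredient_table: pd.DataFrame
    correlation_r: pd.DataFrame | None
    correlation_p: pd.DataFrame | None
    equations: dict[str, RegressionModel]
    panel: list[SamplePanelRow]
    log: dict


def _diet_table(results: Mapping[str, DietEnergyResult], units: str) -> pd.DataFrame:
    scale = 1000.0 if units == "kJ" else 1.0
    unit = "kJ" if units == "kJ" else "MJ"
    rows: dict[str, dict[str, float]] = {}
    for diet_id, r in results.items():
        col = {
            "Body weight (kg)": r.bw_kg,
            "DM intake (kg/d)": r.dmi_kg_per_d,
            **{f"ATTD {nut} (%)": v for nut, v in sorted(r.attd.items())},
            "N intake (g/d)": r.n_balance["intake"],
            "N fecal (g/d)": r.n_balance["fecal"],
            "N urinary (g/d)": r.n_balance["urinary"],
            "N retention (g/d)": r.n_balance["retention"],
            "ME intake (kJ/kg BW^0.6/d)": r.me_intake_per_mbw,
            "THP (kJ/kg BW^0.6/d)": r.thp_per_mbw,
            "FHP (kJ/kg BW^0.6/d)": r.fhp_per_mbw,
            "RE_P (kJ/kg BW^0.6/d)": r.re_p_per_mbw,
            "RE_L (kJ/kg BW^0.6/d)": r.re_l_per_mbw,
            "Total RE (kJ/kg BW^0.6/d)": r.re_per_mbw,
            "RQ fed": r.rq_fed,
            "RQ fasted": r.rq_fasted,
            "Urinary energy (% of DE)": r.ratios["urinaryE_pct_of_DE"],
            "ME/DE (%)": r.ratios["me_de_pct"],
            "NE/ME (%)": r.ratios["ne_me_pct"],
            f"DE ({unit}/kg DM)": r.de_mj_per_kg_dm * scale,
            f"ME ({unit}/kg DM)": r.me_mj_per_kg_dm * scale,
            f"NE ({unit}/kg DM)": r.ne_mj_per_kg_dm * scale,
        }
        rows[diet_id] = col
    return pd.DataFrame(rows)


def _ingredient_table(results: Mapping[str, IngredientEnergyResult], units: str) -> pd.DataFrame:
    scale = 1000.0 if units == "kJ" else 1.0
    unit = "kJ" if units == "kJ" else "MJ"
    rows = {}
    for name, r in results.items():
        rows[name] = {
            f"GE measured ({unit}/kg DM)": r.ge_measured_mj_per_kg_dm * scale,
            f"GE raw ({unit}/kg DM)": r.ge_raw * scale,
            f"DE raw ({unit}/kg DM)": r.de_raw * scale,
            f"ME raw ({unit}/kg DM)": r.me_raw * scale,
            f"NE raw ({unit}/kg DM)": r.ne_raw * scale,
            "DE/GE (%)": r.de_ge_pct,
            "ME/DE (%)": r.me_de_pct,
            "NE/ME (%)": r.ne_me_pct,
            f"DE ({unit}/kg DM)": r.de_final * scale,
            f"ME ({unit}/kg DM)": r.me_final * scale,
            f"NE ({unit}/kg DM)": r.ne_final * scale,
        }
    return pd.DataFrame(rows)


def rank_equations(equations: Mapping[str, RegressionModel]) -> list[str]:
    """Family names ordered best-first: greatest R^2, least RMSE, least AIC."""
    return sorted(
        equations,
        key=lambda k: (-equations[k].r2, equations[k].rmse, equations[k].aic),
    )


def _simulation_panel(truth: TruthConfig, ingredient_results: Mapping[str, IngredientEnergyResult]) -> list[SamplePanelRow]:
    # panel rows for the regression stage: configured composition joined
    # with the pipeline-recovered energy values
    rows: list[SamplePanelRow] = []
    for name, res in ingredient_results.items():
        ing = truth.ingredients[name]
        comp = ing.composition
        try:
            rows.append(
                SamplePanelRow(
                    sample_id=name,
                    cp=comp.get("CP", 0.0),
                    ee=comp.get("EE", 0.0),
                    starch=comp.get("starch", 0.0),
                    ndf=comp.get("NDF", 0.0),
                    adf=comp.get("ADF", 0.0),
                    ash=100.0 - comp.get("OM", 100.0),
                    crude_fiber=comp.get("crude_fiber", 0.0),
                    ge=res.ge_measured_mj_per_kg_dm,
                    de=res.de_final,
                    me=res.me_final,
                    ne=res.ne_final,
                )
            )
        except ValueError:
            continue  # flagged/inconsistent sample stays out of the panel
    return rows


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all pipeline stages and (optionally) write the report bundle."""
    # --- inputs ------------------------------------------------------------
    truth = None
    if config.simulate or config.truth is not None:
        truth = config.truth or reference_study_config(noise=config.noise)
        experiment = generate_experiment(truth, seed=config.seed)
        records = experiment.records
        formulations = {
            d: t.formulation for d, t in experiment.diet_truths.items()
            if t.formulation.test_ingredient is not None
        }
        ge_measured = {
            t.formulation.test_ingredient: truth.ingredients[t.formulation.test_ingredient].ge
            for t in experiment.diet_truths.values()
            if t.formulation.test_ingredient is not None
        }
    else:
        records = read_pig_periods(config.periods_path, config.windows_path)
        formulations = dict(config.formulations or {})
        ge_measured = dict(config.ge_measured or {})

    # --- diet energy balance ----------------------------------------------
    by_diet: dict[str, list[PigPeriodRecord]] = {}
    for r in records:
        by_diet.setdefault(r.diet_id, []).append(r)
    diet_results = {
        diet_id: summarize_diet(
            recs,
            fhp_policy=config.fhp_policy,
            fixed_fhp_per_mbw=config.fixed_fhp_per_mbw,
        )
        for diet_id, recs in by_diet.items()
    }
    if config.basal_diet_id not in diet_results:
        raise ValueError(f"basal diet {config.basal_diet_id!r} not among diets {sorted(by_diet)}")
    basal = diet_results[config.basal_diet_id]
    basal_values = {
        "ge": basal.de_mj_per_kg_dm / (basal.attd["GE"] / 100.0),
        "de": basal.de_mj_per_kg_dm,
        "me": basal.me_mj_per_kg_dm,
        "ne": basal.ne_mj_per_kg_dm,
    }

    # --- ingredient values by difference ------------------------------------
    ingredient_results: dict[str, IngredientEnergyResult] = {}
    for diet_id, form in formulations.items():
        if diet_id == config.basal_diet_id or form.test_ingredient is None:
            continue
        r = diet_results[diet_id]
        test_values = {
            "ge": r.de_mj_per_kg_dm / (r.attd["GE"] / 100.0),
            "de": r.de_mj_per_kg_dm,
            "me": r.me_mj_per_kg_dm,
            "ne": r.ne_mj_per_kg_dm,
        }
        name = form.test_ingredient
        if name not in ge_measured:
            raise ValueError(f"no measured GE supplied for test ingredient {name!r}")
        ingredient_results[name] = ingredient_energy(
            ge_measured[name], basal_values, test_values, form, config.mixture_fraction
        )

    # --- panel correlations and prediction equations ------------------------
    if truth is not None:
        panel = _simulation_panel(truth, ingredient_results)
    else:
        panel = reference_panel()
    if config.panel_path is not None:
        panel = panel + read_panel(config.panel_path)
    correlation_r = correlation_p = None
    equations: dict[str, RegressionModel] = {}
    if len(panel) >= 4:
        try:
            correlation_r, correlation_p = pearson_matrix(panel)
        except ValueError:
            pass  # constant column in a degenerate panel
        equations = fit_equation_families(
            panel, alpha_enter=config.alpha_enter, alpha_stay=config.alpha_stay
        )

    diet_table = _diet_table(diet_results, config.units)
    ingredient_table = _ingredient_table(ingredient_results, config.units)
    log = {
        "swinecal_version": __version__,
        "seed": config.seed,
        "input": "simulate" if truth is not None else str(config.periods_path),
        "n_records": len(records),
        "fhp_policy": config.fhp_policy,
        "units": config.units,
        "alpha_enter": config.alpha_enter,
        "alpha_stay": config.alpha_stay,
        "equation_ranking": rank_equations(equations) if equations else [],
    }
    bundle = ReportBundle(
        diet_results=diet_results,
        ingredient_results=ingredient_results,
        diet_table=diet_table,
        ingredient_table=ingredient_table,
        correlation_r=correlation_r,
        correlation_p=correlation_p,
        equations=equations,
        panel=panel,
        log=log,
    )
    if config.outdir is not None:
        _write_bundle(bundle, Path(config.outdir), records)
    return bundle


def _equation_frame(equations: Mapping[str, RegressionModel]) -> pd.DataFrame:
    rows = []
    for family, m in equations.items():
        rows.append(
            {
                "family": family,
                "equation": m.equation(),
                "predictors": ",".join(m.predictors),
                "intercept": m.intercept,
                **{f"coef_{k}": v for k, v in m.coefficients.items()},
                "r2": m.r2,
                "rmse": m.rmse,
                "aic": m.aic,
                "p": m.overall_p,
                "n": m.n,
            }
        )
    return pd.DataFrame(rows)


def _write_bundle(bundle: ReportBundle, outdir: Path, records) -> None:
    # build everything first so a failure cannot leave partial outputs
    outdir.mkdir(parents=True, exist_ok=True)
    payload: dict[str, str] = {}
    payload["diet_balance.tsv"] = bundle.diet_table.to_csv(sep="\t", index_label="item")
    payload["ingredient_energy.tsv"] = bundle.ingredient_table.to_csv(sep="\t", index_label="item")
    if bundle.correlation_r is not None:
        payload["panel_correlations_r.tsv"] = bundle.correlation_r.to_csv(sep="\t", index_label="item")
        payload["panel_correlations_p.tsv"] = bundle.correlation_p.to_csv(sep="\t", index_label="item")
    if bundle.equations:
        payload["equations.tsv"] = _equation_frame(bundle.equations).to_csv(sep="\t", index=False)
    payload["run_log.json"] = json.dumps(bundle.log, indent=2, sort_keys=True) + "\n"
    for name, text in payload.items():
        (outdir / name).write_text(text)
    write_pig_periods(records, outdir / "pig_periods.tsv", outdir / "gas_windows.tsv")
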