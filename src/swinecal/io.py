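"""Delimiter-separated input/output for the chamber-experiment pipeline.

Two tables describe an experiment:

* ``pig_periods``: one row per pig x period with intakes, fecal/urinary
  outputs (energy and N) and per-nutrient intake/output masses;
* ``gas_windows``: one row per pig x day x window with state, duration and
  O2/CO2/CH4 volumes plus the urinary N attributable to the window.

Both are tab-separated text with a header; schemas are validated on read
and violations reported with the offending column (and row, where known).
The sample-panel table used by the prediction stage carries one row per
ingredient sample with composition and energy columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .calorimetry import GasExchangeWindow
from .energy_balance import NUTRIENTS, PigPeriodRecord
from .ne_prediction import COMPOSITION_COLUMNS, ENERGY_COLUMNS, SamplePanelRow

__all__ = [
    "SchemaError",
    "PIG_PERIOD_COLUMNS",
    "GAS_WINDOW_COLUMNS",
    "read_pig_periods",
    "write_pig_periods",
    "read_panel",
    "write_panel",
]


class SchemaError(ValueError):
    """An input table does not match its expected schema."""


_BASE_COLUMNS = (
    "pig_id",
    "diet_id",
    "period",
    "bw_kg",
    "dm_intake_kg_per_d",
    "ge_intake_kj_per_d",
    "fecal_energy_kj_per_d",
    "urinary_energy_kj_per_d",
    "ch4_l_per_d",
    "n_intake_g_per_d",
    "fecal_n_g_per_d",
    "urinary_n_g_per_d",
)

PIG_PERIOD_COLUMNS = _BASE_COLUMNS + tuple(
    f"{kind}_{nut.lower()}_g_per_d" for nut in NUTRIENTS for kind in ("intake", "fecal")
)

GAS_WINDOW_COLUMNS = (
    "pig_id",
    "diet_id",
    "period",
    "day",
    "state",
    "duration_h",
    "o2_l",
    "co2_l",
    "ch4_l",
    "urinary_n_g",
)

PANEL_COLUMNS = ("sample_id",) + COMPOSITION_COLUMNS + ENERGY_COLUMNS


def _check_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    _check_columns(df, required, path)
    return df


def read_pig_periods(
    periods_path: str | Path, windows_path: str | Path
) -> list[PigPeriodRecord]:
    """Assemble PigPeriodRecords from the two experiment tables."""
    periods = _read_tsv(periods_path, _BASE_COLUMNS)
    windows = _read_tsv(windows_path, GAS_WINDOW_COLUMNS)

    window_map: dict[tuple[str, int], list[GasExchangeWindow]] = {}
    fasted_map: dict[tuple[str, int], GasExchangeWindow] = {}
    for i, row in windows.iterrows():
        try:
            w = GasExchangeWindow(
                o2_l=float(row["o2_l"]),
                co2_l=float(row["co2_l"]),
                ch4_l=float(row["ch4_l"]),
                duration_h=float(row["duration_h"]),
                state=str(row["state"]),
                urinary_n_g=float(row["urinary_n_g"]),
            )
        except ValueError as exc:
            raise SchemaError(f"{windows_path} row {i}: {exc}") from exc
        key = (str(row["pig_id"]), int(row["period"]))
        if w.state == "fasted":
            fasted_map[key] = w
        else:
            window_map.setdefault(key, []).append(w)

    records: list[PigPeriodRecord] = []
    for i, row in periods.iterrows():
        key = (str(row["pig_id"]), int(row["period"]))
        nutrient_intakes: dict[str, float] = {}
        fecal_outputs: dict[str, float] = {}
        for nut in NUTRIENTS:
            icol, fcol = f"intake_{nut.lower()}_g_per_d", f"fecal_{nut.lower()}_g_per_d"
            if icol in periods.columns and pd.notna(row[icol]):
                nutrient_intakes[nut] = float(row[icol])
                fecal_outputs[nut] = float(row.get(fcol, 0.0))
        try:
            records.append(
                PigPeriodRecord(
                    pig_id=str(row["pig_id"]),
                    diet_id=str(row["diet_id"]),
                    period=int(row["period"]),
                    bw_kg=float(row["bw_kg"]),
                    dm_intake_kg_per_d=float(row["dm_intake_kg_per_d"]),
                    ge_intake_kj_per_d=float(row["ge_intake_kj_per_d"]),
                    fecal_energy_kj_per_d=float(row["fecal_energy_kj_per_d"]),
                    urinary_energy_kj_per_d=float(row["urinary_energy_kj_per_d"]),
                    ch4_l_per_d=float(row["ch4_l_per_d"]),
                    n_intake_g_per_d=float(row["n_intake_g_per_d"]),
                    fecal_n_g_per_d=float(row["fecal_n_g_per_d"]),
                    urinary_n_g_per_d=float(row["urinary_n_g_per_d"]),
                    nutrient_intakes=nutrient_intakes,
                    fecal_outputs=fecal_outputs,
                    fed_windows=tuple(window_map.get(key, ())),
                    fasted_window=fasted_map.get(key),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{periods_path} row {i}: {exc}") from exc
    return records


def write_pig_periods(
    records: Iterable[PigPeriodRecord],
    periods_path: str | Path,
    windows_path: str | Path,
) -> None:
    """Write records back to the two-table on-disk form (simulate -> analyze loop)."""
    period_rows = []
    window_rows = []
    for r in records:
        row = {
            "pig_id": r.pig_id,
            "diet_id": r.diet_id,
            "period": r.period,
            "bw_kg": r.bw_kg,
            "dm_intake_kg_per_d": r.dm_intake_kg_per_d,
            "ge_intake_kj_per_d": r.ge_intake_kj_per_d,
            "fecal_energy_kj_per_d": r.fecal_energy_kj_per_d,
            "urinary_energy_kj_per_d": r.urinary_energy_kj_per_d,
            "ch4_l_per_d": r.ch4_l_per_d,
            "n_intake_g_per_d": r.n_intake_g_per_d,
            "fecal_n_g_per_d": r.fecal_n_g_per_d,
            "urinary_n_g_per_d": r.urinary_n_g_per_d,
        }
        for nut in NUTRIENTS:
            if nut in r.nutrient_intakes:
                row[f"intake_{nut.lower()}_g_per_d"] = r.nutrient_intakes[nut]
                row[f"fecal_{nut.lower()}_g_per_d"] = r.fecal_outputs.get(nut, 0.0)
        period_rows.append(row)
        day = 0
        for w in list(r.fed_windows) + ([r.fasted_window] if r.fasted_window else []):
            day += 1
            window_rows.append(
                {
                    "pig_id": r.pig_id,
                    "diet_id": r.diet_id,
                    "period": r.period,
                    "day": day,
                    "state": w.state,
                    "duration_h": w.duration_h,
                    "o2_l": w.o2_l,
                    "co2_l": w.co2_l,
                    "ch4_l": w.ch4_l,
                    "urinary_n_g": w.urinary_n_g,
                }
            )
    pd.DataFrame(period_rows).to_csv(periods_path, sep="\t", index=False)
    pd.DataFrame(window_rows).to_csv(windows_path, sep="\t", index=False)


def read_panel(path: str | Path) -> list[SamplePanelRow]:
    """Read an ingredient sample panel (one row per sample)."""
    df = _read_tsv(path, PANEL_COLUMNS)
    rows = []
    for i, row in df.iterrows():
        try:
            rows.append(
                SamplePanelRow(
                    sample_id=str(row["sample_id"]),
                    **{c: float(row[c]) for c in COMPOSITION_COLUMNS + ENERGY_COLUMNS},
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from exc
    return rows


def write_panel(rows: Iterable[SamplePanelRow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": r.sample_id, **{c: getattr(r, c) for c in COMPOSITION_COLUMNS + ENERGY_COLUMNS}}
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)
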