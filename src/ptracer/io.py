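"""Readers and writers for the tidy CSV / YAML interchange formats.

Observations, seed budgets and titrations travel as tidy UTF-8 CSV with
ISO-8601 dates; labeling records, fertilizer specs and run configurations
as YAML. Writers emit full precision; display rounding belongs to report
formatting only.
"""

from __future__ import annotations

from dataclasses import asdict
from datetime import datetime
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .fertilizer import FertilizerSpec, Quantity
from .partitioning import LabelingEvent, PartitionTable, SeedBudget
from .respiration import TitrationRecord

__all__ = [
    "SchemaError",
    "read_observations",
    "write_observations",
    "read_seed_budgets",
    "write_seed_budgets",
    "read_titrations",
    "write_titrations",
    "read_labeling",
    "read_fertilizer_spec",
    "write_partition_tables",
]

OBS_COLUMNS = {
    "pot_id": "pot_id",
    "treatment": "treatment",
    "cut": "cut",
    "harvest_day": "harvest_day",
    "shoot_dm_g_kg": "shoot_dm",
    "shoot_p_mg_kg": "shoot_p",
    "activity_bq_kg": "shoot_activity",
    "count_date": "count_timestamp",
}

TITRATION_COLUMNS = [
    "jar_id", "treatment", "start_day", "end_day",
    "hcl_normality", "v_blank_ml", "v_sample_ml", "soil_dry_mass_kg",
]


class SchemaError(ValueError):
    """An input table violates the declared schema."""


def _require(df: pd.DataFrame, columns: Iterable[str], path: Path | str) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read a pot-observation CSV into the internal tidy frame."""
    df = pd.read_csv(path)
    _require(df, OBS_COLUMNS, path)
    df = df.rename(columns=OBS_COLUMNS)[list(OBS_COLUMNS.values())]
    df["count_timestamp"] = pd.to_datetime(df["count_timestamp"])
    for i, row in df.iterrows():
        for col in ("shoot_dm", "shoot_p", "shoot_activity"):
            if row[col] < 0:
                raise SchemaError(f"{path}: row {i + 2}: negative {col}")
        if row["cut"] < 1:
            raise SchemaError(f"{path}: row {i + 2}: cut must be >= 1")
    return df


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    inv = {v: k for k, v in OBS_COLUMNS.items()}
    out = df.rename(columns=inv)[list(OBS_COLUMNS.keys())].copy()
    out["count_date"] = pd.to_datetime(out["count_date"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)


def read_seed_budgets(path: str | Path) -> dict[str, SeedBudget]:
    """Read a seed-budget CSV (one row per treatment)."""
    df = pd.read_csv(path)
    cols = ["treatment", "sown_seed_p", "residual_seed_p", "shoot_p", "root_p", "collet_p"]
    _require(df, cols, path)
    return {
        str(r.treatment): SeedBudget(
            r.sown_seed_p, r.residual_seed_p, r.shoot_p, r.root_p, r.collet_p
        )
        for r in df.itertuples(index=False)
    }


def write_seed_budgets(budgets: dict[str, SeedBudget], path: str | Path) -> None:
    rows = [{"treatment": t, **asdict(b)} for t, b in budgets.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_titrations(path: str | Path) -> list[TitrationRecord]:
    df = pd.read_csv(path)
    _require(df, TITRATION_COLUMNS, path)
    return [
        TitrationRecord(
            jar_id=str(r.jar_id), treatment=str(r.treatment),
            start_day=r.start_day, end_day=r.end_day,
            hcl_normality=r.hcl_normality, v_blank=r.v_blank_ml,
            v_sample=r.v_sample_ml, soil_dry_mass=r.soil_dry_mass_kg,
        )
        for r in df.itertuples(index=False)
    ]


def write_titrations(records: list[TitrationRecord], path: str | Path) -> None:
    rows = [
        {
            "jar_id": r.jar_id, "treatment": r.treatment,
            "start_day": r.start_day, "end_day": r.end_day,
            "hcl_normality": r.hcl_normality, "v_blank_ml": r.v_blank,
            "v_sample_ml": r.v_sample, "soil_dry_mass_kg": r.soil_dry_mass,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labeling(path: str | Path) -> LabelingEvent:
    """Read a labeling record from YAML (activity_bq_per_kg, label_date, half_life_days)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        date = doc["label_date"]
        if not isinstance(date, datetime):
            date = pd.Timestamp(date).to_pydatetime()
        return LabelingEvent(
            introduced_activity_R=float(doc["activity_bq_per_kg"]),
            labeling_timestamp=date,
            half_life_days=float(doc.get("half_life_days", 14.276)),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: labeling record missing key {exc}") from exc


def read_fertilizer_spec(path: str | Path) -> FertilizerSpec:
    """Read a fertilizer composition sheet from YAML.

    Constituent keys carry a unit suffix: ``_g_kg``, ``_mg_kg`` or ``_pct``.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    constituents = {}
    for key, value in doc.get("constituents", {}).items():
        for suffix, unit in (("_g_kg", "g/kg"), ("_mg_kg", "mg/kg"), ("_pct", "pct")):
            if key.endswith(suffix):
                constituents[key.removesuffix(suffix)] = Quantity(float(value), unit)
                break
        else:
            raise SchemaError(
                f"{path}: constituent {key!r} has no unit suffix (_g_kg/_mg_kg/_pct)"
            )
    try:
        return FertilizerSpec(
            name=str(doc["name"]),
            total_p=float(doc["total_p_g_per_kg"]),
            constituents=constituents,
            dry_solid_fraction=doc.get("dry_solid_pct"),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: fertilizer spec missing key {exc}") from exc


def write_partition_tables(table: PartitionTable, outdir: str | Path) -> dict[str, Path]:
    """Write per-pot, cumulative and summary CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["per_pot"] = outdir / "partition_per_pot.csv"
    table.per_pot.to_csv(paths["per_pot"], index=False)
    if not table.per_pot_cumulative.empty:
        paths["cumulative"] = outdir / "partition_cumulative.csv"
        table.per_pot_cumulative.to_csv(paths["cumulative"], index=False)
    rows = []
    for m in table.treatment_means:
        eff = table.effectiveness.get(m.treatment)
        rows.append(
            {
                "treatment": m.treatment, "scope": m.scope, "Pt": m.Pt,
                "Pseed": m.Pseed, "Psoil": m.Psoil, "Pfert": m.Pfert,
                "r_over_R_pct": m.r_over_R, "SA": m.SA, "L": m.L,
                "Pdff_pct": m.Pdff, "CPU_pct": m.CPU,
                "AE_CPU_pct": eff.AE_CPU if eff else None,
                "AE_Pdff_pct": eff.AE_Pdff if eff else None,
                "flags": ";".join(m.flags),
            }
        )
    paths["summary"] = outdir / "partition_summary.csv"
    pd.DataFrame(rows).to_csv(paths["summary"], index=False)
    return paths
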