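"""Soil respiration from NaOH-trap back-titration records.

CO₂ respired in a closed jar is absorbed by an NaOH trap
(CO₂ + 2 NaOH → Na₂CO₃ + H₂O); the unconsumed alkali is back-titrated with
HCl to the phenolphthalein endpoint. The difference between blank and
sample titration volumes measures the trapped CO₂: each milliequivalent of
NaOH consumed corresponds to 6 mg of C (12 g C per 2 eq). Interval masses
divide into daily fluxes and accumulate into the respiration curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MG_C_PER_MEQ",
    "SIR_BIOMASS_FACTOR",
    "TitrationRecord",
    "RespirationSeries",
    "RespirationError",
    "c_from_titration",
    "daily_flux",
    "cumulative_respiration",
    "blank_corrected_frame",
    "respiration_series_from_records",
    "sir_biomass_estimate",
]

#: mg of carbon per milliequivalent of NaOH consumed by trapped CO₂.
MG_C_PER_MEQ = 6.0

#: Literature conversion factor from a substrate-induced CO₂-C flush to
#: microbial biomass C (a heuristic, not a measurement).
SIR_BIOMASS_FACTOR = 40.0


class RespirationError(ValueError):
    pass


@dataclass(frozen=True)
class TitrationRecord:
    """One jar × sampling-interval back-titration record.

    Volumes in mL of HCl at ``hcl_normality`` eq L⁻¹; ``soil_dry_mass`` in
    kg (None for blank jars).
    """

    jar_id: str
    treatment: str
    start_day: float
    end_day: float
    hcl_normality: float
    v_blank: float
    v_sample: float
    soil_dry_mass: float | None = 0.1

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise RespirationError("interval must have end_day > start_day")
        if self.v_blank < 0 or self.v_sample < 0:
            raise RespirationError("titration volumes must be >= 0")
        if self.soil_dry_mass is not None and self.soil_dry_mass <= 0:
            raise RespirationError("soil_dry_mass must be > 0")


@dataclass(frozen=True)
class RespirationSeries:
    """Daily fluxes and the cumulative respiration curve for one treatment."""

    treatment: str
    days: tuple[float, ...]              # interval end days
    interval_mass: tuple[float, ...]     # mg C-CO₂ kg⁻¹ per interval
    daily: tuple[float, ...]             # mg C-CO₂ kg⁻¹ day⁻¹
    cumulative: tuple[float, ...]        # running sum, mg C-CO₂ kg⁻¹

    @property
    def total(self) -> float:
        return self.cumulative[-1] if self.cumulative else 0.0


def c_from_titration(record: TitrationRecord) -> tuple[float, float | None]:
    """Trapped CO₂-C from one titration: (absolute mg C, mg C per kg soil).

    ``(v_blank − v_sample) × normality`` gives the meq of NaOH consumed;
    × 6 mg C per meq gives carbon. A sample volume above the blank yields a
    negative mass (flagged by callers, not clipped here). The per-kg value
    is None for blank jars.
    """
    meq = (record.v_blank - record.v_sample) * record.hcl_normality
    mg_c = meq * MG_C_PER_MEQ
    per_kg = mg_c / record.soil_dry_mass if record.soil_dry_mass else None
    return mg_c, per_kg


def daily_flux(mass_per_kg: float, interval_days: float) -> float:
    """Interval-averaged daily flux, mg C kg⁻¹ day⁻¹, assigned to the interval end."""
    if interval_days <= 0:
        raise RespirationError("interval must be > 0 days")
    return mass_per_kg / interval_days


def cumulative_respiration(
    interval_masses: Sequence[float],
    interval_bounds: Sequence[tuple[float, float]],
    treatment: str = "",
    exclude_negative: bool = True,
) -> RespirationSeries:
    """Build the daily-flux and cumulative series from ordered interval masses.

    Intervals must be contiguous and ordered. Negative interval masses
    (sample titration above blank) are excluded from the cumulative sum by
    default but kept in the daily series for QC.
    """
    if len(interval_masses) != len(interval_bounds):
        raise RespirationError("masses and bounds differ in length")
    prev_end = None
    for start, end in interval_bounds:
        if end <= start:
            raise RespirationError("interval must have end > start")
        if prev_end is not None and not np.isclose(start, prev_end):
            raise RespirationError(
                f"intervals not contiguous: gap/overlap at day {start}"
            )
        prev_end = end
    days = tuple(end for _, end in interval_bounds)
    daily = tuple(
        daily_flux(m, end - start)
        for m, (start, end) in zip(interval_masses, interval_bounds)
    )
    summed = 0.0
    cum = []
    for m in interval_masses:
        if m > 0 or not exclude_negative:
            summed += m
        cum.append(summed)
    return RespirationSeries(treatment, days, tuple(interval_masses), daily, tuple(cum))


def blank_corrected_frame(records: Iterable[TitrationRecord]) -> pd.DataFrame:
    """Tidy per-jar interval masses with per-kg values and QC flags."""
    rows = []
    for rec in records:
        mg_c, per_kg = c_from_titration(rec)
        rows.append(
            {
                "jar_id": rec.jar_id,
                "treatment": rec.treatment,
                "start_day": rec.start_day,
                "end_day": rec.end_day,
                "mg_c": mg_c,
                "mg_c_per_kg": per_kg,
                "flags": "negative-mass" if mg_c < 0 else "",
            }
        )
    return pd.DataFrame(rows)


def respiration_series_from_records(
    records: Iterable[TitrationRecord],
) -> dict[str, RespirationSeries]:
    """Per-treatment respiration series, averaging replicate jars per interval."""
    df = blank_corrected_frame(records)
    if df.empty:
        return {}
    out = {}
    for trt, grp in df.groupby("treatment"):
        means = (
            grp.groupby(["start_day", "end_day"], as_index=False)["mg_c_per_kg"].mean()
            .sort_values("start_day")
        )
        out[str(trt)] = cumulative_respiration(
            means["mg_c_per_kg"].tolist(),
            list(zip(means["start_day"], means["end_day"])),
            treatment=str(trt),
        )
    return out


def sir_biomass_estimate(flush_c_mg_per_kg: float) -> float:
    """Microbial biomass C from a substrate-induced respiration flush.

    Applies the literature conversion factor of 40 mg biomass-C per mg of
    flush CO₂-C; a heuristic scaling, not a direct measurement.
    """
    if flush_c_mg_per_kg < 0:
        raise RespirationError("flush C must be >= 0")
    return SIR_BIOMASS_FACTOR * flush_c_mg_per_kg
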