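"""Synthetic pot-experiment and incubation generators with known ground truth.

The pot generator emulates a soil-labeling tracer experiment: the
plant-available soil P pool carries the ³²P label, fertilizer- and
seed-derived P do not. Per treatment and cut it draws shoot P uptake as
the sum of seed-, soil- and fertilizer-derived components, attaches
radioactivity proportional to the soil-derived component through the soil
pool's specific-activity trajectory, applies multiplicative lognormal
noise to biomass and P (biological variation) plus additive Gaussian
counting error, and decays the activities forward to their count dates so
that a correct analysis must decay-correct them back.

An optional assumption-violation mode multiplies one treatment's soil-pool
specific activity (emulating, e.g., microbial immobilization altering the
labeled pool), producing a known, signed bias in the recovered partition:

    bias(Psoil_f) = (Pt0 − Pseed0) · r_f/r0 − Psoil_true
                  = Psoil_true · (m − 1)   for an SA multiplier m.

The incubation generator integrates a two-pool respiration model (an
exponentially decaying flush plus a basal rate) over the sampling schedule
and inverts the interval masses into NaOH-trap back-titration volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .partitioning import LabelingEvent, P32_HALF_LIFE_DAYS
from .respiration import MG_C_PER_MEQ, TitrationRecord

__all__ = [
    "TreatmentConfig",
    "SimulationConfig",
    "GroundTruth",
    "IncubationTreatment",
    "IncubationConfig",
    "SimulationError",
    "simulate_pot_experiment",
    "simulate_incubation",
    "degree_days",
    "default_pot_config",
    "default_incubation_config",
]

#: Default sampling schedule of the incubation (days after fertilization).
INCUBATION_SCHEDULE = (1, 2, 3, 5, 8, 10, 15, 23, 32, 42, 63)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TreatmentConfig:
    """True per-treatment uptake structure for the pot generator.

    ``soil_uptake`` is the true soil-derived shoot P per cut (mg P kg⁻¹);
    ``fert_fraction`` the true fraction of total shoot uptake derived from
    the fertilizer per cut (Pdff/100); ``seed_shoot_p`` the seed P
    allocated to shoots at the first cut. ``sa_multiplier`` perturbs this
    treatment's soil-pool specific activity away from the control's
    (1.0 = the equal-SA assumption holds).
    """

    dose: float  # mg P kg⁻¹ soil, 0 for the control
    soil_uptake: tuple[float, ...]
    fert_fraction: tuple[float, ...]
    seed_shoot_p: float
    shoot_dm: tuple[float, ...] = ()  # g kg⁻¹ per cut; derived if empty
    sa_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if len(self.soil_uptake) != len(self.fert_fraction):
            raise SimulationError("soil_uptake and fert_fraction lengths differ")
        for f in self.fert_fraction:
            if not (0 <= f < 1):
                raise SimulationError("fert_fraction must lie in [0, 1)")
        if self.dose == 0 and any(f > 0 for f in self.fert_fraction):
            raise SimulationError("unfertilized treatment cannot derive P from fertilizer")


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of a synthetic labeled pot experiment."""

    treatments: Mapping[str, TreatmentConfig]
    introduced_activity_R: float = 3.7e6  # Bq kg⁻¹ soil
    #: soil-pool specific activity per cut, percent of R per mg P kg⁻¹
    soil_sa_trajectory: tuple[float, ...] = (3.2, 2.9, 2.6)
    cut_days: tuple[int, ...] = (27, 38, 59)
    n_replicates: int = 5
    cv_dm: float = 0.10
    cv_p: float = 0.10
    cv_count: float = 0.05
    seed: int | None = None
    labeling_date: datetime = datetime(2008, 4, 1, 12, 0)
    count_delay_days: float = 2.0
    half_life_days: float = P32_HALF_LIFE_DAYS

    def __post_init__(self) -> None:
        if len(self.cut_days) != len(self.soil_sa_trajectory):
            raise SimulationError("cut_days and soil_sa_trajectory lengths differ")
        for cv in (self.cv_dm, self.cv_p, self.cv_count):
            if cv < 0:
                raise SimulationError("CVs must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True per-treatment partition, per cut and cumulative."""

    per_cut: pd.DataFrame      # treatment, cut, Pt, Pseed, Psoil, Pfert, Pdff
    cumulative: pd.DataFrame   # treatment, Pt, Pseed, Psoil, Pfert, Pdff, CPU

    def truth(self, treatment: str, column: str) -> float:
        row = self.cumulative.loc[self.cumulative["treatment"] == treatment]
        return float(row[column].iloc[0])


def _treatment_truth(name: str, cfg: TreatmentConfig) -> pd.DataFrame:
    rows = []
    for c, (soil, f) in enumerate(zip(cfg.soil_uptake, cfg.fert_fraction), start=1):
        seed = cfg.seed_shoot_p if c == 1 else 0.0
        # fert fraction f of the total: Pt = (soil + seed) / (1 - f)
        pt = (soil + seed) / (1.0 - f)
        fert = pt * f
        rows.append(
            {"treatment": name, "cut": c, "Pt": pt, "Pseed": seed,
             "Psoil": soil, "Pfert": fert, "Pdff": 100.0 * f}
        )
    return pd.DataFrame(rows)


def simulate_pot_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, float], GroundTruth, LabelingEvent]:
    """Generate a labeled pot experiment.

    Returns ``(observations, seed_budgets, ground_truth, labeling)``:
    a tidy pot × cut observation table, the per-treatment seed P allocated
    to shoots, the true partition, and the labeling record needed to
    analyse the observations.
    """
    if config.seed is None:
        raise SimulationError("a seed is mandatory: refusing to run unseeded")
    rng = np.random.default_rng(config.seed)

    truth_cut = pd.concat(
        [_treatment_truth(n, c) for n, c in config.treatments.items()],
        ignore_index=True,
    )
    cum = truth_cut.groupby("treatment", as_index=False)[
        ["Pt", "Pseed", "Psoil", "Pfert"]
    ].sum()
    cum["Pdff"] = 100.0 * cum["Pfert"] / cum["Pt"]
    cum["CPU"] = [
        100.0 * pf / config.treatments[t].dose if config.treatments[t].dose > 0 else np.nan
        for pf, t in zip(cum["Pfert"], cum["treatment"])
    ]
    truth = GroundTruth(truth_cut, cum)

    def lognorm(mean: float, cv: float, size: int) -> np.ndarray:
        if cv == 0 or mean == 0:
            return np.full(size, mean)
        sigma = np.sqrt(np.log1p(cv**2))
        return mean * rng.lognormal(-(sigma**2) / 2.0, sigma, size)

    rows = []
    for name, cfg in config.treatments.items():
        tt = truth_cut[truth_cut["treatment"] == name].set_index("cut")
        for c, day in enumerate(config.cut_days, start=1):
            t = tt.loc[c]
            sa = config.soil_sa_trajectory[c - 1] * cfg.sa_multiplier
            dm_mean = (
                cfg.shoot_dm[c - 1]
                if cfg.shoot_dm
                else t["Pt"] / 3.5  # ~3.5 mg P per g shoot DM
            )
            n = config.n_replicates
            # one multiplicative draw per pot scales all P pools together
            # (pot-level vigor), so the per-pot fertilizer fraction is exact
            growth = lognorm(1.0, config.cv_p, n)
            seed_p = t["Pseed"] * growth
            soil_p = t["Psoil"] * growth
            fert_p = t["Pfert"] * growth
            shoot_p = seed_p + soil_p + fert_p
            dm = lognorm(dm_mean, config.cv_dm, n)
            # only soil-derived P carries the label
            r_pct_true = sa * soil_p  # percent of R at labeling time
            activity_label = r_pct_true / 100.0 * config.introduced_activity_R
            count_day = day + config.count_delay_days
            decay = 2.0 ** (-count_day / config.half_life_days)
            activity_raw = activity_label * decay
            if config.cv_count > 0:
                activity_raw = activity_raw + rng.normal(
                    0.0, config.cv_count * activity_raw, n
                )
            activity_raw = np.clip(activity_raw, 0.0, None)
            count_ts = config.labeling_date + timedelta(days=float(count_day))
            for i in range(n):
                rows.append(
                    {
                        "pot_id": f"{name}-{i + 1}",
                        "treatment": name,
                        "cut": c,
                        "harvest_day": day,
                        "shoot_dm": dm[i],
                        "shoot_p": shoot_p[i],
                        "shoot_activity": activity_raw[i],
                        "count_timestamp": count_ts,
                    }
                )
    obs = pd.DataFrame(rows)
    # conservation sanity: no pot (1 kg soil basis) holds more label than
    # was introduced per kg, even before decay correction
    per_pot_label = obs.groupby("pot_id")["shoot_activity"].sum()
    if (per_pot_label > config.introduced_activity_R).any():
        raise SimulationError("simulated plant activity exceeds introduced R")

    seed_budgets = {n: c.seed_shoot_p for n, c in config.treatments.items()}
    labeling = LabelingEvent(
        config.introduced_activity_R, config.labeling_date, config.half_life_days
    )
    return obs, seed_budgets, truth, labeling


def default_pot_config(seed: int, **overrides) -> SimulationConfig:
    """A pot-experiment configuration with magnitudes typical of a labeled
    3-treatment grass trial: cumulative shoot uptake ≈ 4.6 / 19.7 / 12.5
    mg P kg⁻¹ for control / TSP / TCSS, fertilizer fractions ≈ 0.55 / 0.56,
    dose 50 mg P kg⁻¹, five replicates, cuts at 27/38/59 days."""
    treatments = {
        "control": TreatmentConfig(
            dose=0.0,
            soil_uptake=(0.44, 1.54, 2.00),
            fert_fraction=(0.0, 0.0, 0.0),
            seed_shoot_p=0.62,
            shoot_dm=(0.5, 1.0, 1.4),
        ),
        "TSP": TreatmentConfig(
            dose=50.0,
            soil_uptake=(1.91, 2.90, 3.10),
            fert_fraction=(0.42, 0.58, 0.61),
            seed_shoot_p=0.89,
            shoot_dm=(1.2, 1.9, 2.2),
        ),
        "TCSS": TreatmentConfig(
            dose=50.0,
            soil_uptake=(1.13, 1.80, 2.00),
            fert_fraction=(0.38, 0.59, 0.63),
            seed_shoot_p=0.67,
            shoot_dm=(0.8, 1.4, 1.6),
        ),
    }
    kw = dict(treatments=treatments, seed=seed)
    kw.update(overrides)
    return SimulationConfig(**kw)


# ---------------------------------------------------------------------------
# Incubation generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IncubationTreatment:
    """Two-pool respiration model: flux(t) = basal + amplitude·exp(−k·t)."""

    basal: float       # mg C kg⁻¹ day⁻¹
    amplitude: float   # mg C kg⁻¹ day⁻¹ at t = 0
    k: float           # day⁻¹

    def interval_mass(self, start: float, end: float) -> float:
        """∫ flux dt over [start, end], mg C kg⁻¹ (closed form)."""
        flush = (
            self.amplitude / self.k * (np.exp(-self.k * start) - np.exp(-self.k * end))
            if self.k > 0
            else self.amplitude * (end - start)
        )
        return self.basal * (end - start) + flush


@dataclass(frozen=True)
class IncubationConfig:
    treatments: Mapping[str, IncubationTreatment]
    schedule: tuple[float, ...] = INCUBATION_SCHEDULE
    n_replicates: int = 3
    soil_dry_mass: float = 0.1      # kg per jar
    naoh_ml: float = 5.0
    naoh_molarity: float = 0.5      # M (eq L⁻¹ for NaOH)
    hcl_normality: float = 0.1      # eq L⁻¹
    cv_titration: float = 0.0       # relative noise on consumed meq
    seed: int | None = None


def simulate_incubation(config: IncubationConfig) -> list[TitrationRecord]:
    """Generate jar-level back-titration records from the two-pool model.

    The trapped-CO₂ meq per interval are inverted into HCl volumes against
    the blank (full-trap) volume. Raises if an interval's CO₂ would exceed
    the trap capacity.
    """
    if config.seed is None:
        raise SimulationError("a seed is mandatory: refusing to run unseeded")
    rng = np.random.default_rng(config.seed)
    trap_meq = config.naoh_ml * config.naoh_molarity
    v_blank = trap_meq / config.hcl_normality  # mL to titrate an untouched trap
    bounds = list(zip((0.0,) + tuple(config.schedule[:-1]), config.schedule))
    records: list[TitrationRecord] = []
    for name, model in config.treatments.items():
        for rep in range(1, config.n_replicates + 1):
            for start, end in bounds:
                mass_per_kg = model.interval_mass(start, end)
                if config.cv_titration > 0:
                    mass_per_kg *= rng.lognormal(
                        0.0, np.sqrt(np.log1p(config.cv_titration**2))
                    )
                meq = mass_per_kg * config.soil_dry_mass / MG_C_PER_MEQ
                if meq > trap_meq:
                    raise SimulationError(
                        f"trap saturation: {name} interval {start}-{end} d needs "
                        f"{meq:.2f} meq > {trap_meq:.2f} meq capacity"
                    )
                records.append(
                    TitrationRecord(
                        jar_id=f"{name}-{rep}",
                        treatment=name,
                        start_day=start,
                        end_day=end,
                        hcl_normality=config.hcl_normality,
                        v_blank=v_blank,
                        v_sample=v_blank - meq / config.hcl_normality,
                        soil_dry_mass=config.soil_dry_mass,
                    )
                )
    return records


def default_incubation_config(seed: int, **overrides) -> IncubationConfig:
    """Incubation defaults for a fertilized-soil trial: an early flush in
    the 49–61 mg C kg⁻¹ d⁻¹ range for the organic amendment decaying to a
    basal rate, 63-day cumulative respiration within 214–255 mg C kg⁻¹."""
    treatments = {
        "control": IncubationTreatment(basal=1.5, amplitude=55.0, k=0.5),
        "TSP": IncubationTreatment(basal=1.6, amplitude=60.0, k=0.5),
        "TCSS": IncubationTreatment(basal=1.8, amplitude=65.0, k=0.5),
    }
    kw = dict(treatments=treatments, seed=seed)
    kw.update(overrides)
    return IncubationConfig(**kw)


def degree_days(daily_mean_temps: Sequence[float], base: float = 0.0) -> float:
    """Cumulated degree days: sum of max(0, T − base) over days."""
    t = np.asarray(daily_mean_temps, dtype=float)
    return float(np.clip(t - base, 0.0, None).sum())
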