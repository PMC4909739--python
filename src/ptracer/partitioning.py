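"""Isotope-dilution partitioning of shoot P uptake into seed, soil and fertilizer sources.

The accounting implemented here is the classical indirect (soil-labeling)
radiotracer method: the plant-available soil P pool is labeled with
carrier-free ³²P before fertilization, so P taken up from the soil pool
carries the label while fertilizer-derived and seed-derived P do not.
Assuming the specific activity of soil-derived P in the plant is the same
in fertilized and unfertilized treatments, the soil-derived uptake of a
fertilized treatment follows from the ratio of tracer recoveries, and the
fertilizer-derived uptake is obtained by difference:

    Pt      = Pseed + Psoil + Pfert          (mass balance, per treatment)
    IC0     = r0 / (Pt0 - Pseed0)            (control isotopic composition)
    Psoil_f = (Pt0 - Pseed0) * r_f / r0
    Pfert_f = Pt_f - Pseed_f - Psoil_f
    Pdff    = 100 * Pfert / Pt               (% of uptake derived from fertilizer)
    CPU     = 100 * Pfert / dose             (% fertilizer P recovery)
    L       = Pt / (r/R)                     (plant-available soil P estimate)
    SA      = (r/R) / Pt                     (specific activity, fraction of R per mg P)

All P quantities are mg P per kg soil; radioactivity is carried as percent
of the introduced activity R after decay correction to the labeling date.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "P32_HALF_LIFE_DAYS",
    "LabelingEvent",
    "PotObservation",
    "SeedBudget",
    "PartitionResult",
    "EffectivenessResult",
    "PartitionTable",
    "PartitioningError",
    "decay_correct",
    "fraction_recovered",
    "specific_activity",
    "l_value",
    "seed_p_allocated",
    "ic0",
    "psoil_from_tracer",
    "pfert_residual",
    "pdff",
    "cpu",
    "agronomic_effectiveness",
    "cumulate_cuts",
    "partition_experiment",
]

#: Physical half-life of ³²P in days.
P32_HALF_LIFE_DAYS = 14.276


class PartitioningError(ValueError):
    """Raised when the tracer algebra is undefined for the given inputs."""


@dataclass(frozen=True)
class LabelingEvent:
    """Introduction of carrier-free ³²P into the soil.

    Parameters
    ----------
    introduced_activity_R
        Activity introduced per kg of soil (Bq kg⁻¹), e.g. 3.7e6 for
        3.7 MBq kg⁻¹.
    labeling_timestamp
        Calendar date-time of labeling; the reference time to which all
        measured activities are decay-corrected.
    half_life_days
        Tracer half-life (days); defaults to the ³²P value.
    """

    introduced_activity_R: float
    labeling_timestamp: datetime
    half_life_days: float = P32_HALF_LIFE_DAYS

    def __post_init__(self) -> None:
        if self.introduced_activity_R <= 0:
            raise PartitioningError("introduced_activity_R must be > 0")
        if self.half_life_days <= 0:
            raise PartitioningError("half_life_days must be > 0")


@dataclass(frozen=True)
class PotObservation:
    """One pot × cut record of dry matter, P uptake and radioactivity.

    ``shoot_dm`` in g kg⁻¹ soil, ``shoot_p`` in mg P kg⁻¹ soil,
    ``shoot_activity`` in Bq kg⁻¹ soil as counted at ``count_timestamp``
    (i.e. not yet decay-corrected).
    """

    pot_id: str
    treatment: str
    cut_index: int
    harvest_day: float
    shoot_dm: float
    shoot_p: float
    shoot_activity: float
    count_timestamp: datetime
    root_p: float | None = None
    collet_p: float | None = None
    residual_seed_p: float | None = None

    def __post_init__(self) -> None:
        if self.cut_index < 1:
            raise PartitioningError("cut_index must be >= 1")
        for name in ("shoot_dm", "shoot_p", "shoot_activity"):
            if getattr(self, name) < 0:
                raise PartitioningError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SeedBudget:
    """Whole-plant seed-P budget used to allocate seed-derived P to shoots.

    All quantities in mg P kg⁻¹ soil. ``sown_seed_p`` is the P content of
    the sown seeds, ``residual_seed_p`` what remains in seeds at harvest;
    the difference is the seed P remobilized into the plant, of which the
    shoot receives its share of whole-plant P uptake.
    """

    sown_seed_p: float
    residual_seed_p: float
    shoot_p: float
    root_p: float
    collet_p: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.residual_seed_p):
            raise PartitioningError("residual_seed_p must be >= 0")
        if self.residual_seed_p > self.sown_seed_p:
            raise PartitioningError(
                "residual seed P exceeds sown seed P (data inconsistency)"
            )


@dataclass
class PartitionResult:
    """Source partition of shoot P uptake for one treatment (one cut or cumulative)."""

    treatment: str
    scope: str  # "cut:<k>" or "cumulative"
    Pt: float
    Pseed: float
    Psoil: float
    Pfert: float
    r_over_R: float  # percent of introduced R
    SA: float | None = None
    L: float | None = None
    Pdff: float | None = None
    CPU: float | None = None
    flags: list[str] = field(default_factory=list)

    def mass_balance_residual(self) -> float:
        return self.Pt - (self.Pseed + self.Psoil + self.Pfert)


@dataclass(frozen=True)
class EffectivenessResult:
    """Agronomic effectiveness of a test fertilizer relative to a reference."""

    AE_CPU: float
    AE_Pdff: float
    reference_treatment: str


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def decay_correct(activity: float, elapsed_days: float, half_life_days: float = P32_HALF_LIFE_DAYS) -> float:
    """Correct an activity for radioactive decay over ``elapsed_days``.

    Returns the activity at the reference time ``elapsed_days`` *before*
    the measurement: ``activity * 2**(elapsed/half_life)``. A negative
    ``elapsed_days`` back-corrects (the exact inverse), so the round trip
    is the identity.
    """
    if half_life_days <= 0:
        raise PartitioningError("half_life_days must be > 0")
    return activity * 2.0 ** (elapsed_days / half_life_days)


def fraction_recovered(shoot_activity_corrected: float, R: float) -> float:
    """Percent of the introduced radioactivity recovered in shoots (r/R, %)."""
    if R <= 0:
        raise PartitioningError("introduced activity R must be > 0")
    if shoot_activity_corrected < 0:
        raise PartitioningError("activity must be >= 0")
    return 100.0 * shoot_activity_corrected / R


def specific_activity(r_over_R: float, shoot_p: float) -> float:
    """Specific activity SA = (r/R as a fraction) / shoot P uptake.

    Units: fraction of R per mg P kg⁻¹ soil.
    """
    if shoot_p <= 0:
        raise PartitioningError("SA undefined for shoot_p <= 0")
    return (r_over_R / 100.0) / shoot_p


def l_value(shoot_p: float, r_over_R: float) -> float:
    """Isotope-dilution L-value: plant-available soil P, mg P kg⁻¹ soil.

    ``L = Pt / (r/R)``; the reciprocal of the specific activity.
    """
    if r_over_R <= 0:
        raise PartitioningError("L-value undefined for r/R <= 0")
    return shoot_p / (r_over_R / 100.0)


def seed_p_allocated(budget: SeedBudget) -> float:
    """Seed-derived P allocated to shoots (mg P kg⁻¹ soil).

    Seed P remobilized into the plant (sown minus residual) multiplied by
    the shoot share of whole-plant P uptake (shoots + roots + collets).
    """
    total = budget.shoot_p + budget.root_p + budget.collet_p
    if total <= 0:
        raise PartitioningError("whole-plant P uptake must be > 0 for allocation")
    depleted = budget.sown_seed_p - budget.residual_seed_p
    return depleted * budget.shoot_p / total


def ic0(r0: float, Pt0: float, Pseed0: float) -> float:
    """Isotopic composition of soil-derived P in the control shoots.

    ``IC0 = r0 / (Pt0 - Pseed0)`` in percent of R per mg P kg⁻¹. Under the
    equal-specific-activity assumption this equals the isotopic composition
    of soil-derived P in every treatment.
    """
    if Pt0 <= Pseed0:
        raise PartitioningError(
            "degenerate control: Pt0 must exceed Pseed0 for IC0"
        )
    return r0 / (Pt0 - Pseed0)


def psoil_from_tracer(Pt0: float, Pseed0: float, r_f: float, r0: float) -> float:
    """Soil-derived shoot P of a fertilized treatment, mg P kg⁻¹ soil.

    ``Psoil_f = (Pt0 - Pseed0) * r_f / r0``: the control's soil-derived
    uptake scaled by the ratio of tracer recoveries.
    """
    if r0 <= 0:
        raise PartitioningError("partition undefined for control recovery r0 <= 0")
    return (Pt0 - Pseed0) * r_f / r0


def pfert_residual(Pt: float, Pseed: float, Psoil: float) -> float:
    """Fertilizer-derived shoot P by difference: ``Pt - Pseed - Psoil``.

    May be negative under measurement noise; callers flag rather than clip.
    """
    return Pt - Pseed - Psoil


def pdff(Pfert: float, Pt: float) -> float:
    """Percent of shoot P uptake derived from the fertilizer."""
    if Pt <= 0:
        raise PartitioningError("Pdff undefined for Pt <= 0")
    return 100.0 * Pfert / Pt


def cpu(Pfert: float, applied_dose: float) -> float:
    """Coefficient of fertilizer P utilization: percent of the dose recovered in shoots."""
    if applied_dose <= 0:
        raise PartitioningError("CPU undefined for dose <= 0")
    return 100.0 * Pfert / applied_dose


def agronomic_effectiveness(test: PartitionResult, reference: PartitionResult) -> EffectivenessResult:
    """Agronomic effectiveness of ``test`` relative to ``reference`` (both %, ref = 100).

    AE_CPU compares fertilizer-derived uptake (equivalently CPU at equal
    dose); AE_Pdff compares the fertilizer contributions to plant nutrition.
    """
    if reference.Pfert is None or reference.Pfert <= 0:
        raise PartitioningError("AE undefined: reference Pfert must be > 0")
    if reference.Pdff is None or reference.Pdff <= 0:
        raise PartitioningError("AE undefined: reference Pdff must be > 0")
    if test.Pdff is None:
        raise PartitioningError("AE undefined: test treatment has no Pdff")
    return EffectivenessResult(
        AE_CPU=100.0 * test.Pfert / reference.Pfert,
        AE_Pdff=100.0 * test.Pdff / reference.Pdff,
        reference_treatment=reference.treatment,
    )


def _derive_ratios(res: PartitionResult, dose: float | None) -> PartitionResult:
    """Fill SA, L, Pdff, CPU from the additive fields; flag degenerate cases."""
    if res.Pt > 0:
        res.SA = specific_activity(res.r_over_R, res.Pt)
        res.Pdff = pdff(res.Pfert, res.Pt)
    else:
        res.flags.append("zero-Pt")
    if res.r_over_R > 0:
        res.L = l_value(res.Pt, res.r_over_R)
    else:
        res.flags.append("zero-recovery")
    if dose is not None and dose > 0:
        res.CPU = cpu(res.Pfert, dose)
    if res.Pfert < 0:
        res.flags.append("negative-Pfert")
    if res.Psoil < 0:
        res.flags.append("negative-Psoil")
    return res


def cumulate_cuts(per_cut: Sequence[PartitionResult], dose: float | None = None) -> PartitionResult:
    """Cumulate per-cut partitions of one treatment over the growth cycles.

    Additive quantities (Pt, Pseed, Psoil, Pfert, r/R) are summed; ratio
    quantities (Pdff, CPU, SA, L) are recomputed from the cumulated sums.
    """
    if not per_cut:
        raise PartitioningError("cannot cumulate an empty sequence of cuts")
    treatments = {r.treatment for r in per_cut}
    if len(treatments) > 1:
        raise PartitioningError(f"mixed treatments in cumulation: {sorted(treatments)}")
    out = PartitionResult(
        treatment=per_cut[0].treatment,
        scope="cumulative",
        Pt=sum(r.Pt for r in per_cut),
        Pseed=sum(r.Pseed for r in per_cut),
        Psoil=sum(r.Psoil for r in per_cut),
        Pfert=sum(r.Pfert for r in per_cut),
        r_over_R=sum(r.r_over_R for r in per_cut),
        flags=sorted({f for r in per_cut for f in r.flags}),
    )
    return _derive_ratios(out, dose)


# ---------------------------------------------------------------------------
# Experiment-level orchestration
# ---------------------------------------------------------------------------

def _obs_to_frame(observations: Iterable[PotObservation] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations.copy()
    rows = [
        {
            "pot_id": o.pot_id,
            "treatment": o.treatment,
            "cut": o.cut_index,
            "harvest_day": o.harvest_day,
            "shoot_dm": o.shoot_dm,
            "shoot_p": o.shoot_p,
            "shoot_activity": o.shoot_activity,
            "count_timestamp": o.count_timestamp,
        }
        for o in observations
    ]
    return pd.DataFrame(rows)


@dataclass
class PartitionTable:
    """Full output of :func:`partition_experiment`.

    ``per_pot`` has one row per pot × cut, ``per_pot_cumulative`` one row
    per pot, ``treatment_means`` one row per treatment (cumulative means
    across replicates with SE), ``effectiveness`` the AE of each fertilized
    treatment against the reference.
    """

    per_pot: pd.DataFrame
    per_pot_cumulative: pd.DataFrame
    treatment_means: list[PartitionResult]
    effectiveness: dict[str, EffectivenessResult]
    flags: list[str]


def partition_experiment(
    observations: Iterable[PotObservation] | pd.DataFrame,
    seed_budgets: Mapping[str, SeedBudget | float],
    labeling: LabelingEvent,
    doses: Mapping[str, float],
    control: str = "control",
    reference: str | None = "TSP",
    mode: str = "per_cut",
) -> PartitionTable:
    """Partition shoot P uptake of a whole pot experiment into its sources.

    Parameters
    ----------
    observations
        Pot × cut records (:class:`PotObservation` iterable or a tidy
        DataFrame with columns pot_id, treatment, cut, harvest_day,
        shoot_dm, shoot_p, shoot_activity, count_timestamp).
    seed_budgets
        Per-treatment seed-P budget (:class:`SeedBudget`) or directly the
        allocated shoot seed-P in mg kg⁻¹; applied to the first cut only
        (seed remobilization is negligible from the second cut on).
    labeling
        The soil-labeling event (R, date, half-life) for decay correction.
    doses
        Applied P per treatment, mg P kg⁻¹ soil (0 for the control).
    control
        Name of the unfertilized treatment carrying the reference isotopic
        composition.
    reference
        Reference fertilizer for agronomic effectiveness (None disables AE).
    mode
        ``"per_cut"`` (default): partition each pot at each cut against the
        control means of that cut, then cumulate per pot — the arithmetic a
        replicated experiment calls for. ``"aggregate"``: evaluate the
        partition once per treatment on cumulative treatment means; a
        diagnostic/teaching mode that discards replicate structure.
    """
    df = _obs_to_frame(observations)
    required = {"pot_id", "treatment", "cut", "shoot_p", "shoot_activity"}
    missing = required - set(df.columns)
    if missing:
        raise PartitioningError(f"observations missing columns: {sorted(missing)}")
    if control not in set(df["treatment"]):
        raise PartitioningError(
            f"cannot partition: control treatment {control!r} absent from data"
        )
    if mode not in ("per_cut", "aggregate"):
        raise PartitioningError(f"unknown mode {mode!r}")

    # Decay-correct activities to the labeling date and express as % of R.
    if "count_timestamp" in df.columns:
        elapsed = (
            pd.to_datetime(df["count_timestamp"]) - pd.Timestamp(labeling.labeling_timestamp)
        ).dt.total_seconds() / 86400.0
    else:  # already corrected upstream
        elapsed = pd.Series(0.0, index=df.index)
    corrected = decay_correct(
        df["shoot_activity"].to_numpy(float),
        elapsed.to_numpy(float),
        labeling.half_life_days,
    )
    df["r_pct"] = 100.0 * corrected / labeling.introduced_activity_R

    def seed_alloc(treatment: str, cut: int) -> float:
        if cut >= 2:
            return 0.0
        b = seed_budgets.get(treatment, 0.0)
        if isinstance(b, SeedBudget):
            return seed_p_allocated(b)
        return float(b)

    df["Pseed"] = [seed_alloc(t, c) for t, c in zip(df["treatment"], df["cut"])]

    flags: list[str] = []

    if mode == "aggregate":
        per_pot = df.copy()
        agg = (
            df.groupby("treatment")
            .agg(Pt=("shoot_p", "sum"), r_pct=("r_pct", "sum"), Pseed=("Pseed", "sum"), n=("pot_id", "nunique"))
        )
        # cumulative treatment means across replicates
        agg[["Pt", "r_pct", "Pseed"]] = agg[["Pt", "r_pct", "Pseed"]].div(agg["n"], axis=0)
        Pt0, r0, Pseed0 = agg.loc[control, ["Pt", "r_pct", "Pseed"]]
        means: list[PartitionResult] = []
        for trt, row in agg.iterrows():
            if trt == control:
                psoil = row["Pt"] - row["Pseed"]
                pfert = 0.0
            else:
                psoil = psoil_from_tracer(Pt0, Pseed0, row["r_pct"], r0)
                pfert = pfert_residual(row["Pt"], row["Pseed"], psoil)
            res = PartitionResult(
                treatment=str(trt), scope="cumulative", Pt=row["Pt"], Pseed=row["Pseed"],
                Psoil=psoil, Pfert=pfert, r_over_R=row["r_pct"],
            )
            dose = doses.get(str(trt), 0.0)
            means.append(_derive_ratios(res, dose if dose > 0 else None))
        eff = _effectiveness(means, reference, control)
        for m in means:
            flags.extend(f"{m.treatment}: {f}" for f in m.flags)
        return PartitionTable(per_pot, pd.DataFrame(), means, eff, flags)

    # --- per-cut mode -------------------------------------------------------
    ctl = df[df["treatment"] == control]
    ctl_means = ctl.groupby("cut").agg(
        Pt0=("shoot_p", "mean"), r0=("r_pct", "mean"), Pseed0=("Pseed", "mean")
    )
    for cut, row in ctl_means.iterrows():
        if row["r0"] <= 0:
            raise PartitioningError(f"control tracer recovery is zero at cut {cut}")

    rows = []
    for rec in df.itertuples(index=False):
        cut = rec.cut
        if cut not in ctl_means.index:
            raise PartitioningError(f"no control observations for cut {cut}")
        Pt0, r0, Pseed0 = ctl_means.loc[cut, ["Pt0", "r0", "Pseed0"]]
        if rec.treatment == control:
            psoil = rec.shoot_p - rec.Pseed
            pfert = 0.0
        else:
            psoil = psoil_from_tracer(Pt0, Pseed0, rec.r_pct, r0)
            pfert = pfert_residual(rec.shoot_p, rec.Pseed, psoil)
        row_flags = []
        if pfert < 0:
            row_flags.append("negative-Pfert")
        if psoil < 0:
            row_flags.append("negative-Psoil")
        rows.append(
            {
                "pot_id": rec.pot_id, "treatment": rec.treatment, "cut": cut,
                "Pt": rec.shoot_p, "Pseed": rec.Pseed, "Psoil": psoil,
                "Pfert": pfert, "r_pct": rec.r_pct, "flags": ";".join(row_flags),
            }
        )
    per_pot = pd.DataFrame(rows)

    cum = (
        per_pot.groupby(["treatment", "pot_id"], as_index=False)[["Pt", "Pseed", "Psoil", "Pfert", "r_pct"]]
        .sum()
    )
    cum["Pdff"] = 100.0 * cum["Pfert"] / cum["Pt"]
    cum["SA"] = (cum["r_pct"] / 100.0) / cum["Pt"]
    with np.errstate(divide="ignore"):
        cum["L"] = np.where(cum["r_pct"] > 0, cum["Pt"] / (cum["r_pct"] / 100.0), np.nan)
    cum["CPU"] = [
        100.0 * pf / doses[t] if doses.get(t, 0.0) > 0 else np.nan
        for pf, t in zip(cum["Pfert"], cum["treatment"])
    ]

    means = []
    for trt, grp in cum.groupby("treatment"):
        res = PartitionResult(
            treatment=str(trt), scope="cumulative",
            Pt=grp["Pt"].mean(), Pseed=grp["Pseed"].mean(),
            Psoil=grp["Psoil"].mean(), Pfert=grp["Pfert"].mean(),
            r_over_R=grp["r_pct"].mean(),
        )
        dose = doses.get(str(trt), 0.0)
        means.append(_derive_ratios(res, dose if dose > 0 else None))
    eff = _effectiveness(means, reference, control)

    flagged = per_pot.loc[per_pot["flags"] != "", ["pot_id", "cut", "flags"]]
    flags.extend(
        f"pot {p} cut {c}: {f}" for p, c, f in flagged.itertuples(index=False)
    )
    return PartitionTable(per_pot, cum, means, eff, flags)


def _effectiveness(
    means: list[PartitionResult], reference: str | None, control: str
) -> dict[str, EffectivenessResult]:
    if reference is None:
        return {}
    ref = next((m for m in means if m.treatment == reference), None)
    if ref is None:
        return {}
    out = {}
    for m in means:
        if m.treatment in (control,):
            continue
        try:
            out[m.treatment] = agronomic_effectiveness(m, ref)
        except PartitioningError:
            continue
    return out
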