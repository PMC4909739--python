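"""Fertilizer dose arithmetic, co-application budgets and heavy-metal compliance.

Given a fertilizer composition sheet (total P plus nutrient and trace-metal
concentrations per kg dry matter), this module computes the dry-matter dose
delivering a target P rate, the nutrient/contaminant amounts co-applied per
kg of soil and per hectare, and a pass/fail check of trace-metal
concentrations against regulatory limits (the French sludge limits ship as
the default table).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "Quantity",
    "FertilizerSpec",
    "ComplianceReport",
    "MetalCheck",
    "UnitError",
    "FRENCH_SLUDGE_LIMITS_MG_KG",
    "dm_for_dose",
    "coapplication_rates",
    "per_hectare",
    "heavy_metal_compliance",
]

#: French regulatory limits for heavy metals in sewage sludge applied to
#: agricultural land, mg per kg dry matter.
FRENCH_SLUDGE_LIMITS_MG_KG: dict[str, float] = {
    "Cu": 1000.0,
    "Zn": 3000.0,
    "Cr": 1000.0,
    "Ni": 200.0,
    "Pb": 800.0,
    "Cd": 20.0,
    "Hg": 10.0,
}

_UNIT_TO_G = {"g/kg": 1.0, "mg/kg": 1e-3, "pct": 10.0}


class UnitError(ValueError):
    """Raised when a constituent's unit cannot be resolved."""


@dataclass(frozen=True)
class Quantity:
    """A unit-tagged concentration or rate.

    ``unit`` is one of ``g/kg``, ``mg/kg`` (per kg fertilizer DM for specs,
    per kg soil for rates) or ``pct``.
    """

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in _UNIT_TO_G:
            raise UnitError(f"unresolvable unit {self.unit!r}")

    def in_g_per_kg(self) -> float:
        return self.value * _UNIT_TO_G[self.unit]


@dataclass(frozen=True)
class FertilizerSpec:
    """Composition sheet of a fertilizer.

    ``total_p`` in g P per kg dry matter; ``constituents`` maps an element
    or fraction name to its unit-tagged concentration per kg DM.
    """

    name: str
    total_p: float
    constituents: Mapping[str, Quantity] = field(default_factory=dict)
    dry_solid_fraction: float | None = None  # percent

    def __post_init__(self) -> None:
        if self.total_p <= 0:
            raise ValueError("total_p must be > 0")
        for k, q in self.constituents.items():
            if q.value < 0:
                raise ValueError(f"negative concentration for {k!r}")


@dataclass(frozen=True)
class MetalCheck:
    metal: str
    concentration_mg_kg: float
    limit_mg_kg: float

    @property
    def passes(self) -> bool:
        return self.concentration_mg_kg <= self.limit_mg_kg


@dataclass(frozen=True)
class ComplianceReport:
    fertilizer: str
    checks: tuple[MetalCheck, ...]
    skipped: tuple[str, ...] = ()

    @property
    def overall_pass(self) -> bool:
        return all(c.passes for c in self.checks)


def dm_for_dose(dose_mg_p_per_kg: float, spec: FertilizerSpec) -> float:
    """Fertilizer dry matter (g per kg soil) delivering ``dose`` mg P per kg soil.

    ``dose [mg P] / total_p [g P kg⁻¹ DM] → g DM`` (the mg/g pair cancels).
    """
    if dose_mg_p_per_kg < 0:
        raise ValueError("dose must be >= 0")
    if spec.total_p <= 0:
        raise ValueError("invalid spec: total_p must be > 0")
    return dose_mg_p_per_kg / spec.total_p


def coapplication_rates(dose_mg_p_per_kg: float, spec: FertilizerSpec) -> dict[str, Quantity]:
    """Amount of every constituent co-applied at the given P dose, per kg soil.

    Rates keep their spec units: a constituent listed in g kg⁻¹ DM comes
    back in g kg⁻¹ soil, one in mg kg⁻¹ DM in mg kg⁻¹ soil.
    """
    dm_g = dm_for_dose(dose_mg_p_per_kg, spec)
    return {
        name: Quantity(dm_g / 1000.0 * q.value, q.unit)
        for name, q in spec.constituents.items()
    }


def per_hectare(rate_per_kg_soil: Quantity, soil_mass_t_per_ha: float = 3500.0) -> float:
    """Convert a per-kg-soil rate into kg per hectare.

    Defaults to 3500 t soil per ha (25 cm plough layer at bulk density 1.4).
    A rate of x g kg⁻¹ soil equals x kg t⁻¹, hence x × soil mass in kg ha⁻¹.
    """
    if soil_mass_t_per_ha <= 0:
        raise ValueError("soil mass must be > 0")
    return rate_per_kg_soil.in_g_per_kg() * soil_mass_t_per_ha


def heavy_metal_compliance(
    spec: FertilizerSpec,
    limits_mg_kg: Mapping[str, float] | None = None,
) -> ComplianceReport:
    """Check trace-metal concentrations against regulatory limits.

    Metals present in the spec but absent from the limits table are skipped
    (reported in ``skipped``); the overall verdict is the conjunction of the
    per-metal checks.
    """
    limits = dict(limits_mg_kg) if limits_mg_kg is not None else FRENCH_SLUDGE_LIMITS_MG_KG
    checks: list[MetalCheck] = []
    skipped: list[str] = []
    for metal in limits:
        q = spec.constituents.get(metal)
        if q is None:
            q = spec.constituents.get(f"Total {metal}")
        if q is None:
            continue
        conc_mg = q.in_g_per_kg() * 1000.0
        if conc_mg < 0:
            raise ValueError(f"invalid spec: negative concentration for {metal}")
        checks.append(MetalCheck(metal, conc_mg, limits[metal]))
    known = {c.metal for c in checks}
    for name, q in spec.constituents.items():
        bare = name.removeprefix("Total ").strip()
        if bare in FRENCH_SLUDGE_LIMITS_MG_KG and bare not in known and bare not in limits:
            skipped.append(bare)
    return ComplianceReport(spec.name, tuple(checks), tuple(skipped))
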