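"""Supplementation and fortification gap arithmetic.

Identifies countries whose per-capita apparent intake falls short of their
per-capita requirement, aggregates the annual deficit across those countries,
and converts it into intervention quantities: vitamin A capsules for children
6-59 months, and fortified wheat flour tonnages for vitamin A (3 mg/kg
retinol), iron (35 mg/kg NaFeEDTA at 10% bioavailability) and zinc (30 mg/kg
zinc oxide at 30% bioavailability).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

DAYS_PER_YEAR = 365.0
MG_PER_MCG = 1e-3
KG_PER_1000_MT = 1e6

#: Conversion of deficit units into mg (the fortificant level unit).
_TO_MG = {"mg": 1.0, "mcg": MG_PER_MCG, "mcg_RAE": MG_PER_MCG, "g": 1e3}


@dataclass(frozen=True)
class CapsuleSpec:
    """Vitamin A capsule doses and the standard delivery protocol.

    100K IU = 30,000 mcg retinol; 200K IU = 60,000 mcg.  Protocol: infants
    6-11 months get one 100K capsule per year, children 1-4 years (12-59
    months) get two 200K capsules per year.
    """

    dose_100k_mcg: float = 30_000.0
    dose_200k_mcg: float = 60_000.0
    infant_capsules_per_year: int = 1
    child_capsules_per_year: int = 2

    def __post_init__(self) -> None:
        if self.dose_100k_mcg <= 0 or self.dose_200k_mcg <= 0:
            raise ValueError("capsule doses must be positive")


@dataclass(frozen=True)
class FortificantSpec:
    """Fortificant dosage and bioavailability for one nutrient."""

    nutrient: str
    level_mg_per_kg: float
    bioavailability_fraction: float = 1.0
    compound: str = ""

    def __post_init__(self) -> None:
        if self.level_mg_per_kg <= 0:
            raise ValueError("fortificant level must be positive")
        if not 0.0 < self.bioavailability_fraction <= 1.0:
            raise ValueError("bioavailability fraction must be in (0,1]")


@dataclass(frozen=True)
class DeficitSummary:
    """Aggregate nutrient gap across deficit countries for one nutrient-year."""

    nutrient: str
    year: int
    deficit_countries: frozenset[str]
    aggregate_intake_per_day: float
    aggregate_requirement_per_day: float
    annual_deficit: float  # nutrient units / year
    unit: str = "mg"

    @property
    def n_countries(self) -> int:
        return len(self.deficit_countries)


def default_intervention_specs() -> dict:
    """The shipped capsule and fortificant specifications."""
    path = Path(__file__).parent / "data" / "intervention_specs.yaml"
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    caps = cfg["capsules"]
    fortificants = {
        k: FortificantSpec(
            nutrient=k,
            level_mg_per_kg=float(v["level_mg_per_kg"]),
            bioavailability_fraction=float(v["bioavailability_fraction"]),
            compound=v.get("compound", ""),
        )
        for k, v in cfg["fortificants"].items()
    }
    return {
        "capsules": CapsuleSpec(
            dose_100k_mcg=float(caps["dose_100k_mcg"]),
            dose_200k_mcg=float(caps["dose_200k_mcg"]),
        ),
        "fortificants": fortificants,
    }


def identify_and_aggregate_deficit(
    adequacy: pd.DataFrame,
    populations: pd.DataFrame,
    nutrient: str,
    year: int,
    unit: str = "mg",
) -> DeficitSummary:
    """Build the deficit summary for one nutrient-year.

    ``adequacy`` needs columns ``country, year, nutrient, pc_value,
    pc_requirement`` computed against the nutrient's designated standard
    (absorbed basis for bioavailability-adjusted iron/zinc); ``populations``
    columns ``country, year, population``.  Surplus countries never offset
    deficits.
    """
    sub = adequacy[(adequacy["nutrient"] == nutrient) & (adequacy["year"] == year)]
    pop = populations.set_index(["country", "year"])["population"]
    deficit_rows = sub[sub["pc_value"] < sub["pc_requirement"]]
    intake = requirement = deficit = 0.0
    countries = []
    for row in deficit_rows.itertuples(index=False):
        p = float(pop.loc[(row.country, year)])
        countries.append(row.country)
        intake += row.pc_value * p
        requirement += row.pc_requirement * p
        deficit += (row.pc_requirement - row.pc_value) * p * DAYS_PER_YEAR
    return DeficitSummary(
        nutrient=nutrient,
        year=int(year),
        deficit_countries=frozenset(countries),
        aggregate_intake_per_day=intake,
        aggregate_requirement_per_day=requirement,
        annual_deficit=deficit,
        unit=unit,
    )


def capsules_by_requirement(
    annual_req_infants_mcg: float,
    annual_req_children_mcg: float,
    spec: CapsuleSpec | None = None,
) -> float:
    """Capsules needed to supply the annual vitamin A requirement.

    Infant (6-11 mo) requirements are served by 100K IU capsules, child
    (1-4 y) requirements by 200K IU capsules.
    """
    if annual_req_infants_mcg < 0 or annual_req_children_mcg < 0:
        raise ValueError("requirements must be non-negative")
    spec = spec or CapsuleSpec()
    return (
        annual_req_infants_mcg / spec.dose_100k_mcg
        + annual_req_children_mcg / spec.dose_200k_mcg
    )


def capsules_by_protocol(
    n_infants_6_11: float,
    n_children_1_4: float,
    spec: CapsuleSpec | None = None,
) -> float:
    """Capsules needed under the delivery protocol (1/yr infants, 2/yr children)."""
    if n_infants_6_11 < 0 or n_children_1_4 < 0:
        raise ValueError("counts must be non-negative")
    spec = spec or CapsuleSpec()
    return (
        n_infants_6_11 * spec.infant_capsules_per_year
        + n_children_1_4 * spec.child_capsules_per_year
    )


def fortification_required(
    annual_deficit: float,
    deficit_unit: str,
    spec: FortificantSpec,
    annual_flour_consumed_1000mt: float,
) -> dict:
    """Fortified flour required to fill an annual nutrient deficit.

    flour (kg) = deficit (mg) / (level mg/kg × bioavailability); reported in
    1000 MT/yr alongside the share of annual wheat-flour consumption it
    represents (rounded half-up to an integer percent for reporting, with the
    unrounded value retained).  Percentages above 100 are meaningful — the
    whole flour supply would not suffice — and are never clamped.
    """
    if annual_deficit < 0:
        raise ValueError("deficit must be non-negative")
    if deficit_unit not in _TO_MG:
        raise ValueError(f"unknown deficit unit {deficit_unit!r}")
    deficit_mg = annual_deficit * _TO_MG[deficit_unit]
    flour_kg = deficit_mg / (spec.level_mg_per_kg * spec.bioavailability_fraction)
    flour_1000mt = flour_kg / KG_PER_1000_MT

    if annual_flour_consumed_1000mt > 0:
        pct = 100.0 * flour_1000mt / annual_flour_consumed_1000mt
        pct_int = int(math.floor(pct + 0.5))
    elif flour_1000mt == 0:
        pct, pct_int = 0.0, 0
    else:
        pct, pct_int = float("nan"), None
    return {
        "flour_required_1000mt": flour_1000mt,
        "percent_of_consumption": pct,
        "percent_of_consumption_rounded": pct_int,
    }


def fortification_table(
    summaries: Mapping[tuple[str, int], DeficitSummary],
    flour_consumed: Mapping[int, float],
    fortificants: Mapping[str, FortificantSpec],
) -> pd.DataFrame:
    """Fortification requirements for several nutrient-years as one table."""
    rows = []
    for (nutrient, year), summary in summaries.items():
        spec = fortificants[nutrient]
        res = fortification_required(
            summary.annual_deficit, summary.unit, spec, flour_consumed[year]
        )
        rows.append(
            {
                "nutrient": nutrient,
                "year": year,
                "n_deficit_countries": summary.n_countries,
                "annual_deficit": summary.annual_deficit,
                "deficit_unit": summary.unit,
                "flour_required_1000mt": res["flour_required_1000mt"],
                "flour_consumed_1000mt": flour_consumed[year],
                "percent_of_consumption": res["percent_of_consumption"],
                "percent_of_consumption_rounded": res[
                    "percent_of_consumption_rounded"
                ],
            }
        )
    return pd.DataFrame(rows)
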