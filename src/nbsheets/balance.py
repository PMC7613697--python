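"""Commodity flows → per-capita daily nutrient values.

Converts food-balance-sheet commodity flow quantities (1000 metric tonnes per
year, by country × year × food category × element) into per-capita daily
nutrient values under four loss-accounting variants:

``raw``
    edible mass × composition only (no processing, loss/waste or cooking).
``processing_only``
    adds cereal flour extraction and processing mass factors.
``flw_cooking_only``
    adds regional food loss & waste (FLW) and cooking nutrient retention,
    but no processing.
``final_best``
    all three adjustments together — the best estimate of apparent intake.

FLW fractions apply to the *food* element only (availability for human
consumption); the FBS "losses" element is a separate supply-side account and
passes through untouched, avoiding double counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .food_model import (
    BASE_VARIANT,
    CompositionTable,
    CookingRetention,
    FlwTable,
    OverrideRules,
    ProcessingFactors,
    RefuseTable,
    Taxonomy,
    resolve_composition,
)

#: FBS elements a flow record may carry.
ELEMENTS = frozenset(
    {
        "production",
        "imports",
        "exports",
        "stock_change",
        "feed",
        "seed",
        "processing",
        "other_uses",
        "losses",
        "food",
    }
)

#: Loss-accounting variants.
VARIANTS = ("raw", "processing_only", "flw_cooking_only", "final_best")

#: Map FBS element → flow role used when resolving composition overrides.
_ELEMENT_ROLE = {"exports": "export", "imports": "import"}

DAYS_PER_YEAR = 365.0  # FBS convention; no leap years
GRAMS_PER_1000_MT = 1.0e9


@dataclass(frozen=True)
class FlowRecord:
    """One commodity-flow cell (quantity in 1000 metric tonnes/year)."""

    country: str
    year: int
    fc_code: str
    element: str
    quantity: float

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown FBS element {self.element!r}")
        if self.quantity < 0 and self.element != "stock_change":
            raise ValueError(
                f"negative quantity for element {self.element!r} "
                f"({self.country}/{self.year}/{self.fc_code})"
            )


@dataclass(frozen=True)
class CerealSplitSpec:
    """Regional refined/whole flour split for one cereal.

    ``refined_proportion`` is the share of the grain milled to refined flour;
    extraction rates are the mass fraction of grain recovered as flour
    (e.g. 0.72 for straight-grade wheat flour, 1.0 for whole-grain flours).
    """

    cereal: str
    region: str
    refined_proportion: float
    refined_extraction: float
    whole_extraction: float
    refined_fc: str = ""
    whole_fc: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.refined_proportion <= 1.0:
            raise ValueError(
                f"refined_proportion out of [0,1]: {self.refined_proportion}"
            )
        for name in ("refined_extraction", "whole_extraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} out of (0,1]: {v}")


def to_per_capita(quantity_1000mt: float, population: float) -> float:
    """Convert an annual flow (1000 MT/yr) to grams per person per day."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    return quantity_1000mt * GRAMS_PER_1000_MT / (population * DAYS_PER_YEAR)


def split_cereal_flours(
    percapita_grain: float, spec: CerealSplitSpec
) -> tuple[float, float]:
    """Split per-capita grain (g/day) into refined and whole flour masses.

    refined = grain × p × e_refined; whole = grain × (1−p) × e_whole.  The
    as-consumed cereal quantity is the sum of the two flour masses.
    """
    if percapita_grain < 0:
        raise ValueError("grain quantity must be non-negative")
    refined = percapita_grain * spec.refined_proportion * spec.refined_extraction
    whole = percapita_grain * (1.0 - spec.refined_proportion) * spec.whole_extraction
    return refined, whole


def apply_processing_factor(percapita: float, factor: float) -> float:
    """Primary-commodity mass → as-consumed mass (factor >1 = dilution)."""
    if factor <= 0:
        raise ValueError(f"processing factor must be positive, got {factor}")
    if percapita < 0:
        raise ValueError("per-capita quantity must be non-negative")
    return percapita * factor


def compute_nutrients(
    percapita: float,
    refuse_fraction: float,
    processing_retention: float,
    composition_per_100g: pd.Series,
    variant: str,
    flw_retention: float = 1.0,
    cooking_retention: pd.Series | float = 1.0,
) -> pd.Series:
    """Per-capita daily nutrient vector for one flow under one variant.

    base = g/day × (1 − refuse) × processing × composition/100; the
    ``raw`` and ``flw_cooking_only`` variants force processing to 1, and the
    ``flw_cooking_only`` / ``final_best`` variants multiply by FLW retention
    (1 for exempt subgroups) and per-nutrient cooking retention.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if percapita < 0:
        raise ValueError("per-capita quantity must be non-negative")
    if not 0.0 <= refuse_fraction < 1.0:
        raise ValueError(f"refuse fraction out of [0,1): {refuse_fraction}")
    if processing_retention <= 0:
        raise ValueError("processing retention must be positive")
    if not 0.0 <= flw_retention <= 1.0:
        raise ValueError(f"FLW retention out of [0,1]: {flw_retention}")

    proc = processing_retention if variant in ("processing_only", "final_best") else 1.0
    out = percapita * (1.0 - refuse_fraction) * proc * composition_per_100g / 100.0
    if variant in ("flw_cooking_only", "final_best"):
        out = out * flw_retention * cooking_retention
    return out


# ---------------------------------------------------------------------------
# Table-level pipeline
# ---------------------------------------------------------------------------


class BalanceInputs:
    """Bundle of everything the table-level engine needs."""

    def __init__(
        self,
        taxonomy: Taxonomy,
        fct: CompositionTable,
        refuse: RefuseTable,
        processing: ProcessingFactors,
        cooking: CookingRetention,
        flw: FlwTable,
        country_regions: Mapping[str, str],
        cereal_splits: Sequence[CerealSplitSpec] = (),
        override_rules: OverrideRules | None = None,
    ):
        self.taxonomy = taxonomy
        self.fct = fct
        self.refuse = refuse
        self.processing = processing
        self.cooking = cooking
        self.flw = flw
        self.country_regions = dict(country_regions)
        self.cereal_splits = {
            (s.cereal, s.region): s for s in cereal_splits
        }
        self.override_rules = override_rules


def _flow_role(element: str) -> str:
    return _ELEMENT_ROLE.get(element, "domestic_retained")


def compute_nutrient_table(
    flows: pd.DataFrame,
    population: pd.DataFrame,
    inputs: BalanceInputs,
    variants: Sequence[str] = VARIANTS,
) -> pd.DataFrame:
    """Run the full flows → nutrients conversion.

    Parameters
    ----------
    flows
        Columns ``country, year, fc_code, element, qty_1000mt``.
    population
        Columns ``country, year, population``.
    inputs
        Taxonomy, composition and factor tables.
    variants
        Loss-accounting variants to compute.

    Returns
    -------
    Long DataFrame with columns
    ``country, year, fc_code, element, variant, nutrient, value``.
    Cereal grains with a split spec appear under their flour FC codes for the
    processing variants and under the grain FC for the non-processing ones.
    """
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
    pop = population.set_index(["country", "year"])["population"]
    nutrients = inputs.fct.nutrients
    records: list[dict] = []

    for row in flows.itertuples(index=False):
        country, year, fc, element, qty = (
            row.country,
            int(row.year),
            row.fc_code,
            row.element,
            float(row.qty_1000mt),
        )
        if element not in ELEMENTS:
            raise ValueError(f"unknown FBS element {element!r}")
        if fc not in inputs.taxonomy:
            raise KeyError(f"unknown food category {fc!r} in flows")
        region = inputs.country_regions.get(country)
        if region is None:
            raise KeyError(f"country {country!r} has no region metadata")
        g_day = to_per_capita(qty, float(pop.loc[(country, year)]))
        role = _flow_role(element)
        fsg = inputs.taxonomy.fsg(fc)
        split = inputs.cereal_splits.get((fc, region))

        for variant in variants:
            with_processing = variant in ("processing_only", "final_best")
            with_flw_cooking = variant in ("flw_cooking_only", "final_best")
            flw_ret = (
                inputs.flw.retention(region, fsg)
                if (with_flw_cooking and element == "food")
                else 1.0
            )

            if with_processing and split is not None:
                # Grain is consumed as refined + whole flour with their own
                # composition records (flour FCs) and extraction-rate masses.
                refined_g, whole_g = split_cereal_flours(g_day, split)
                parts = [(split.refined_fc, refined_g), (split.whole_fc, whole_g)]
            else:
                parts = [(fc, g_day)]

            for part_fc, part_g in parts:
                comp = resolve_composition(
                    inputs.fct, part_fc, country, role, inputs.override_rules
                )
                proc = inputs.processing.get(part_fc) if with_processing else 1.0
                cook = (
                    pd.Series(
                        inputs.cooking.vector(part_fc, nutrients), index=nutrients
                    )
                    if with_flw_cooking
                    else 1.0
                )
                vec = compute_nutrients(
                    part_g,
                    inputs.refuse.get(part_fc),
                    proc if with_processing else 1.0,
                    comp,
                    variant,
                    flw_retention=flw_ret,
                    cooking_retention=cook,
                )
                for nut in nutrients:
                    records.append(
                        {
                            "country": country,
                            "year": year,
                            "fc_code": part_fc,
                            "source_fc": fc,
                            "element": element,
                            "variant": variant,
                            "nutrient": nut,
                            "value": float(vec[nut]),
                        }
                    )

    return pd.DataFrame.from_records(
        records,
        columns=[
            "country",
            "year",
            "fc_code",
            "source_fc",
            "element",
            "variant",
            "nutrient",
            "value",
        ],
    )


def compute_mass_table(
    flows: pd.DataFrame,
    population: pd.DataFrame,
    inputs: BalanceInputs,
    variant: str = "final_best",
    element: str = "food",
) -> pd.DataFrame:
    """Edible as-consumed grams per person per day by country/year/FC.

    Mirrors the mass chain of :func:`compute_nutrient_table` (per-capita
    conversion, cereal split, processing factor, refuse, FLW) without the
    composition step.  Used to build diet profiles (e.g. meat/fish/poultry
    grams for iron bioavailability) on an edible, post-refuse basis.
    """
    pop = population.set_index(["country", "year"])["population"]
    with_processing = variant in ("processing_only", "final_best")
    with_flw = variant in ("flw_cooking_only", "final_best")
    records = []
    for row in flows.itertuples(index=False):
        if row.element != element:
            continue
        country, year, fc = row.country, int(row.year), row.fc_code
        region = inputs.country_regions[country]
        g_day = to_per_capita(float(row.qty_1000mt), float(pop.loc[(country, year)]))
        fsg = inputs.taxonomy.fsg(fc)
        flw_ret = inputs.flw.retention(region, fsg) if with_flw else 1.0
        split = inputs.cereal_splits.get((fc, region))
        if with_processing and split is not None:
            refined_g, whole_g = split_cereal_flours(g_day, split)
            parts = [(split.refined_fc, refined_g), (split.whole_fc, whole_g)]
        else:
            parts = [(fc, g_day)]
        for part_fc, part_g in parts:
            proc = inputs.processing.get(part_fc) if with_processing else 1.0
            edible = part_g * proc * (1.0 - inputs.refuse.get(part_fc)) * flw_ret
            records.append(
                {
                    "country": country,
                    "year": year,
                    "fc_code": part_fc,
                    "source_fc": fc,
                    "grams_per_person_day": edible,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["country", "year", "fc_code", "source_fc", "grams_per_person_day"],
    )


def aggregate_country(
    nutrient_table: pd.DataFrame,
    side: str,
    taxonomy: Taxonomy,
) -> pd.DataFrame:
    """Country-year per-capita nutrient totals for one side of the balance.

    ``production`` sums the production element, excluding food categories
    flagged as processed foods (vegetable oils, alcohol, butter, cream, fish
    oils) to avoid double counting nutrients already counted in their raw
    commodities; ``apparent_intake`` sums the food element across all FCs.

    Returns a DataFrame with columns ``country, year, variant, nutrient,
    value``.
    """
    if side not in ("production", "apparent_intake"):
        raise ValueError(f"unknown side {side!r}")
    element = "production" if side == "production" else "food"
    sub = nutrient_table[nutrient_table["element"] == element]
    if side == "production":
        processed = {
            c.fc_code for c in taxonomy if c.is_processed_food
        }
        sub = sub[~sub["source_fc"].isin(processed)]
    if sub.empty:
        warnings.warn(f"no rows for side {side!r}; returning empty totals")
        return pd.DataFrame(
            columns=["country", "year", "variant", "nutrient", "value"]
        )
    out = (
        sub.groupby(["country", "year", "variant", "nutrient"], as_index=False)[
            "value"
        ].sum()
    )
    return out
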