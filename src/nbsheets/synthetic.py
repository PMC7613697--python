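"""Synthetic food-balance worlds with construction-time ground truth.

Generates complete, internally consistent input bundles — commodity flows,
food-composition item matches, refuse/processing/cooking/FLW factor tables,
demographics, reproductive statistics and DRVs — shaped like the national
food-balance-sheet data the engine consumes, together with expected outputs
computed here by direct scalar evaluation of the accounting formulas.  The
ground-truth path shares no code with the engine: it is plain loops over the
generated records, so a full-pipeline comparison is a genuine oracle test.

Worlds are structural, not statistically calibrated: magnitudes are chosen to
be dietarily plausible (hundreds of g/day of staples, tens of meat) so the
bioavailability stage operates in a realistic regime, but no attempt is made
to mimic real countries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import bioavailability as bio
from .balance import BalanceInputs, CerealSplitSpec
from .food_model import (
    CompositionTable,
    CookingRetention,
    FlwRecord,
    FlwTable,
    FoodCategory,
    OverrideRule,
    OverrideRules,
    ProcessingFactors,
    RefuseTable,
    Taxonomy,
    collapse_fct,
)

DAYS = 365.0

NUTRIENTS = [
    "energy",
    "protein",
    "vitamin_a",
    "iron",
    "zinc",
    "vitamin_c",
    "calcium",
    "phytate",
    "polyphenols",
]

#: Nutrients whose adequacy is computed directly from intake totals.
PLAIN_ADEQUACY_NUTRIENTS = [
    "energy",
    "protein",
    "vitamin_a",
    "vitamin_c",
    "calcium",
]

#: Nutrients a target adequacy profile may constrain (linear in one FC mass).
TARGETABLE = {"vitamin_a", "vitamin_c", "calcium"}

_ADJUSTER_COMP = {"vitamin_a": 1000.0, "vitamin_c": 500.0, "calcium": 2000.0}


@dataclass(frozen=True)
class WorldSpec:
    """Specification of a synthetic world; deterministic given ``seed``."""

    n_countries: int = 3
    years: tuple[int, ...] = (2000, 2010)
    n_filler_fcs: int = 2
    fco_mass_fraction: float = 0.15
    seed: int = 0
    #: (country, nutrient) → target percent of requirement for apparent intake.
    adequacy_targets: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_countries < 1 or not self.years:
            raise ValueError("need at least one country and one year")
        if not 0.0 < self.fco_mass_fraction < 0.9:
            raise ValueError("fco_mass_fraction out of (0, 0.9)")
        for (_, nutrient) in self.adequacy_targets:
            if nutrient not in TARGETABLE:
                raise ValueError(
                    f"adequacy targets supported only for {sorted(TARGETABLE)}"
                )


@dataclass
class World:
    """A generated input bundle plus its ground truth."""

    spec: WorldSpec
    taxonomy: Taxonomy
    fct_items: pd.DataFrame        # item matches, pre-collapse
    composition: dict              # (fc, variant) -> {nutrient: value} (intended)
    refuse: RefuseTable
    processing: ProcessingFactors
    cooking: CookingRetention
    flw: FlwTable
    cereal_splits: list
    override_rules: OverrideRules
    country_regions: dict
    flows: pd.DataFrame            # country, year, fc_code, element, qty_1000mt
    population: pd.DataFrame       # country, year, population
    demographics: pd.DataFrame     # country, year, age, sex, count
    reproductive: pd.DataFrame
    drvs: pd.DataFrame
    body_weights: pd.DataFrame
    fco_candidates: dict           # fco -> DataFrame of candidate compositions
    ground_truth: dict

    def balance_inputs(self) -> BalanceInputs:
        fct = collapse_fct(self.fct_items)
        return BalanceInputs(
            taxonomy=self.taxonomy,
            fct=fct,
            refuse=self.refuse,
            processing=self.processing,
            cooking=self.cooking,
            flw=self.flw,
            country_regions=self.country_regions,
            cereal_splits=self.cereal_splits,
            override_rules=self.override_rules,
        )


# ---------------------------------------------------------------------------
# Static world structure
# ---------------------------------------------------------------------------


def _base_categories(n_filler: int) -> list[FoodCategory]:
    cats = [
        FoodCategory("wheat", "Wheat", "cereals", "starchy_staples"),
        FoodCategory("wheat_flour_refined", "Wheat flour, refined", "cereals", "starchy_staples"),
        FoodCategory("wheat_flour_whole", "Wheat flour, whole", "cereals", "starchy_staples"),
        FoodCategory("rice", "Rice", "cereals", "starchy_staples"),
        FoodCategory("cereals_other", "Cereals, other", "cereals", "starchy_staples", is_fco=True),
        FoodCategory("veg_leafy", "Leafy vegetables", "vegetables", "nutrient_dense_vegetal", is_fv=True),
        FoodCategory("vegetables_other", "Vegetables, other", "vegetables", "nutrient_dense_vegetal", is_fco=True, is_fv=True),
        FoodCategory("fruit_citrus", "Citrus fruit", "fruits", "nutrient_dense_vegetal", is_fv=True),
        FoodCategory("beef", "Bovine meat", "meat", "animal_source", is_hsi=True),
        FoodCategory("poultry", "Poultry meat", "meat", "animal_source", is_hsi=True),
        FoodCategory("fish_demersal", "Demersal fish", "fish_seafood", "animal_source", is_hsi=True),
        FoodCategory("pulses_other", "Pulses, other", "pulses", "nutrient_dense_vegetal", is_fco=True),
        FoodCategory("palm_oil", "Palm oil", "vegetable_oils", "other", is_processed_food=True),
        FoodCategory("tea", "Tea", "stimulants", "other"),
    ]
    for nutrient, _ in _ADJUSTER_COMP.items():
        cats.append(
            FoodCategory(
                f"adj_{nutrient}",
                f"Adjuster food ({nutrient})",
                "vegetables",
                "nutrient_dense_vegetal",
            )
        )
    for i in range(n_filler):
        cats.append(
            FoodCategory(
                f"filler_{i}", f"Filler food {i}", "fruits", "nutrient_dense_vegetal",
                is_fv=True,
            )
        )
    return cats


def _compositions(rng: np.random.Generator, n_filler: int) -> dict:
    """Intended (fc, variant) → per-100 g nutrient dicts."""

    def vec(**kw) -> dict:
        d = {n: 0.0 for n in NUTRIENTS}
        d.update(kw)
        return d

    comp = {
        ("wheat", "base"): vec(energy=340, protein=12, iron=3.5, zinc=2.8, calcium=30, phytate=800),
        ("wheat_flour_refined", "base"): vec(energy=364, protein=10, iron=1.2, zinc=0.9, calcium=15, phytate=250),
        ("wheat_flour_whole", "base"): vec(energy=340, protein=13, iron=3.6, zinc=2.9, calcium=34, phytate=850),
        ("rice", "base"): vec(energy=360, protein=7, iron=1.5, zinc=1.2, calcium=10, phytate=300),
        ("rice", "parboiled_white"): vec(energy=370, protein=6.8, iron=1.1, zinc=1.0, calcium=8, phytate=200),
        ("veg_leafy", "base"): vec(energy=25, protein=2.5, vitamin_a=40, iron=2.0, zinc=0.4, vitamin_c=50, calcium=100),
        ("fruit_citrus", "base"): vec(energy=45, protein=0.8, vitamin_a=10, iron=0.3, zinc=0.1, vitamin_c=45, calcium=25),
        ("beef", "base"): vec(energy=250, protein=26, iron=2.6, zinc=6.3, calcium=18),
        ("poultry", "base"): vec(energy=215, protein=27, iron=1.3, zinc=2.0, calcium=14),
        ("fish_demersal", "base"): vec(energy=105, protein=23, iron=0.9, zinc=0.5, calcium=60),
        ("palm_oil", "base"): vec(energy=884),
        ("palm_oil", "red_palm"): vec(energy=884, vitamin_a=5000),
        ("tea", "base"): vec(energy=1, polyphenols=25),
    }
    for nutrient, value in _ADJUSTER_COMP.items():
        comp[(f"adj_{nutrient}", "base")] = vec(**{nutrient: value})
    for i in range(n_filler):
        comp[(f"filler_{i}", "base")] = vec(
            energy=float(rng.uniform(30, 90)),
            protein=float(rng.uniform(0.5, 3.0)),
            vitamin_c=float(rng.uniform(5, 40)),
            iron=float(rng.uniform(0.2, 1.5)),
            zinc=float(rng.uniform(0.1, 0.8)),
            calcium=float(rng.uniform(10, 60)),
        )
    return comp


def _fco_candidate_sets(rng: np.random.Generator) -> dict:
    """Candidate item compositions per FCO (3 candidates each)."""

    def frame(rows):
        return pd.DataFrame(rows, columns=NUTRIENTS).astype(float)

    cands = {}
    cands["cereals_other"] = frame(
        [
            dict.fromkeys(NUTRIENTS, 0.0) | {"energy": 350.0, "protein": 11.0, "iron": 3.0, "zinc": 2.5, "calcium": 25.0, "phytate": 700.0},
            dict.fromkeys(NUTRIENTS, 0.0) | {"energy": 330.0, "protein": 9.0, "iron": 4.5, "zinc": 3.0, "calcium": 40.0, "phytate": 900.0},
            dict.fromkeys(NUTRIENTS, 0.0) | {"energy": 365.0, "protein": 12.5, "iron": 2.0, "zinc": 2.0, "calcium": 15.0, "phytate": 500.0},
        ]
    )
    cands["vegetables_other"] = frame(
        [
            dict.fromkeys(NUTRIENTS, 0.0) | {"energy": 30.0, "protein": 1.5, "vitamin_a": 30.0, "vitamin_c": 30.0, "iron": 1.0, "zinc": 0.3, "calcium": 50.0},
            dict.fromkeys(NUTRIENTS, 0.0) | {"energy": 22.0, "protein": 1.0, "vitamin_a": 80.0, "vitamin_c": 60.0, "iron": 2.5, "zinc": 0.5, "calcium": 120.0},
            dict.fromkeys(NUTRIENTS, 0.0) | {"energy": 40.0, "protein": 2.0, "vitamin_a": 10.0, "vitamin_c": 15.0, "iron": 0.6, "zinc": 0.4, "calcium": 30.0},
        ]
    )
    cands["pulses_other"] = frame(
        [
            dict.fromkeys(NUTRIENTS, 0.0) | {"energy": 340.0, "protein": 22.0, "iron": 6.0, "zinc": 3.0, "calcium": 100.0, "phytate": 1000.0},
            dict.fromkeys(NUTRIENTS, 0.0) | {"energy": 330.0, "protein": 20.0, "iron": 7.5, "zinc": 3.5, "calcium": 140.0, "phytate": 1200.0},
            dict.fromkeys(NUTRIENTS, 0.0) | {"energy": 350.0, "protein": 24.0, "iron": 5.0, "zinc": 2.8, "calcium": 80.0, "phytate": 800.0},
        ]
    )
    return cands


_REFUSE = {"beef": 0.333, "poultry": 0.25, "fish_demersal": 0.20, "fruit_citrus": 0.28}
_PROCESSING = {"tea": 119.05}
_COOKING = {
    ("veg_leafy", "vitamin_c"): 0.70,
    ("vegetables_other", "vitamin_c"): 0.70,
    ("fruit_citrus", "vitamin_c"): 0.95,
    ("beef", "iron"): 0.90,
    ("poultry", "iron"): 0.90,
    ("wheat_flour_refined", "iron"): 0.95,
    ("wheat_flour_whole", "iron"): 0.95,
}

_FLW_EXEMPT_FSGS = {"vegetable_oils", "stimulants", "pulses"}
_FLW_BY_FSG = {
    # fsg: (postharvest, retail, consumption)
    "cereals": (0.0, 0.02, 0.10),
    "vegetables": (0.0, 0.05, 0.15),
    "fruits": (0.0, 0.04, 0.12),
    "meat": (0.0, 0.03, 0.08),
    "fish_seafood": (0.10, 0.05, 0.08),
}

# Baseline food-element mass ranges (g/person/day).
_FOOD_G_DAY = {
    "wheat": (100, 300),
    "rice": (50, 200),
    "cereals_other": (20, 60),
    "veg_leafy": (50, 150),
    "vegetables_other": (30, 80),
    "fruit_citrus": (30, 100),
    "beef": (20, 80),
    "poultry": (10, 60),
    "fish_demersal": (10, 50),
    "pulses_other": (10, 50),
    "palm_oil": (5, 30),
    "tea": (0.5, 2.0),
}

_REGIONS = ("ssa_trop", "asia", "europe")

# Synthetic DRV values: (child 0-14, adult M, adult F, pregnant, lactating)
_DRV_VALUES = {
    ("energy", "AR", "absolute_per_day"): (1600, 2500, 2000, 2200, 2500),
    ("protein", "AR", "per_kg_bodyweight"): (0.9, 0.66, 0.66, 0.8, 0.85),
    ("vitamin_a", "AR", "absolute_per_day"): (300, 570, 490, 540, 1020),
    ("vitamin_c", "AI", "absolute_per_day"): (40, 90, 80, 95, 140),
    ("calcium", "AR", "absolute_per_day"): (600, 750, 750, 750, 750),
    ("iron", "AR", "absolute_per_day"): (5, 6, 7, 7, 7),
    ("iron", "physiological", "absolute_per_day"): (0.6, 0.95, 1.3, 2.2, 1.1),
    ("zinc", "AR", "absolute_per_day"): (4.0, 9.0, 7.0, 9.0, 10.0),
    ("zinc", "physiological", "absolute_per_day"): (1.2, 3.0, 2.5, 3.3, 4.0),
}

_AGE_CELLS = [2, 8, 25, 30, 40, 70]  # 1-year ages sampled by the fixture


def _drv_table() -> pd.DataFrame:
    rows = []
    groups = [
        # (age_min, age_max, sex, pregnant, lactating)
        (0, 14, "any", False, False),
        (15, 100, "M", False, False),
        (15, 100, "F", False, False),
        (0, 100, "F", True, False),
        (0, 100, "F", False, True),
    ]
    for (nutrient, vtype, basis), values in _DRV_VALUES.items():
        for (a0, a1, sex, preg, lact), value in zip(groups, values):
            rows.append(
                {
                    "nutrient": nutrient,
                    "age_min": a0,
                    "age_max": a1,
                    "sex": sex,
                    "pregnant": preg,
                    "lactating": lact,
                    "value_type": vtype,
                    "value": float(value),
                    "basis": basis,
                }
            )
    return pd.DataFrame(rows)


def _body_weights() -> pd.DataFrame:
    rows = [
        {"age_min": 0, "age_max": 14, "sex": "any", "weight_kg": 25.0},
        {"age_min": 15, "age_max": 100, "sex": "M", "weight_kg": 70.0},
        {"age_min": 15, "age_max": 100, "sex": "F", "weight_kg": 60.0},
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ground-truth helpers (independent scalar path)
# ---------------------------------------------------------------------------


def _gt_flw_retention(fsg: str) -> float:
    if fsg in _FLW_EXEMPT_FSGS or fsg not in _FLW_BY_FSG:
        return 1.0
    p, r, c = _FLW_BY_FSG[fsg]
    return (1.0 - p) * (1.0 - r) * (1.0 - c)


def _gt_composition(
    world_comp: dict,
    fc: str,
    country: str,
    role: str,
    region: str,
    rice_country: str,
) -> dict:
    """Scalar override resolution mirroring the shipped rules."""
    base = world_comp[(fc, "base")]
    if fc == "palm_oil" and region == "ssa_trop" and role == "domestic_retained":
        red = world_comp[("palm_oil", "red_palm")]
        return {n: 0.70 * red[n] + 0.30 * base[n] for n in NUTRIENTS}
    if fc == "rice" and country == rice_country:
        return world_comp[("rice", "parboiled_white")]
    return base


def _gt_nutrient_rows(
    flow_rows: list[dict],
    pop: dict,
    world_comp: dict,
    country_regions: dict,
    rice_country: str,
    fsg_of: dict,
    split_spec: CerealSplitSpec,
) -> list[dict]:
    """Direct evaluation of the per-capita nutrient formula, all variants."""
    out = []
    for fr in flow_rows:
        country, year, fc, element, qty = (
            fr["country"],
            fr["year"],
            fr["fc_code"],
            fr["element"],
            fr["qty_1000mt"],
        )
        region = country_regions[country]
        g_day = qty * 1e9 / (pop[(country, year)] * DAYS)
        role = {"exports": "export", "imports": "import"}.get(
            element, "domestic_retained"
        )
        for variant in ("raw", "processing_only", "flw_cooking_only", "final_best"):
            with_proc = variant in ("processing_only", "final_best")
            with_flwcook = variant in ("flw_cooking_only", "final_best")
            flw_ret = (
                _gt_flw_retention(fsg_of[fc])
                if (with_flwcook and element == "food")
                else 1.0
            )
            if with_proc and fc == "wheat":
                parts = [
                    (
                        "wheat_flour_refined",
                        g_day
                        * split_spec.refined_proportion
                        * split_spec.refined_extraction,
                    ),
                    (
                        "wheat_flour_whole",
                        g_day
                        * (1.0 - split_spec.refined_proportion)
                        * split_spec.whole_extraction,
                    ),
                ]
            else:
                parts = [(fc, g_day)]
            for part_fc, part_g in parts:
                comp = _gt_composition(
                    world_comp, part_fc, country, role, region, rice_country
                )
                proc = _PROCESSING.get(part_fc, 1.0) if with_proc else 1.0
                refuse = _REFUSE.get(part_fc, 0.0)
                for nutrient in NUTRIENTS:
                    v = part_g * (1.0 - refuse) * proc * comp[nutrient] / 100.0
                    if with_flwcook:
                        v = v * flw_ret * _COOKING.get((part_fc, nutrient), 1.0)
                    out.append(
                        {
                            "country": country,
                            "year": year,
                            "fc_code": part_fc,
                            "source_fc": fc,
                            "element": element,
                            "variant": variant,
                            "nutrient": nutrient,
                            "value": v,
                        }
                    )
    return out


def _gt_weighted_requirement(
    cells: list[dict],
    drvs: pd.DataFrame,
    nutrient: str,
    standard: str,
    body_weights: pd.DataFrame,
) -> float:
    """Independent scalar DRV weighting (mirrors the published convention)."""
    rows = drvs[(drvs["nutrient"] == nutrient)]
    vtype = standard
    if standard == "auto":
        vtype = "AR" if (rows["value_type"] == "AR").any() else "AI"
    rows = rows[rows["value_type"] == vtype]
    total = sum(c["count"] for c in cells)
    acc = 0.0
    for c in cells:
        if c["pregnant"]:
            rec = rows[rows["pregnant"]].iloc[0]
        elif c["lactating"]:
            rec = rows[rows["lactating"]].iloc[0]
        else:
            m = rows[
                ~rows["pregnant"]
                & ~rows["lactating"]
                & (rows["age_min"] <= c["age"])
                & (c["age"] <= rows["age_max"])
                & rows["sex"].isin([c["sex"], "any"])
            ]
            rec = m.iloc[0]
        value = float(rec["value"])
        if rec["basis"] == "per_kg_bodyweight":
            bw = body_weights[
                (body_weights["age_min"] <= c["age"])
                & (c["age"] <= body_weights["age_max"])
                & body_weights["sex"].isin([c["sex"], "any"])
            ]
            value *= float(bw["weight_kg"].iloc[0])
        acc += c["count"] * value
    return acc / total


def _gt_cells(
    demo_rows: list[dict], births: float, abortions: float, miscarriages: float
) -> list[dict]:
    """Reallocated demographic cells, scalar path."""
    n_preg = births * (40.0 / 52.0) + abortions * (10.0 / 52.0) + miscarriages * (
        10.0 / 52.0
    )
    n_lact = births * 0.5
    cells = [
        {
            "age": r["age"],
            "sex": r["sex"],
            "count": r["count"],
            "pregnant": False,
            "lactating": False,
        }
        for r in demo_rows
    ]
    pool = sum(c["count"] for c in cells if c["sex"] == "F" and 15 <= c["age"] <= 49)
    needed = n_preg + n_lact
    if needed > pool:
        raise ValueError("infeasible reproductive counts in synthetic world")
    for c in cells:
        if c["sex"] == "F" and 15 <= c["age"] <= 49:
            c["count"] -= c["count"] / pool * needed
    cells.append({"age": 32, "sex": "F", "count": n_preg, "pregnant": True, "lactating": False})
    cells.append({"age": 32, "sex": "F", "count": n_lact, "pregnant": False, "lactating": True})
    return cells


def _gt_iron_algorithm(profile: dict, spec: dict, serum_ferritin: float,
                       polyphenol_mg_per_cup: float) -> float:
    """Scalar evaluation of an iron-algorithm parameter entry."""
    cov = dict(profile)
    cov["serum_ferritin"] = serum_ferritin
    cov["tea_cups"] = profile["polyphenols"] / polyphenol_mg_per_cup
    if spec["form"] == "loglinear":
        acc = float(spec["intercept"])
        for term in spec["terms"]:
            x = cov[term["covariate"]] + float(term.get("offset", 0.0))
            if term["transform"] == "log":
                x = math.log(x)
            acc += float(term["coefficient"]) * x
        value = math.exp(acc)
    else:
        enh = sum(
            float(e["amplitude"])
            * cov[e["covariate"]]
            / (cov[e["covariate"]] + float(e["half_saturation"]))
            for e in spec.get("enhancers", [])
        )
        inh = sum(
            float(e["amplitude"])
            * cov[e["covariate"]]
            / (cov[e["covariate"]] + float(e["half_saturation"]))
            for e in spec.get("inhibitors", [])
        )
        value = float(spec["baseline_fraction"]) * (1.0 + enh) / (1.0 + inh)
    if spec.get("output", "fraction") == "percent":
        value /= 100.0
    return min(max(value, 1e-3), 1.0)


def _gt_taz(zinc_mg: float, phytate_mg: float, params: bio.AbsorptionParams) -> float:
    tdz = zinc_mg / params.zinc_molar_mass
    tdp = phytate_mg / params.phytate_molar_mass
    a = params.miller_amax + tdz + params.miller_kr * (1.0 + tdp / params.miller_kp)
    return (
        0.5 * (a - math.sqrt(a * a - 4.0 * params.miller_amax * tdz))
    ) * params.zinc_molar_mass


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_world(spec: WorldSpec) -> World:
    """Generate a complete world and its ground truth.

    Raises if an adequacy target is infeasible (would require negative
    intake of the adjuster food).
    """
    rng = np.random.default_rng(spec.seed)
    countries = [f"C{i+1:02d}" for i in range(spec.n_countries)]
    country_regions = {
        c: _REGIONS[i % len(_REGIONS)] for i, c in enumerate(countries)
    }
    rice_country = countries[1 % len(countries)]  # the "parboiled rice" country

    categories = _base_categories(spec.n_filler_fcs)
    taxonomy = Taxonomy(categories)
    fsg_of = {c.fc_code: c.fsg_code for c in categories}
    comp = _compositions(rng, spec.n_filler_fcs)
    fco_candidates = _fco_candidate_sets(rng)
    # FCO intended composition = mean of its candidates (the collapse rule).
    for fco, cand in fco_candidates.items():
        comp[(fco, "base")] = {n: float(cand[n].mean()) for n in NUTRIENTS}

    # FCT item matches: symmetric pairs around the intended value for plain
    # FCs, and the candidate items themselves for FCOs.
    item_rows = []
    for (fc, variant), vector in comp.items():
        if fc in fco_candidates and variant == "base":
            for i, (_, cand) in enumerate(fco_candidates[fc].iterrows()):
                item_rows.append(
                    {"fc_code": fc, "variant": variant, "item_id": f"{fc}_{i}"}
                    | {n: float(cand[n]) for n in NUTRIENTS}
                )
        else:
            for factor, tag in ((0.8, "lo"), (1.2, "hi")):
                item_rows.append(
                    {"fc_code": fc, "variant": variant, "item_id": f"{fc}_{tag}"}
                    | {n: vector[n] * factor for n in NUTRIENTS}
                )
    fct_items = pd.DataFrame(item_rows)

    split = CerealSplitSpec(
        cereal="wheat",
        region="*",
        refined_proportion=0.8,
        refined_extraction=0.72,
        whole_extraction=1.0,
        refined_fc="wheat_flour_refined",
        whole_fc="wheat_flour_whole",
    )
    cereal_splits = [
        CerealSplitSpec(
            "wheat", region, 0.8, 0.72, 1.0, "wheat_flour_refined", "wheat_flour_whole"
        )
        for region in _REGIONS
    ]
    flw_records = [
        FlwRecord(region, fsg, p, r, c)
        for region in _REGIONS
        for fsg, (p, r, c) in _FLW_BY_FSG.items()
    ] + [
        FlwRecord(region, fsg, exempt=True)
        for region in _REGIONS
        for fsg in _FLW_EXEMPT_FSGS
    ]
    override_rules = OverrideRules(
        [
            OverrideRule(
                name="red_palm_oil_domestic",
                fc_code="palm_oil",
                countries=frozenset(
                    c for c, r in country_regions.items() if r == "ssa_trop"
                ),
                flow_roles=frozenset({"domestic_retained"}),
                action="blend",
                variant="red_palm",
                weight=0.70,
            ),
            OverrideRule(
                name="parboiled_rice",
                fc_code="rice",
                countries=frozenset({rice_country}),
                flow_roles=frozenset({"domestic_retained", "export", "import"}),
                action="replace",
                variant="parboiled_white",
            ),
        ],
        known_countries=countries,
    )

    # Demographics → population.
    demo_rows, repro_rows, pop = [], [], {}
    for country in countries:
        scale = rng.uniform(1e6, 8e6)
        for year in spec.years:
            growth = 1.0 + 0.1 * spec.years.index(year)
            weights = {
                (2, "M"): 0.05, (2, "F"): 0.05, (8, "M"): 0.06, (8, "F"): 0.06,
                (25, "M"): 0.10, (25, "F"): 0.10, (30, "M"): 0.10, (30, "F"): 0.10,
                (40, "M"): 0.12, (40, "F"): 0.12, (70, "M"): 0.07, (70, "F"): 0.07,
            }
            total = 0.0
            for (age, sex), w in weights.items():
                count = float(np.round(scale * growth * w))
                demo_rows.append(
                    {"country": country, "year": year, "age": age, "sex": sex, "count": count}
                )
                total += count
            pop[(country, year)] = total
            births = float(np.round(total * 0.018))
            repro_rows.append(
                {
                    "country": country,
                    "year": year,
                    "live_births": births,
                    "induced_abortions": float(np.round(births * 0.1)),
                    "miscarriages": float(np.round(births * 0.05)),
                }
            )
    demographics = pd.DataFrame(demo_rows)
    reproductive = pd.DataFrame(repro_rows)
    population = pd.DataFrame(
        [
            {"country": c, "year": y, "population": p}
            for (c, y), p in pop.items()
        ]
    )
    drvs = _drv_table()
    body_weights = _body_weights()

    # NNRD ground truth (needed before target inversion).
    nnrd_rows = []
    cells_by_cy = {}
    for country in countries:
        for year in spec.years:
            dr = [r for r in demo_rows if r["country"] == country and r["year"] == year]
            rr = next(
                r for r in repro_rows if r["country"] == country and r["year"] == year
            )
            cells = _gt_cells(
                dr, rr["live_births"], rr["induced_abortions"], rr["miscarriages"]
            )
            cells_by_cy[(country, year)] = cells
            for nutrient in PLAIN_ADEQUACY_NUTRIENTS:
                req = _gt_weighted_requirement(cells, drvs, nutrient, "auto", body_weights)
                nnrd_rows.append(
                    {"country": country, "year": year, "nutrient": nutrient,
                     "requirement": req, "standard_used": "AI" if nutrient == "vitamin_c" else "AR"}
                )
            for nutrient, label in (("iron", "iron_bioavailable"), ("zinc", "zinc_absorbed")):
                req = _gt_weighted_requirement(
                    cells, drvs, nutrient, "physiological", body_weights
                )
                nnrd_rows.append(
                    {"country": country, "year": year, "nutrient": label,
                     "requirement": req, "standard_used": "physiological"}
                )
    nnrd_gt = pd.DataFrame(nnrd_rows)

    # Baseline flows.
    flow_rows: list[dict] = []
    food_fcs = list(_FOOD_G_DAY) + [f"filler_{i}" for i in range(spec.n_filler_fcs)]
    fco_set = set(fco_candidates)
    for country in countries:
        for year in spec.years:
            p = pop[(country, year)]
            g_targets = {}
            for fc in food_fcs:
                lo, hi = _FOOD_G_DAY.get(fc, (5, 30))
                g_targets[fc] = float(rng.uniform(lo, hi))
            # Scale FCO food masses to the requested share of total food mass.
            non_fco = sum(g for fc, g in g_targets.items() if fc not in fco_set)
            fco_now = sum(g for fc, g in g_targets.items() if fc in fco_set)
            f = spec.fco_mass_fraction
            scale_fco = f / (1.0 - f) * non_fco / fco_now
            for fc in g_targets:
                if fc in fco_set:
                    g_targets[fc] *= scale_fco
            for fc, g in g_targets.items():
                qty_food = g * p * DAYS / 1e9
                flow_rows.append(
                    {"country": country, "year": year, "fc_code": fc,
                     "element": "food", "qty_1000mt": qty_food}
                )
                flow_rows.append(
                    {"country": country, "year": year, "fc_code": fc,
                     "element": "production",
                     "qty_1000mt": qty_food * float(rng.uniform(0.5, 3.0))}
                )
                flow_rows.append(
                    {"country": country, "year": year, "fc_code": fc,
                     "element": "imports",
                     "qty_1000mt": qty_food * float(rng.uniform(0.0, 0.5))}
                )
                flow_rows.append(
                    {"country": country, "year": year, "fc_code": fc,
                     "element": "exports",
                     "qty_1000mt": qty_food * float(rng.uniform(0.0, 0.4))}
                )

    # Target-adequacy inversion: set the adjuster FC's food quantity so that
    # final-best apparent intake of the target nutrient hits the requested
    # percent of requirement.
    req_lookup = nnrd_gt.set_index(["country", "year", "nutrient"])["requirement"]
    for (country, nutrient), target_pct in spec.adequacy_targets.items():
        if country not in countries:
            raise ValueError(f"unknown target country {country!r}")
        for year in spec.years:
            current = 0.0
            for fr in flow_rows:
                if (
                    fr["country"] != country
                    or fr["year"] != year
                    or fr["element"] != "food"
                ):
                    continue
                rows = _gt_nutrient_rows(
                    [fr], pop, comp, country_regions, rice_country, fsg_of, split
                )
                current += sum(
                    r["value"]
                    for r in rows
                    if r["variant"] == "final_best" and r["nutrient"] == nutrient
                )
            req = float(req_lookup.loc[(country, year, nutrient)])
            needed = target_pct / 100.0 * req
            extra = needed - current
            if extra < 0:
                raise ValueError(
                    f"adequacy target infeasible for ({country}, {nutrient}): "
                    f"baseline intake already exceeds the target"
                )
            adj_fc = f"adj_{nutrient}"
            flw_ret = _gt_flw_retention(fsg_of[adj_fc])
            mass = extra / (_ADJUSTER_COMP[nutrient] / 100.0 * flw_ret)
            flow_rows.append(
                {"country": country, "year": year, "fc_code": adj_fc,
                 "element": "food", "qty_1000mt": mass * pop[(country, year)] * DAYS / 1e9}
            )

    flows = pd.DataFrame(flow_rows)

    # -------------------------------------------------------------------
    # Ground truth from the final flow table.
    # -------------------------------------------------------------------
    gt_rows = _gt_nutrient_rows(
        flow_rows, pop, comp, country_regions, rice_country, fsg_of, split
    )
    nutrient_table = pd.DataFrame(gt_rows)

    def _totals(element: str, exclude_processed: bool) -> pd.DataFrame:
        acc: dict = {}
        for r in gt_rows:
            if r["element"] != element:
                continue
            if exclude_processed and taxonomy[r["source_fc"]].is_processed_food:
                continue
            key = (r["country"], r["year"], r["variant"], r["nutrient"])
            acc[key] = acc.get(key, 0.0) + r["value"]
        return pd.DataFrame(
            [
                {"country": c, "year": y, "variant": v, "nutrient": n, "value": val}
                for (c, y, v, n), val in acc.items()
            ]
        )

    production_totals = _totals("production", exclude_processed=True)
    intake_totals = _totals("food", exclude_processed=False)

    # Diet profiles and bioavailability on the final-best intake.
    params = bio.default_params()
    bio_rows, adequacy_rows = [], []
    intake_fb = intake_totals[intake_totals["variant"] == "final_best"]
    for country in countries:
        for year in spec.years:
            sub = intake_fb[(intake_fb["country"] == country) & (intake_fb["year"] == year)]
            totals = {r.nutrient: r.value for r in sub.itertuples(index=False)}
            # Per-FC iron and edible HSI mass on the final-best food element.
            iron_by_fc: dict = {}
            mfp = 0.0
            for r in gt_rows:
                if (
                    r["country"] == country
                    and r["year"] == year
                    and r["element"] == "food"
                    and r["variant"] == "final_best"
                    and r["nutrient"] == "iron"
                ):
                    iron_by_fc[r["fc_code"]] = (
                        iron_by_fc.get(r["fc_code"], 0.0) + r["value"]
                    )
            for fr in flow_rows:
                if (
                    fr["country"] == country
                    and fr["year"] == year
                    and fr["element"] == "food"
                    and taxonomy[fr["fc_code"]].is_hsi
                ):
                    g = fr["qty_1000mt"] * 1e9 / (pop[(country, year)] * DAYS)
                    mfp += (
                        g
                        * (1.0 - _REFUSE.get(fr["fc_code"], 0.0))
                        * _gt_flw_retention(fsg_of[fr["fc_code"]])
                    )
            hsi_iron = sum(
                v
                for fc, v in iron_by_fc.items()
                if fc in taxonomy and taxonomy[fc].is_hsi
            )
            heme = params.heme_fraction * hsi_iron
            nonheme = sum(iron_by_fc.values()) - heme
            profile = {
                "nonheme_iron": nonheme,
                "heme_iron": heme,
                "vitamin_c": totals.get("vitamin_c", 0.0),
                "mfp": mfp,
                "phytate": totals.get("phytate", 0.0),
                "calcium": totals.get("calcium", 0.0),
                "polyphenols": totals.get("polyphenols", 0.0),
            }
            fractions = {
                alg: _gt_iron_algorithm(
                    profile,
                    params.iron_algorithms[alg],
                    params.serum_ferritin_ref,
                    params.polyphenol_mg_per_cup,
                )
                for alg in ("conway", "rickard", "armah")
            }
            taz = _gt_taz(
                totals.get("zinc", 0.0), totals.get("phytate", 0.0), params
            )
            bio_rows.append(
                {
                    "country": country,
                    "year": year,
                    "heme_iron": heme,
                    "nonheme_iron": nonheme,
                    "mfp_g": mfp,
                    **{f"fraction_{a}": f for a, f in fractions.items()},
                    **{
                        f"iron_bioavailable_{a}": heme * params.heme_bioavailability
                        + nonheme * f
                        for a, f in fractions.items()
                    },
                    "zinc_absorbed": taz,
                }
            )
            for nutrient in PLAIN_ADEQUACY_NUTRIENTS:
                req = float(req_lookup.loc[(country, year, nutrient)])
                value = totals.get(nutrient, 0.0)
                adequacy_rows.append(
                    {
                        "country": country, "year": year, "nutrient": nutrient,
                        "side": "apparent_intake", "pc_value": value,
                        "pc_requirement": req,
                        "percent_of_requirement": 100.0 * value / req,
                        "percent_gap": 100.0 * value / req - 100.0,
                    }
                )
            iron_bio = (
                heme * params.heme_bioavailability + nonheme * fractions["rickard"]
            )
            for label, value in (
                ("iron_bioavailable", iron_bio),
                ("zinc_absorbed", taz),
            ):
                req = float(req_lookup.loc[(country, year, label)])
                adequacy_rows.append(
                    {
                        "country": country, "year": year, "nutrient": label,
                        "side": "apparent_intake", "pc_value": value,
                        "pc_requirement": req,
                        "percent_of_requirement": 100.0 * value / req,
                        "percent_gap": 100.0 * value / req - 100.0,
                    }
                )
    bio_gt = pd.DataFrame(bio_rows)
    adequacy_gt = pd.DataFrame(adequacy_rows)

    # Deficit summaries per nutrient-year.
    deficit_rows = []
    for nutrient in ("vitamin_a", "iron_bioavailable", "zinc_absorbed"):
        for year in spec.years:
            sub = adequacy_gt[
                (adequacy_gt["nutrient"] == nutrient) & (adequacy_gt["year"] == year)
            ]
            deficit_countries = []
            intake = req_agg = deficit = 0.0
            for r in sub.itertuples(index=False):
                if r.pc_value < r.pc_requirement:
                    p = pop[(r.country, year)]
                    deficit_countries.append(r.country)
                    intake += r.pc_value * p
                    req_agg += r.pc_requirement * p
                    deficit += (r.pc_requirement - r.pc_value) * p * DAYS
            deficit_rows.append(
                {
                    "nutrient": nutrient,
                    "year": year,
                    "n_deficit_countries": len(deficit_countries),
                    "deficit_countries": ";".join(sorted(deficit_countries)),
                    "aggregate_intake_per_day": intake,
                    "aggregate_requirement_per_day": req_agg,
                    "annual_deficit": deficit,
                }
            )
    deficits_gt = pd.DataFrame(deficit_rows)

    # FCO mass shares actually realised (food element).
    share_rows = []
    for country in countries:
        for year in spec.years:
            tot = fco = 0.0
            for fr in flow_rows:
                if (
                    fr["country"] != country
                    or fr["year"] != year
                    or fr["element"] != "food"
                ):
                    continue
                tot += fr["qty_1000mt"]
                if fr["fc_code"] in fco_set:
                    fco += fr["qty_1000mt"]
            share_rows.append(
                {"country": country, "year": year, "fco_share": fco / tot}
            )
    fco_share_gt = pd.DataFrame(share_rows)

    ground_truth = {
        "nutrient_table": nutrient_table,
        "production_totals": production_totals,
        "intake_totals": intake_totals,
        "nnrd": nnrd_gt,
        "bioavailability": bio_gt,
        "adequacy": adequacy_gt,
        "deficits": deficits_gt,
        "fco_share": fco_share_gt,
    }

    return World(
        spec=spec,
        taxonomy=taxonomy,
        fct_items=fct_items,
        composition=comp,
        refuse=RefuseTable(_REFUSE),
        processing=ProcessingFactors(_PROCESSING),
        cooking=CookingRetention(_COOKING),
        flw=FlwTable(flw_records),
        cereal_splits=cereal_splits,
        override_rules=override_rules,
        country_regions=country_regions,
        flows=flows,
        population=population,
        demographics=demographics,
        reproductive=reproductive,
        drvs=drvs,
        body_weights=body_weights,
        fco_candidates=fco_candidates,
        ground_truth=ground_truth,
    )
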