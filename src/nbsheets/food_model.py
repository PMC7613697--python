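"""Food classification hierarchy and composition/factor tables.

The accounting engine organises national food supplies in a four-level
hierarchy: individual food products roll up into ~98 food categories (FC),
food categories into ~21 subgroups (FSG), and subgroups into four reporting
groups (FG): starchy staples, nutrient-dense vegetal foods, animal-source
foods and other foods.  One FC inside many subgroups is a catch-all "other /
not elsewhere specified" category (FCO) whose composition is uncertain; flags
also mark fruits and vegetables (FV) and heme-iron sources (HSI).

This module holds the taxonomy, the food composition table (nutrients per
100 g edible portion), refuse fractions, processing mass factors, cooking
retention factors and regional food loss & waste (FLW) fractions, together
with the rules that resolve an (FC, country, flow role) triple to a nutrient
vector — including config-driven country overrides such as red palm oil in
tropical-belt Sub-Saharan Africa and parboiled white rice in Bangladesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# Nutrient and taxonomy definitions
# ---------------------------------------------------------------------------

#: Units a nutrient may be expressed in (per 100 g edible portion).
NUTRIENT_UNITS = frozenset({"kcal", "g", "mg", "mcg", "mcg_RAE", "IU_free"})

#: Bases on which a per-capita requirement may be defined.
REQUIREMENT_BASES = frozenset({"AR", "AI", "RI", "physiological", "none"})

#: The four reporting food groups.
FOOD_GROUPS = frozenset(
    {"starchy_staples", "nutrient_dense_vegetal", "animal_source", "other"}
)

BASE_VARIANT = "base"


@dataclass(frozen=True)
class NutrientDef:
    """Definition of one tracked nutrient or antinutrient."""

    code: str
    name: str
    unit: str
    is_antinutrient: bool = False
    requirement_basis: str = "AR"

    def __post_init__(self) -> None:
        if self.unit not in NUTRIENT_UNITS:
            raise ValueError(f"unknown unit {self.unit!r} for nutrient {self.code}")
        if self.requirement_basis not in REQUIREMENT_BASES:
            raise ValueError(
                f"unknown requirement basis {self.requirement_basis!r} "
                f"for nutrient {self.code}"
            )


@dataclass(frozen=True)
class FoodCategory:
    """One food category (FC) with its subgroup/group membership and flags."""

    fc_code: str
    name: str
    fsg_code: str
    fg_code: str
    is_fco: bool = False
    is_fv: bool = False
    is_hsi: bool = False
    is_processed_food: bool = False
    cpc_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.fg_code not in FOOD_GROUPS:
            raise ValueError(
                f"FC {self.fc_code}: unknown food group {self.fg_code!r}"
            )


class Taxonomy:
    """The FC → FSG → FG hierarchy with dummy-variable flags.

    Parameters
    ----------
    categories
        Food category records.  ``fc_code`` must be unique.
    """

    def __init__(self, categories: Iterable[FoodCategory]):
        cats = list(categories)
        codes = [c.fc_code for c in cats]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise ValueError(f"duplicate fc_codes in taxonomy: {sorted(dupes)}")
        self._by_code: dict[str, FoodCategory] = {c.fc_code: c for c in cats}

    def __contains__(self, fc_code: str) -> bool:
        return fc_code in self._by_code

    def __iter__(self):
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    def __getitem__(self, fc_code: str) -> FoodCategory:
        try:
            return self._by_code[fc_code]
        except KeyError:
            raise KeyError(f"unknown food category {fc_code!r}") from None

    @property
    def fc_codes(self) -> list[str]:
        return list(self._by_code)

    def fsg(self, fc_code: str) -> str:
        return self[fc_code].fsg_code

    def is_hsi(self, fc_code: str) -> bool:
        return self[fc_code].is_hsi

    def frame(self) -> pd.DataFrame:
        """Taxonomy as a DataFrame (one row per FC)."""
        rows = [
            {
                "fc_code": c.fc_code,
                "name": c.name,
                "fsg_code": c.fsg_code,
                "fg_code": c.fg_code,
                "is_fco": c.is_fco,
                "is_fv": c.is_fv,
                "is_hsi": c.is_hsi,
                "is_processed_food": c.is_processed_food,
                "cpc_codes": ";".join(c.cpc_codes),
            }
            for c in self
        ]
        return pd.DataFrame(rows)


def validate_taxonomy(categories: Iterable[FoodCategory]) -> list[str]:
    """Report structural problems in a taxonomy (report-only, never raises).

    Checks: duplicate FC codes, unknown food groups, subgroups with more than
    one catch-all FCO, and heme-iron flags outside animal-source foods.
    """
    cats = list(categories)
    findings: list[str] = []

    seen: dict[str, FoodCategory] = {}
    for c in cats:
        if c.fc_code in seen:
            findings.append(f"duplicate fc_code {c.fc_code!r}")
        seen[c.fc_code] = c
        if c.fg_code not in FOOD_GROUPS:
            findings.append(f"FC {c.fc_code}: unknown food group {c.fg_code!r}")
        if c.is_hsi and c.fg_code != "animal_source":
            findings.append(
                f"FC {c.fc_code}: heme-iron flag on non-animal-source food "
                f"(fg={c.fg_code})"
            )

    fco_by_fsg: dict[str, list[str]] = {}
    for c in cats:
        if c.is_fco:
            fco_by_fsg.setdefault(c.fsg_code, []).append(c.fc_code)
    for fsg, fcos in fco_by_fsg.items():
        if len(fcos) > 1:
            findings.append(f"FSG {fsg}: multiple FCO categories {sorted(fcos)}")

    return findings


# ---------------------------------------------------------------------------
# Composition table
# ---------------------------------------------------------------------------


class CompositionTable:
    """Nutrients per 100 g edible portion, keyed by (fc_code, variant).

    ``variant`` distinguishes alternative composition records for the same
    category — e.g. refined vs red palm oil, or Bangladesh's parboiled white
    rice.  The default record carries variant ``"base"``.

    Attributes
    ----------
    values : pandas.DataFrame
        Indexed by (fc_code, variant); columns are nutrient codes.
    imputed : pandas.DataFrame
        Boolean mask aligned with ``values``; True where a missing source
        value was imputed at its lower bound of zero.
    n_source_items : pandas.Series
        Number of food-item matches averaged into each record.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        imputed: pd.DataFrame | None = None,
        n_source_items: pd.Series | None = None,
    ):
        if values.index.nlevels == 1:
            values = values.copy()
            values.index = pd.MultiIndex.from_arrays(
                [values.index, [BASE_VARIANT] * len(values)],
                names=["fc_code", "variant"],
            )
        values.index.names = ["fc_code", "variant"]
        if (values.to_numpy() < 0).any():
            raise ValueError("composition values must be non-negative")
        self.values = values.sort_index()
        if imputed is None:
            imputed = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        self.imputed = imputed.reindex(self.values.index).fillna(False)
        if n_source_items is None:
            n_source_items = pd.Series(1, index=self.values.index)
        self.n_source_items = n_source_items.reindex(self.values.index).fillna(1)

    @property
    def nutrients(self) -> list[str]:
        return list(self.values.columns)

    def has(self, fc_code: str, variant: str = BASE_VARIANT) -> bool:
        return (fc_code, variant) in self.values.index

    def record(self, fc_code: str, variant: str = BASE_VARIANT) -> pd.Series:
        try:
            return self.values.loc[(fc_code, variant)]
        except KeyError:
            raise KeyError(
                f"no composition record for FC {fc_code!r} variant {variant!r}"
            ) from None


def collapse_fct(
    item_matches: pd.DataFrame,
    required_fcs: Sequence[str] | None = None,
) -> CompositionTable:
    """Collapse food-item matches to one composition record per FC.

    Each FC's record is the arithmetic mean of its item matches, nutrient by
    nutrient.  Missing source values are set at their lower bound of zero
    before averaging and flagged as imputed in the result.

    Parameters
    ----------
    item_matches
        One row per food-item match with columns ``fc_code``, optionally
        ``variant``, and one column per nutrient code.  Missing values are
        NaN.
    required_fcs
        FC codes that must be present; an FC with zero matches raises.
    """
    if "fc_code" not in item_matches.columns:
        raise ValueError("item_matches must have an fc_code column")
    matches = item_matches.copy()
    if "variant" not in matches.columns:
        matches["variant"] = BASE_VARIANT
    nutrient_cols = [
        c for c in matches.columns if c not in ("fc_code", "variant", "item_id")
    ]
    if required_fcs is not None:
        missing = sorted(set(required_fcs) - set(matches["fc_code"]))
        if missing:
            raise ValueError(
                f"no composition matches for food categories: {missing}"
            )

    grouped = matches.groupby(["fc_code", "variant"], sort=True)
    was_nan = matches[nutrient_cols].isna()
    filled = matches[nutrient_cols].fillna(0.0)
    values = filled.groupby(
        [matches["fc_code"], matches["variant"]], sort=True
    ).mean()
    values.index.names = ["fc_code", "variant"]
    imputed = was_nan.groupby(
        [matches["fc_code"], matches["variant"]], sort=True
    ).any()
    imputed.index.names = ["fc_code", "variant"]
    n_items = grouped.size()
    n_items.name = "n_source_items"
    return CompositionTable(values, imputed=imputed, n_source_items=n_items)


# ---------------------------------------------------------------------------
# Factor tables
# ---------------------------------------------------------------------------


class RefuseTable:
    """Inedible (refuse) fraction per FC; unmatched categories default to 0."""

    def __init__(self, fractions: Mapping[str, float]):
        for fc, r in fractions.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"refuse fraction for {fc} out of [0,1): {r}")
        self._fractions = dict(fractions)

    def get(self, fc_code: str) -> float:
        return self._fractions.get(fc_code, 0.0)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fc_code": list(self._fractions), "refuse_fraction": list(self._fractions.values())}
        )


class ProcessingFactors:
    """Primary-commodity → as-consumed mass multipliers (tea may exceed 1)."""

    def __init__(self, factors: Mapping[str, float]):
        for fc, f in factors.items():
            if not f > 0:
                raise ValueError(f"processing factor for {fc} must be > 0: {f}")
        self._factors = dict(factors)

    def get(self, fc_code: str) -> float:
        return self._factors.get(fc_code, 1.0)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fc_code": list(self._factors), "factor": list(self._factors.values())}
        )


class CookingRetention:
    """Per-(FC, nutrient) cooking retention fractions; unmatched default to 1."""

    def __init__(self, retention: Mapping[tuple[str, str], float]):
        for (fc, nut), r in retention.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(
                    f"cooking retention for ({fc},{nut}) out of [0,1]: {r}"
                )
        self._retention = dict(retention)

    def get(self, fc_code: str, nutrient: str) -> float:
        return self._retention.get((fc_code, nutrient), 1.0)

    def vector(self, fc_code: str, nutrients: Sequence[str]) -> np.ndarray:
        return np.array([self.get(fc_code, n) for n in nutrients])

    def frame(self) -> pd.DataFrame:
        rows = [
            {"fc_code": fc, "nutrient": nut, "retention": r}
            for (fc, nut), r in self._retention.items()
        ]
        return pd.DataFrame(rows, columns=["fc_code", "nutrient", "retention"])


@dataclass(frozen=True)
class FlwRecord:
    """Food loss & waste fractions for one (region, FSG) cell.

    Post-harvest loss applies to fish/seafood subgroups only (a property of
    the source data, carried as-is); exempt subgroups (sugar crops, sugars,
    pulses, treenuts, vegetable oils, stimulants, spices, alcohol, animal
    fats, infant foods) are treated as lossless.
    """

    region_code: str
    fsg_code: str
    postharvest_loss_fraction: float = 0.0
    retail_waste_fraction: float = 0.0
    consumption_waste_fraction: float = 0.0
    exempt: bool = False

    def __post_init__(self) -> None:
        for name in (
            "postharvest_loss_fraction",
            "retail_waste_fraction",
            "consumption_waste_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} out of [0,1): {v}")

    @property
    def retention(self) -> float:
        """Mass fraction surviving all FLW stages."""
        if self.exempt:
            return 1.0
        return (
            (1.0 - self.postharvest_loss_fraction)
            * (1.0 - self.retail_waste_fraction)
            * (1.0 - self.consumption_waste_fraction)
        )


class FlwTable:
    """FLW retention lookup by (region, FSG); unmatched cells default to 1."""

    def __init__(self, records: Iterable[FlwRecord]):
        self._records = {(r.region_code, r.fsg_code): r for r in records}

    def retention(self, region_code: str, fsg_code: str) -> float:
        rec = self._records.get((region_code, fsg_code))
        return 1.0 if rec is None else rec.retention

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "region_code": r.region_code,
                "fsg_code": r.fsg_code,
                "postharvest_loss_fraction": r.postharvest_loss_fraction,
                "retail_waste_fraction": r.retail_waste_fraction,
                "consumption_waste_fraction": r.consumption_waste_fraction,
                "exempt": r.exempt,
            }
            for r in self._records.values()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Country composition overrides
# ---------------------------------------------------------------------------

#: Roles a commodity flow can play when resolving composition.
FLOW_ROLES = frozenset({"domestic_retained", "export", "import"})


@dataclass(frozen=True)
class OverrideRule:
    """A config-driven composition override.

    ``action`` is ``blend`` (weight × variant + (1−weight) × base) or
    ``replace`` (use the variant record outright).
    """

    name: str
    fc_code: str
    countries: frozenset[str]
    flow_roles: frozenset[str]
    action: str
    variant: str
    weight: float = 1.0

    def matches(self, fc_code: str, country: str, flow_role: str) -> bool:
        return (
            fc_code == self.fc_code
            and country in self.countries
            and flow_role in self.flow_roles
        )


class OverrideRules:
    """Ordered set of composition override rules plus named country lists."""

    def __init__(
        self,
        rules: Sequence[OverrideRule],
        known_countries: Iterable[str] | None = None,
    ):
        self.rules = list(rules)
        self.known_countries = (
            None if known_countries is None else frozenset(known_countries)
        )

    @classmethod
    def from_config(cls, config: Mapping) -> "OverrideRules":
        """Build rules from a parsed YAML mapping.

        Expected shape::

            country_lists:
              tropical_belt_ssa: [NGA, GHA, ...]
            rules:
              - name: red_palm_oil_domestic
                fc_code: palm_oil
                countries: {list_ref: tropical_belt_ssa}
                flow_roles: [domestic_retained]
                action: {type: blend, variant: red_palm, weight: 0.70}
        """
        lists = {k: list(v) for k, v in (config.get("country_lists") or {}).items()}
        rules = []
        for raw in config.get("rules") or []:
            spec = raw["countries"]
            if "list_ref" in spec:
                countries = lists[spec["list_ref"]]
            else:
                countries = spec["list"]
            action = raw["action"]
            rules.append(
                OverrideRule(
                    name=raw["name"],
                    fc_code=raw["fc_code"],
                    countries=frozenset(countries),
                    flow_roles=frozenset(raw["flow_roles"]),
                    action=action["type"],
                    variant=action["variant"],
                    weight=float(action.get("weight", 1.0)),
                )
            )
        return cls(rules)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OverrideRules":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh) or {})

    @classmethod
    def none(cls) -> "OverrideRules":
        return cls([])


def default_override_rules() -> OverrideRules:
    """The shipped override rules (red palm oil, Bangladesh rice)."""
    path = Path(__file__).parent / "data" / "composition_overrides.yaml"
    return OverrideRules.from_yaml(path)


def resolve_composition(
    fct: CompositionTable,
    fc_code: str,
    country: str,
    flow_role: str = "domestic_retained",
    rules: OverrideRules | None = None,
) -> pd.Series:
    """Resolve an (FC, country, flow role) triple to a per-100 g nutrient vector.

    Returns the base record unless an override rule fires.  The shipped rules
    blend 70% red palm oil into domestically retained palm oil in tropical-belt
    Sub-Saharan African countries (exports and imports stay refined) and use a
    parboiled-white-only rice record for Bangladesh.
    """
    if flow_role not in FLOW_ROLES:
        raise ValueError(f"unknown flow role {flow_role!r}")
    if not fct.has(fc_code):
        raise KeyError(f"unknown food category {fc_code!r}")
    if rules is not None and rules.known_countries is not None:
        if country not in rules.known_countries:
            raise KeyError(f"unknown country {country!r}")

    base = fct.record(fc_code)
    if rules is None:
        return base
    for rule in rules.rules:
        if not rule.matches(fc_code, country, flow_role):
            continue
        alt = fct.record(fc_code, rule.variant)
        if rule.action == "replace":
            return alt
        if rule.action == "blend":
            return rule.weight * alt + (1.0 - rule.weight) * base
        raise ValueError(f"unknown override action {rule.action!r}")
    return base
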