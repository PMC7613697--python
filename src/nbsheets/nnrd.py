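"""National Nutrient Requirement Database (NNRD).

Crosses country demographic counts (1-year age × sex, plus estimated numbers
of pregnant and lactating women) with dietary reference values (DRVs) to
produce demographically weighted per-capita daily requirements per
country-year-nutrient.

The weighting standard follows the EFSA convention: the Average Requirement
(AR) where one exists, otherwise the Adequate Intake (AI); Reference Intake
range endpoints for carbohydrate and fat; and median physiological (absorbed)
requirements for iron and zinc wherever intakes are bioavailability-adjusted.
Protein requirements are specified per kg of body weight and converted using
reference body weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: DRV value types.
VALUE_TYPES = frozenset({"AR", "AI", "RI_low", "RI_high", "physiological"})

#: Reproductive age range from which pregnant/lactating women are drawn.
MATERNAL_AGE_RANGE = (15, 49)


@dataclass(frozen=True)
class ReproductiveStats:
    """Annual counts of pregnancy outcomes for one country-year."""

    live_births: float
    induced_abortions: float = 0.0
    miscarriages: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"ReproductiveStats.{name} must be non-negative")


@dataclass(frozen=True)
class PregnancyDurations:
    """Year-fraction durations weighting each pregnancy outcome.

    Defaults assume a 40-week term pregnancy and 10 weeks for pregnancies
    ending in induced abortion or miscarriage; fully configurable since the
    underlying surveillance method does not fix the constants.
    """

    d_birth: float = 40.0 / 52.0
    d_abortion: float = 10.0 / 52.0
    d_miscarriage: float = 10.0 / 52.0


def estimate_pregnant(
    stats: ReproductiveStats, durations: PregnancyDurations | None = None
) -> float:
    """Duration-weighted expected number of currently pregnant women."""
    d = durations or PregnancyDurations()
    return (
        stats.live_births * d.d_birth
        + stats.induced_abortions * d.d_abortion
        + stats.miscarriages * d.d_miscarriage
    )


def estimate_lactating(live_births: float, lactation_years: float = 0.5) -> float:
    """Lactating women = live births × average constant-production period (6 mo)."""
    if live_births < 0:
        raise ValueError("live_births must be non-negative")
    return live_births * lactation_years


def infants_0_5_months(
    live_births: float, exclusive_breastfeeding_fraction: float = 1.0
) -> float:
    """Infants aged 0-5 months, equated to exclusively breastfeeding mothers."""
    return estimate_lactating(live_births) * exclusive_breastfeeding_fraction


# ---------------------------------------------------------------------------
# Demographic reallocation
# ---------------------------------------------------------------------------


def reallocate_reproductive(
    cells: pd.DataFrame,
    n_pregnant: float,
    n_lactating: float,
    age_range: tuple[int, int] = MATERNAL_AGE_RANGE,
) -> pd.DataFrame:
    """Move pregnant/lactating women out of their base female age cells.

    Counts are drawn proportionally from female cells in ``age_range`` and
    added back as dedicated pregnant / lactating rows, conserving the total
    population.  ``cells`` has columns ``age, sex, count``.

    Returns a DataFrame with columns ``age, sex, pregnant, lactating, count``.
    """
    out = cells.copy()
    if (out["count"] < 0).any():
        raise ValueError("demographic counts must be non-negative")
    out["pregnant"] = False
    out["lactating"] = False

    needed = n_pregnant + n_lactating
    if needed < 0:
        raise ValueError("pregnant/lactating counts must be non-negative")
    lo, hi = age_range
    mask = (out["sex"] == "F") & out["age"].between(lo, hi)
    pool = out.loc[mask, "count"].sum()
    if needed > 0:
        if pool <= 0 or needed > pool:
            raise ValueError(
                f"pregnant+lactating ({needed:g}) exceeds female population "
                f"aged {lo}-{hi} ({pool:g})"
            )
        out.loc[mask, "count"] -= out.loc[mask, "count"] / pool * needed
    mid_age = (lo + hi) // 2
    extra = pd.DataFrame(
        {
            "age": [mid_age, mid_age],
            "sex": ["F", "F"],
            "pregnant": [True, False],
            "lactating": [False, True],
            "count": [n_pregnant, n_lactating],
        }
    )
    return pd.concat([out, extra], ignore_index=True)


# ---------------------------------------------------------------------------
# DRV matching and weighting
# ---------------------------------------------------------------------------

_DRV_COLUMNS = [
    "nutrient",
    "age_min",
    "age_max",
    "sex",
    "pregnant",
    "lactating",
    "value_type",
    "value",
    "basis",
]


def _match_drv(cell, drvs: pd.DataFrame) -> pd.DataFrame:
    """DRV rows applicable to one demographic cell."""
    if cell.pregnant:
        return drvs[drvs["pregnant"]]
    if cell.lactating:
        return drvs[drvs["lactating"]]
    m = (
        ~drvs["pregnant"]
        & ~drvs["lactating"]
        & (drvs["age_min"] <= cell.age)
        & (cell.age <= drvs["age_max"])
        & drvs["sex"].isin([cell.sex, "any"])
    )
    return drvs[m]


def _reference_weight(cell, body_weights: pd.DataFrame | None) -> float:
    if body_weights is None:
        raise ValueError("per-kg DRV basis requires reference body weights")
    m = (
        (body_weights["age_min"] <= cell.age)
        & (cell.age <= body_weights["age_max"])
        & body_weights["sex"].isin([cell.sex, "any"])
    )
    rows = body_weights[m]
    if rows.empty:
        raise ValueError(
            f"no reference body weight for age {cell.age}, sex {cell.sex}"
        )
    return float(rows["weight_kg"].iloc[0])


def weighted_requirement(
    cells: pd.DataFrame,
    drvs: pd.DataFrame,
    nutrient: str,
    standard: str = "auto",
    body_weights: pd.DataFrame | None = None,
) -> tuple[float, str]:
    """Population-weighted per-capita daily requirement for one nutrient.

    Parameters
    ----------
    cells
        Demographic cells with columns ``age, sex, pregnant, lactating,
        count`` (see :func:`reallocate_reproductive`).
    drvs
        Long DRV table with columns ``nutrient, age_min, age_max, sex,
        pregnant, lactating, value_type, value, basis``.
    nutrient
        Nutrient code to weight.
    standard
        ``"auto"`` uses the AR if the nutrient has any AR rows, else the AI;
        an explicit value type (``physiological``, ``RI_low``, ...) selects
        that standard.
    body_weights
        Reference body weights (``age_min, age_max, sex, weight_kg``) for
        per-kg DRV bases.

    Returns
    -------
    (requirement, standard_used)
    """
    rows = drvs[drvs["nutrient"] == nutrient]
    if rows.empty:
        raise ValueError(f"no DRV rows for nutrient {nutrient!r}")
    if standard == "auto":
        used = "AR" if (rows["value_type"] == "AR").any() else "AI"
    else:
        if standard not in VALUE_TYPES:
            raise ValueError(f"unknown DRV standard {standard!r}")
        used = standard
    rows = rows[rows["value_type"] == used]
    if rows.empty:
        raise ValueError(f"nutrient {nutrient!r} has no {used} rows")

    total = cells["count"].sum()
    if total <= 0:
        raise ValueError("total population must be positive")
    acc = 0.0
    unmatched = []
    for cell in cells.itertuples(index=False):
        if cell.count == 0:
            continue
        match = _match_drv(cell, rows)
        if match.empty:
            unmatched.append(
                f"(age={cell.age}, sex={cell.sex}, pregnant={cell.pregnant}, "
                f"lactating={cell.lactating})"
            )
            continue
        rec = match.iloc[0]
        value = float(rec["value"])
        if rec["basis"] == "per_kg_bodyweight":
            value *= _reference_weight(cell, body_weights)
        elif rec["basis"] != "absolute_per_day":
            raise ValueError(f"unknown DRV basis {rec['basis']!r}")
        acc += cell.count * value
    if unmatched:
        raise ValueError(
            f"no {used} DRV match for nutrient {nutrient!r} in groups: "
            + "; ".join(unmatched)
        )
    return acc / total, used


def build_nnrd(
    demographics: pd.DataFrame,
    reproductive: pd.DataFrame,
    drvs: pd.DataFrame,
    nutrient_standards: Mapping[str, str],
    body_weights: pd.DataFrame | None = None,
    durations: PregnancyDurations | None = None,
) -> pd.DataFrame:
    """Assemble the NNRD for every country-year present in ``demographics``.

    Parameters
    ----------
    demographics
        Columns ``country, year, age, sex, count`` (1-year ages).
    reproductive
        Columns ``country, year, live_births, induced_abortions,
        miscarriages``.
    drvs
        Long DRV table (see :func:`weighted_requirement`).
    nutrient_standards
        Mapping nutrient code → standard ("auto", "physiological", ...).

    Returns
    -------
    DataFrame with columns ``country, year, nutrient, requirement,
    standard_used``.
    """
    repro = reproductive.set_index(["country", "year"])
    records = []
    for (country, year), group in demographics.groupby(["country", "year"]):
        cells = group[["age", "sex", "count"]].reset_index(drop=True)
        if (country, year) in repro.index:
            r = repro.loc[(country, year)]
            stats = ReproductiveStats(
                float(r["live_births"]),
                float(r.get("induced_abortions", 0.0)),
                float(r.get("miscarriages", 0.0)),
            )
            n_preg = estimate_pregnant(stats, durations)
            n_lact = estimate_lactating(stats.live_births)
        else:
            n_preg = n_lact = 0.0
        alloc = reallocate_reproductive(cells, n_preg, n_lact)
        for nutrient, standard in nutrient_standards.items():
            req, used = weighted_requirement(
                alloc, drvs, nutrient, standard, body_weights
            )
            records.append(
                {
                    "country": country,
                    "year": int(year),
                    "nutrient": nutrient,
                    "requirement": req,
                    "standard_used": used,
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["country", "year", "nutrient", "requirement", "standard_used"]
    )
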