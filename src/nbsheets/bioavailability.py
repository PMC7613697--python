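"""Iron and zinc bioavailability.

Total iron in national food supplies is split into heme and non-heme pools:
40% of iron in heme-source foods counts as heme, absorbed at a fixed 25%.
Non-heme absorption depends on the whole diet — enhanced by vitamin C and
meat/fish/poultry, inhibited by phytate, polyphenols and calcium — and is
predicted by one of three pluggable algorithms (Conway food-group regression,
Rickard saturable test-meal model, Armah complete-diet equation).  The Armah
equation also needs iron status; a constant serum ferritin of 21.7 mcg/L,
corresponding to 40% reference-dose absorption, stands in for population iron
status.

Absorbed zinc follows the updated Miller saturable-absorption model with
phytate inhibition: with total dietary zinc (TDZ) and phytate (TDP) in
mmol/day,

    TAZ = 0.5 * (A - sqrt(A^2 - 4*Amax*TDZ)),
    A   = Amax + TDZ + Kr*(1 + TDP/Kp).

All constants live in a versioned YAML parameter file.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

_FRACTION_FLOOR = 1e-3
_FRACTION_CEIL = 1.0

IRON_ALGORITHMS = ("conway", "rickard", "armah")


@dataclass(frozen=True)
class DietProfile:
    """Per-capita daily totals of absorption-relevant dietary quantities."""

    nonheme_iron: float = 0.0  # mg/day
    heme_iron: float = 0.0     # mg/day
    zinc: float = 0.0          # mg/day
    phytate: float = 0.0       # mg/day
    calcium: float = 0.0       # mg/day
    vitamin_c: float = 0.0     # mg/day
    mfp: float = 0.0           # g/day edible meat+fish+poultry
    polyphenols: float = 0.0   # mg/day tannic acid equivalents
    energy: float = 0.0        # kcal/day
    protein: float = 0.0       # g/day

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"DietProfile.{name} must be non-negative")


@dataclass(frozen=True)
class BioavailResult:
    """Bioavailable iron supplies and the implied percent bioavailability."""

    bioavailable_heme: float
    bioavailable_nonheme: float
    total_bioavailable: float
    percent_bioavailability: float  # NaN when total intake is zero


class AbsorptionParams:
    """Absorption constants loaded from the versioned YAML parameter file."""

    def __init__(self, config: Mapping, checksum: str = ""):
        self.config = config
        self.checksum = checksum
        heme = config["heme"]
        self.heme_fraction = float(heme["heme_fraction"])
        self.heme_bioavailability = float(heme["heme_bioavailability"])
        if not 0.0 < self.heme_fraction <= 1.0:
            raise ValueError("heme_fraction must be in (0,1]")
        if not 0.0 < self.heme_bioavailability <= 1.0:
            raise ValueError("heme_bioavailability must be in (0,1]")
        self.serum_ferritin_ref = float(config["serum_ferritin_ref"])
        self.polyphenol_mg_per_cup = float(config.get("polyphenol_mg_per_cup", 100.0))
        self.iron_algorithms = config["iron_algorithms"]
        zn = config["zinc_miller"]
        self.miller_amax = float(zn["amax_mmol_day"])
        self.miller_kr = float(zn["kr_mmol_day"])
        self.miller_kp = float(zn["kp_mmol_day"])
        self.zinc_molar_mass = float(zn["zinc_molar_mass"])
        self.phytate_molar_mass = float(zn["phytate_molar_mass"])
        for name in ("miller_amax", "miller_kr", "miller_kp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AbsorptionParams":
        raw = Path(path).read_bytes()
        checksum = hashlib.sha256(raw).hexdigest()
        return cls(yaml.safe_load(raw), checksum=checksum)


def default_params() -> AbsorptionParams:
    return AbsorptionParams.from_yaml(
        Path(__file__).parent / "data" / "absorption_params.yaml"
    )


# ---------------------------------------------------------------------------
# Heme / non-heme split
# ---------------------------------------------------------------------------


def split_heme(
    iron_by_fc: Mapping[str, float] | pd.Series,
    hsi_flags: Mapping[str, bool],
    heme_fraction: float = 0.40,
) -> tuple[float, float]:
    """Disaggregate per-capita iron into heme and non-heme pools.

    heme = heme_fraction × Σ iron over heme-source (HSI) food categories;
    non-heme is the remainder of total iron.
    """
    series = pd.Series(iron_by_fc, dtype=float)
    if (series < 0).any():
        raise ValueError("iron values must be non-negative")
    total = float(series.sum())
    hsi_total = float(
        sum(v for fc, v in series.items() if hsi_flags.get(fc, False))
    )
    heme = heme_fraction * hsi_total
    return heme, total - heme


# ---------------------------------------------------------------------------
# Non-heme iron algorithms
# ---------------------------------------------------------------------------


def _covariates(profile: DietProfile, params: AbsorptionParams) -> dict[str, float]:
    return {
        "nonheme_iron": profile.nonheme_iron,
        "heme_iron": profile.heme_iron,
        "vitamin_c": profile.vitamin_c,
        "mfp": profile.mfp,
        "phytate": profile.phytate,
        "calcium": profile.calcium,
        "polyphenols": profile.polyphenols,
        "tea_cups": profile.polyphenols / params.polyphenol_mg_per_cup,
        "serum_ferritin": params.serum_ferritin_ref,
        "energy": profile.energy,
        "protein": profile.protein,
    }


def _eval_loglinear(spec: Mapping, cov: dict[str, float]) -> float:
    acc = float(spec["intercept"])
    for term in spec["terms"]:
        name = term["covariate"]
        if name not in cov:
            raise KeyError(f"missing covariate {name!r} for iron algorithm")
        x = cov[name] + float(term.get("offset", 0.0))
        if term["transform"] == "log":
            if x <= 0:
                raise ValueError(
                    f"covariate {name!r} non-positive under log transform"
                )
            x = math.log(x)
        elif term["transform"] != "linear":
            raise ValueError(f"unknown transform {term['transform']!r}")
        acc += float(term["coefficient"]) * x
    return math.exp(acc)


def _eval_saturating_ratio(spec: Mapping, cov: dict[str, float]) -> float:
    def fold(entries):
        s = 0.0
        for e in entries:
            name = e["covariate"]
            if name not in cov:
                raise KeyError(f"missing covariate {name!r} for iron algorithm")
            x = cov[name]
            s += float(e["amplitude"]) * x / (x + float(e["half_saturation"]))
        return s

    enh = fold(spec.get("enhancers", []))
    inh = fold(spec.get("inhibitors", []))
    return float(spec["baseline_fraction"]) * (1.0 + enh) / (1.0 + inh)


def nonheme_bioavailability(
    profile: DietProfile,
    algorithm: str,
    params: AbsorptionParams | None = None,
) -> float:
    """Predicted non-heme iron absorption fraction, clamped to (0.001, 1].

    ``algorithm`` is one of ``conway`` (food-group log-linear regression),
    ``rickard`` (saturable enhancer/inhibitor ratio) or ``armah``
    (complete-diet log-linear equation with reference serum ferritin).
    """
    params = params or default_params()
    if algorithm not in params.iron_algorithms:
        raise ValueError(
            f"unknown iron algorithm {algorithm!r}; "
            f"available: {sorted(params.iron_algorithms)}"
        )
    spec = params.iron_algorithms[algorithm]
    cov = _covariates(profile, params)
    if spec["form"] == "loglinear":
        value = _eval_loglinear(spec, cov)
    elif spec["form"] == "saturating_ratio":
        value = _eval_saturating_ratio(spec, cov)
    else:
        raise ValueError(f"unknown algorithm form {spec['form']!r}")
    if spec.get("output", "fraction") == "percent":
        value /= 100.0
    return float(min(max(value, _FRACTION_FLOOR), _FRACTION_CEIL))


def total_bioavailable_iron(
    heme_mg: float,
    nonheme_mg: float,
    nonheme_fraction: float,
    heme_bioavailability: float = 0.25,
) -> BioavailResult:
    """Total bioavailable iron = 25% of heme + predicted fraction of non-heme."""
    if heme_mg < 0 or nonheme_mg < 0:
        raise ValueError("iron inputs must be non-negative")
    bio_heme = heme_mg * heme_bioavailability
    bio_nonheme = nonheme_mg * nonheme_fraction
    total_intake = heme_mg + nonheme_mg
    total = bio_heme + bio_nonheme
    percent = float("nan") if total_intake == 0 else 100.0 * total / total_intake
    return BioavailResult(bio_heme, bio_nonheme, total, percent)


# ---------------------------------------------------------------------------
# Zinc: updated Miller saturable absorption model
# ---------------------------------------------------------------------------


def absorbed_zinc(
    zinc_mg: float,
    phytate_mg: float,
    params: AbsorptionParams | None = None,
) -> float:
    """Total absorbed zinc (TAZ, mg/day) from the updated Miller model.

    TAZ_mmol = 0.5*(A - sqrt(A^2 - 4*Amax*TDZ)) with
    A = Amax + TDZ + Kr*(1 + TDP/Kp), all in mmol/day.
    """
    if zinc_mg < 0 or phytate_mg < 0:
        raise ValueError("zinc and phytate must be non-negative")
    params = params or default_params()
    tdz = zinc_mg / params.zinc_molar_mass
    tdp = phytate_mg / params.phytate_molar_mass
    amax, kr, kp = params.miller_amax, params.miller_kr, params.miller_kp
    a = amax + tdz + kr * (1.0 + tdp / kp)
    disc = a * a - 4.0 * amax * tdz
    if disc < 0:
        raise ValueError("negative discriminant in Miller model (invalid params)")
    taz_mmol = 0.5 * (a - math.sqrt(disc))
    return taz_mmol * params.zinc_molar_mass


def percent_absorbed_zinc(zinc_mg: float, phytate_mg: float,
                          params: AbsorptionParams | None = None) -> float:
    """Percent bioavailability of the zinc supply (NaN for a zero supply)."""
    if zinc_mg == 0:
        return float("nan")
    return 100.0 * absorbed_zinc(zinc_mg, phytate_mg, params) / zinc_mg


# ---------------------------------------------------------------------------
# Diet profiles from engine outputs
# ---------------------------------------------------------------------------


def diet_profile(
    intake_totals: Mapping[str, float] | pd.Series,
    iron_by_fc: Mapping[str, float] | pd.Series,
    hsi_flags: Mapping[str, bool],
    mfp_g: float,
    params: AbsorptionParams | None = None,
) -> DietProfile:
    """Build a :class:`DietProfile` from per-capita intake totals.

    ``intake_totals`` are apparent-intake nutrient totals (final best
    estimate); ``iron_by_fc`` the per-FC iron contributions for the heme
    split; ``mfp_g`` the edible (post-refuse) grams of meat, fish and poultry.
    """
    params = params or default_params()
    totals = pd.Series(intake_totals, dtype=float)
    heme, nonheme = split_heme(iron_by_fc, hsi_flags, params.heme_fraction)

    def get(code: str) -> float:
        return float(totals.get(code, 0.0))

    return DietProfile(
        nonheme_iron=nonheme,
        heme_iron=heme,
        zinc=get("zinc"),
        phytate=get("phytate"),
        calcium=get("calcium"),
        vitamin_c=get("vitamin_c"),
        mfp=mfp_g,
        polyphenols=get("polyphenols"),
        energy=get("energy"),
        protein=get("protein"),
    )
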