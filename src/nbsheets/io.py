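"""CSV/YAML readers and writers, pipeline orchestration and run manifests.

Every table the engine consumes or produces travels as plain CSV with unit
suffixes in the column names (``qty_1000mt``, ``grams_per_person_day``, ...).
``run_analysis`` ties the stages together in memory; ``run_pipeline`` is the
file-to-file wrapper used by the CLI, writing stage outputs plus a manifest
(input checksums, seed, parameter-file checksum) that allows an exact re-run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import bioavailability as bio
from .adequacy import adequacy_table, bin_gap
from .balance import (
    BalanceInputs,
    CerealSplitSpec,
    ELEMENTS,
    aggregate_country,
    compute_mass_table,
    compute_nutrient_table,
)
from .food_model import (
    CompositionTable,
    CookingRetention,
    FlwRecord,
    FlwTable,
    FoodCategory,
    OverrideRules,
    ProcessingFactors,
    RefuseTable,
    Taxonomy,
    collapse_fct,
)
from .interventions import identify_and_aggregate_deficit
from .nnrd import build_nnrd
from .uncertainty import mc_report, sample_fco_totals

#: Nutrients whose adequacy uses plain intake totals and the AR/AI standard.
DEFAULT_PLAIN_NUTRIENTS = ("energy", "protein", "vitamin_a", "vitamin_c", "calcium")

#: Nutrient-years examined by the intervention stage.
DEFICIT_NUTRIENTS = ("vitamin_a", "iron_bioavailable", "zinc_absorbed")


# ---------------------------------------------------------------------------
# Readers (schema-validated)
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing columns {missing}")


def read_flows(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["country", "year", "fc_code", "element", "qty_1000mt"], "flows")
    bad_el = df[~df["element"].isin(ELEMENTS)]
    if not bad_el.empty:
        raise ValueError(
            f"flows: unknown elements at rows {list(bad_el.index + 2)}"
        )
    bad = df[(df["qty_1000mt"] < 0) & (df["element"] != "stock_change")]
    if not bad.empty:
        raise ValueError(
            "flows: negative quantity for non-stock-change elements at rows "
            f"{list(bad.index + 2)}"
        )
    return df


def read_population(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["country", "year", "population"], "population")
    if (df["population"] <= 0).any():
        raise ValueError("population: non-positive counts")
    return df


def read_taxonomy(path: str | Path) -> Taxonomy:
    df = pd.read_csv(path)
    _require_columns(
        df, ["fc_code", "name", "fsg_code", "fg_code"], "taxonomy"
    )
    cats = []
    for r in df.itertuples(index=False):
        cpc = getattr(r, "cpc_codes", "")
        cats.append(
            FoodCategory(
                fc_code=r.fc_code,
                name=r.name,
                fsg_code=r.fsg_code,
                fg_code=r.fg_code,
                is_fco=bool(getattr(r, "is_fco", False)),
                is_fv=bool(getattr(r, "is_fv", False)),
                is_hsi=bool(getattr(r, "is_hsi", False)),
                is_processed_food=bool(getattr(r, "is_processed_food", False)),
                cpc_codes=tuple(str(cpc).split(";")) if isinstance(cpc, str) and cpc else (),
            )
        )
    return Taxonomy(cats)


def read_fct_items(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["fc_code"], "fct_items")
    return df


def read_refuse(path: str | Path) -> RefuseTable:
    df = pd.read_csv(path)
    _require_columns(df, ["fc_code", "refuse_fraction"], "refuse")
    return RefuseTable(dict(zip(df["fc_code"], df["refuse_fraction"])))


def read_processing(path: str | Path) -> ProcessingFactors:
    df = pd.read_csv(path)
    _require_columns(df, ["fc_code", "factor"], "processing factors")
    return ProcessingFactors(dict(zip(df["fc_code"], df["factor"])))


def read_cooking(path: str | Path) -> CookingRetention:
    df = pd.read_csv(path)
    _require_columns(df, ["fc_code", "nutrient", "retention"], "cooking retention")
    return CookingRetention(
        {(r.fc_code, r.nutrient): float(r.retention) for r in df.itertuples(index=False)}
    )


def read_flw(path: str | Path) -> FlwTable:
    df = pd.read_csv(path)
    _require_columns(
        df,
        [
            "region_code",
            "fsg_code",
            "postharvest_loss_fraction",
            "retail_waste_fraction",
            "consumption_waste_fraction",
            "exempt",
        ],
        "flw",
    )
    return FlwTable(
        FlwRecord(
            r.region_code,
            r.fsg_code,
            float(r.postharvest_loss_fraction),
            float(r.retail_waste_fraction),
            float(r.consumption_waste_fraction),
            bool(r.exempt),
        )
        for r in df.itertuples(index=False)
    )


def read_cereal_splits(path: str | Path) -> list[CerealSplitSpec]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        [
            "cereal",
            "region",
            "refined_proportion",
            "refined_extraction",
            "whole_extraction",
            "refined_fc",
            "whole_fc",
        ],
        "cereal splits",
    )
    return [
        CerealSplitSpec(
            r.cereal,
            r.region,
            float(r.refined_proportion),
            float(r.refined_extraction),
            float(r.whole_extraction),
            r.refined_fc,
            r.whole_fc,
        )
        for r in df.itertuples(index=False)
    ]


def read_country_meta(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    _require_columns(df, ["country", "region_code"], "country metadata")
    return dict(zip(df["country"], df["region_code"]))


def read_demographics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["country", "year", "age", "sex", "count"], "demographics")
    if (df["count"] < 0).any():
        raise ValueError("demographics: negative counts")
    return df


def read_reproductive(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["country", "year", "live_births"], "reproductive stats")
    return df


def read_drvs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["nutrient", "age_min", "age_max", "sex", "pregnant", "lactating",
         "value_type", "value", "basis"],
        "DRVs",
    )
    df["pregnant"] = df["pregnant"].astype(bool)
    df["lactating"] = df["lactating"].astype(bool)
    return df


def read_body_weights(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["age_min", "age_max", "sex", "weight_kg"], "body weights")
    return df


def read_fco_candidates(path: str | Path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path)
    _require_columns(df, ["fco_code", "item_id"], "FCO candidates")
    nutrient_cols = [c for c in df.columns if c not in ("fco_code", "item_id")]
    return {
        fco: g[nutrient_cols].reset_index(drop=True)
        for fco, g in df.groupby("fco_code")
    }


# ---------------------------------------------------------------------------
# World writer (synthetic fixtures on disk)
# ---------------------------------------------------------------------------

_WORLD_FILES = {
    "flows": "flows.csv",
    "population": "population.csv",
    "taxonomy": "taxonomy.csv",
    "fct_items": "fct_items.csv",
    "refuse": "refuse.csv",
    "processing": "processing_factors.csv",
    "cooking": "cooking_retention.csv",
    "flw": "flw.csv",
    "cereal_splits": "cereal_splits.csv",
    "country_meta": "country_meta.csv",
    "demographics": "demographics.csv",
    "reproductive": "reproductive.csv",
    "drvs": "drvs.csv",
    "body_weights": "body_weights.csv",
    "fco_candidates": "fco_candidates.csv",
    "overrides": "overrides.yaml",
}


def write_world(world, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic world's input bundle as the standard CSV dialects."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in _WORLD_FILES.items()}

    world.flows.to_csv(paths["flows"], index=False)
    world.population.to_csv(paths["population"], index=False)
    world.taxonomy.frame().to_csv(paths["taxonomy"], index=False)
    world.fct_items.to_csv(paths["fct_items"], index=False)
    world.refuse.frame().to_csv(paths["refuse"], index=False)
    world.processing.frame().to_csv(paths["processing"], index=False)
    world.cooking.frame().to_csv(paths["cooking"], index=False)
    world.flw.frame().to_csv(paths["flw"], index=False)
    pd.DataFrame(
        [
            {
                "cereal": s.cereal,
                "region": s.region,
                "refined_proportion": s.refined_proportion,
                "refined_extraction": s.refined_extraction,
                "whole_extraction": s.whole_extraction,
                "refined_fc": s.refined_fc,
                "whole_fc": s.whole_fc,
            }
            for s in world.cereal_splits
        ]
    ).to_csv(paths["cereal_splits"], index=False)
    pd.DataFrame(
        [{"country": c, "region_code": r} for c, r in world.country_regions.items()]
    ).to_csv(paths["country_meta"], index=False)
    world.demographics.to_csv(paths["demographics"], index=False)
    world.reproductive.to_csv(paths["reproductive"], index=False)
    world.drvs.to_csv(paths["drvs"], index=False)
    world.body_weights.to_csv(paths["body_weights"], index=False)
    cand_rows = []
    for fco, cand in world.fco_candidates.items():
        for i, (_, row) in enumerate(cand.iterrows()):
            cand_rows.append({"fco_code": fco, "item_id": f"{fco}_{i}"} | row.to_dict())
    pd.DataFrame(cand_rows).to_csv(paths["fco_candidates"], index=False)
    with open(paths["overrides"], "w") as fh:
        yaml.safe_dump(
            {
                "rules": [
                    {
                        "name": r.name,
                        "fc_code": r.fc_code,
                        "countries": {"list": sorted(r.countries)},
                        "flow_roles": sorted(r.flow_roles),
                        "action": {
                            "type": r.action,
                            "variant": r.variant,
                            "weight": r.weight,
                        },
                    }
                    for r in world.override_rules.rules
                ]
            },
            fh,
        )
    gt_dir = out / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    for name, df in world.ground_truth.items():
        df.to_csv(gt_dir / f"{name}.csv", index=False)
    return paths


# ---------------------------------------------------------------------------
# In-memory pipeline
# ---------------------------------------------------------------------------


def run_analysis(
    flows: pd.DataFrame,
    population: pd.DataFrame,
    balance_inputs: BalanceInputs,
    demographics: pd.DataFrame,
    reproductive: pd.DataFrame,
    drvs: pd.DataFrame,
    body_weights: pd.DataFrame,
    plain_nutrients: Sequence[str] = DEFAULT_PLAIN_NUTRIENTS,
    iron_algorithm: str = "rickard",
    absorption_params: bio.AbsorptionParams | None = None,
    fco_candidates: Mapping[str, pd.DataFrame] | None = None,
    mc_draws: int = 0,
    seed: int = 0,
) -> dict:
    """Run the full accounting pipeline in memory.

    Returns a dict of DataFrames: ``nutrient_table``, ``production_totals``,
    ``intake_totals``, ``nnrd``, ``bioavailability``, ``adequacy``,
    ``deficits`` and (when requested) ``mc``.
    """
    params = absorption_params or bio.default_params()
    taxonomy = balance_inputs.taxonomy

    nutrient_table = compute_nutrient_table(flows, population, balance_inputs)
    production_totals = aggregate_country(nutrient_table, "production", taxonomy)
    intake_totals = aggregate_country(nutrient_table, "apparent_intake", taxonomy)

    # Requirements: AR/AI for plain nutrients, physiological (absorbed) for
    # bioavailability-adjusted iron and zinc.
    nnrd_plain = build_nnrd(
        demographics, reproductive, drvs,
        {n: "auto" for n in plain_nutrients}, body_weights,
    )
    nnrd_absorbed = build_nnrd(
        demographics, reproductive, drvs,
        {"iron": "physiological", "zinc": "physiological"}, body_weights,
    )
    nnrd_absorbed = nnrd_absorbed.assign(
        nutrient=nnrd_absorbed["nutrient"].map(
            {"iron": "iron_bioavailable", "zinc": "zinc_absorbed"}
        )
    )
    nnrd = pd.concat([nnrd_plain, nnrd_absorbed], ignore_index=True)
    req_lookup = nnrd.set_index(["country", "year", "nutrient"])["requirement"]

    # Diet profiles and bioavailability on the final-best food element.
    mass = compute_mass_table(flows, population, balance_inputs, variant="final_best")
    fb_food = nutrient_table[
        (nutrient_table["element"] == "food")
        & (nutrient_table["variant"] == "final_best")
    ]
    hsi_flags = {c.fc_code: c.is_hsi for c in taxonomy}
    bio_rows, adequacy_rows = [], []
    keys = population[["country", "year"]].drop_duplicates()
    for key in keys.itertuples(index=False):
        country, year = key.country, int(key.year)
        sub = fb_food[(fb_food["country"] == country) & (fb_food["year"] == year)]
        totals = sub.groupby("nutrient")["value"].sum()
        iron_by_fc = (
            sub[sub["nutrient"] == "iron"].groupby("fc_code")["value"].sum()
        )
        msub = mass[(mass["country"] == country) & (mass["year"] == year)]
        mfp = float(
            msub[msub["fc_code"].map(lambda f: hsi_flags.get(f, False))][
                "grams_per_person_day"
            ].sum()
        )
        profile = bio.diet_profile(totals, iron_by_fc, hsi_flags, mfp, params)
        fractions = {
            alg: bio.nonheme_bioavailability(profile, alg, params)
            for alg in bio.IRON_ALGORITHMS
        }
        taz = bio.absorbed_zinc(profile.zinc, profile.phytate, params)
        bio_rows.append(
            {
                "country": country,
                "year": year,
                "heme_iron": profile.heme_iron,
                "nonheme_iron": profile.nonheme_iron,
                "mfp_g": mfp,
                **{f"fraction_{a}": f for a, f in fractions.items()},
                **{
                    f"iron_bioavailable_{a}": bio.total_bioavailable_iron(
                        profile.heme_iron, profile.nonheme_iron, f,
                        params.heme_bioavailability,
                    ).total_bioavailable
                    for a, f in fractions.items()
                },
                "zinc_absorbed": taz,
            }
        )
        iron_bio = bio.total_bioavailable_iron(
            profile.heme_iron,
            profile.nonheme_iron,
            fractions[iron_algorithm],
            params.heme_bioavailability,
        ).total_bioavailable
        for nutrient in plain_nutrients:
            req = float(req_lookup.loc[(country, year, nutrient)])
            value = float(totals.get(nutrient, 0.0))
            adequacy_rows.append(
                {
                    "country": country, "year": year, "nutrient": nutrient,
                    "side": "apparent_intake", "pc_value": value,
                    "pc_requirement": req,
                    "percent_of_requirement": 100.0 * value / req,
                    "percent_gap": 100.0 * value / req - 100.0,
                }
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
    bio_df = pd.DataFrame(bio_rows)
    adequacy_df = pd.DataFrame(adequacy_rows)
    adequacy_df["gap_bin"] = adequacy_df["percent_gap"].map(bin_gap)

    deficit_rows = []
    years = sorted(population["year"].unique())
    for nutrient in DEFICIT_NUTRIENTS:
        for year in years:
            s = identify_and_aggregate_deficit(
                adequacy_df, population, nutrient, int(year)
            )
            deficit_rows.append(
                {
                    "nutrient": nutrient,
                    "year": int(year),
                    "n_deficit_countries": s.n_countries,
                    "deficit_countries": ";".join(sorted(s.deficit_countries)),
                    "aggregate_intake_per_day": s.aggregate_intake_per_day,
                    "aggregate_requirement_per_day": s.aggregate_requirement_per_day,
                    "annual_deficit": s.annual_deficit,
                }
            )
    deficits_df = pd.DataFrame(deficit_rows)

    out = {
        "nutrient_table": nutrient_table,
        "production_totals": production_totals,
        "intake_totals": intake_totals,
        "nnrd": nnrd,
        "bioavailability": bio_df,
        "adequacy": adequacy_df,
        "deficits": deficits_df,
    }

    if fco_candidates and mc_draws > 0:
        year = years[-1]
        pop_y = population[population["year"] == year].set_index("country")[
            "population"
        ]
        total_pop = float(pop_y.sum())
        mass_y = mass[mass["year"] == year]
        fco_mass = {}
        for fco in fco_candidates:
            sub = mass_y[mass_y["fc_code"] == fco]
            fco_mass[fco] = float(
                sum(
                    r.grams_per_person_day * pop_y.loc[r.country]
                    for r in sub.itertuples(index=False)
                )
                / total_pop
            )
        fb_y = fb_food[fb_food["year"] == year]
        non_fco = fb_y[~fb_y["fc_code"].isin(fco_candidates)]
        base_totals = (
            non_fco.assign(
                weighted=lambda d: d["value"]
                * d["country"].map(pop_y).astype(float)
            )
            .groupby("nutrient")["weighted"]
            .sum()
            / total_pop
        )
        results = sample_fco_totals(
            fco_candidates, fco_mass, base_totals, n_draws=mc_draws, seed=seed
        )
        out["mc"] = mc_report(results)

    return out


# ---------------------------------------------------------------------------
# File-to-file pipeline with manifest
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved run configuration (all paths verified to exist)."""

    inputs: dict
    outdir: Path
    iron_algorithm: str = "rickard"
    seed: int = 0
    mc_draws: int = 0
    plain_nutrients: tuple = DEFAULT_PLAIN_NUTRIENTS
    absorption_params_path: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        inputs = {k: (base / v) for k, v in cfg["inputs"].items()}
        for k, p in inputs.items():
            if not p.exists():
                raise FileNotFoundError(f"input {k!r}: {p} does not exist")
        opts = cfg.get("options", {})
        ap = opts.get("absorption_params")
        return cls(
            inputs=inputs,
            outdir=base / cfg.get("outdir", "out"),
            iron_algorithm=opts.get("iron_algorithm", "rickard"),
            seed=int(opts.get("seed", 0)),
            mc_draws=int(opts.get("mc_draws", 0)),
            absorption_params_path=(base / ap) if ap else None,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_balance_inputs(inputs: Mapping[str, Path]) -> BalanceInputs:
    taxonomy = read_taxonomy(inputs["taxonomy"])
    fct = collapse_fct(read_fct_items(inputs["fct_items"]))
    overrides = None
    if "overrides" in inputs:
        overrides = OverrideRules.from_yaml(inputs["overrides"])
    return BalanceInputs(
        taxonomy=taxonomy,
        fct=fct,
        refuse=read_refuse(inputs["refuse"]),
        processing=read_processing(inputs["processing"]),
        cooking=read_cooking(inputs["cooking"]),
        flw=read_flw(inputs["flw"]),
        country_regions=read_country_meta(inputs["country_meta"]),
        cereal_splits=read_cereal_splits(inputs["cereal_splits"]),
        override_rules=overrides,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Load inputs, run every stage, write outputs and a manifest.

    Any stage failure is re-raised with the stage name attached.
    """
    stage = "load"
    try:
        balance_inputs = load_balance_inputs(config.inputs)
        flows = read_flows(config.inputs["flows"])
        population = read_population(config.inputs["population"])
        demographics = read_demographics(config.inputs["demographics"])
        reproductive = read_reproductive(config.inputs["reproductive"])
        drvs = read_drvs(config.inputs["drvs"])
        body_weights = read_body_weights(config.inputs["body_weights"])
        fco_candidates = (
            read_fco_candidates(config.inputs["fco_candidates"])
            if "fco_candidates" in config.inputs
            else None
        )
        params = (
            bio.AbsorptionParams.from_yaml(config.absorption_params_path)
            if config.absorption_params_path
            else bio.default_params()
        )
        stage = "analysis"
        results = run_analysis(
            flows,
            population,
            balance_inputs,
            demographics,
            reproductive,
            drvs,
            body_weights,
            plain_nutrients=config.plain_nutrients,
            iron_algorithm=config.iron_algorithm,
            absorption_params=params,
            fco_candidates=fco_candidates,
            mc_draws=config.mc_draws,
            seed=config.seed,
        )
        stage = "write"
        config.outdir.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(config.outdir / f"{name}.csv", index=False)
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "iron_algorithm": config.iron_algorithm,
            "mc_draws": config.mc_draws,
            "absorption_params_checksum": params.checksum,
            "inputs": {k: _sha256(p) for k, p in config.inputs.items()},
        }
        with open(config.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        results["manifest"] = manifest
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
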