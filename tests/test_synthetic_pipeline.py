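import numpy as np
import pandas as pd
import pytest

from conftest import merge_on
from nbsheets.balance import BalanceInputs, compute_nutrient_table
from nbsheets.food_model import (
    CompositionTable,
    CookingRetention,
    FlwTable,
    FoodCategory,
    ProcessingFactors,
    RefuseTable,
    Taxonomy,
)
from nbsheets.synthetic import WorldSpec, generate_world

RTOL = 1e-9


class TestGenerator:
    def test_same_seed_identical_bundle(self):
        a = generate_world(WorldSpec(seed=5))
        b = generate_world(WorldSpec(seed=5))
        pd.testing.assert_frame_equal(a.flows, b.flows)
        pd.testing.assert_frame_equal(a.demographics, b.demographics)
        pd.testing.assert_frame_equal(a.fct_items, b.fct_items)

    def test_fco_mass_share_matches_request(self, default_world):
        share = default_world.ground_truth["fco_share"]
        assert np.allclose(
            share["fco_share"], default_world.spec.fco_mass_fraction, atol=0.01
        )

    def test_adequacy_target_hits_requested_gap(self, world, results):
        ad = results["adequacy"]
        row = ad[(ad["country"] == "C02") & (ad["nutrient"] == "vitamin_a")]
        assert np.allclose(row["percent_gap"], -10.0, rtol=RTOL)

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_world(
                WorldSpec(seed=1, adequacy_targets={("C01", "calcium"): 0.1})
            )

    def test_unsupported_target_nutrient_rejected(self):
        with pytest.raises(ValueError, match="targets supported"):
            WorldSpec(adequacy_targets={("C01", "iron"): 50.0})


class TestOracleEquivalence:
    """Full pipeline vs construction-time ground truth at 1e-9 relative."""

    def test_nutrient_table_all_variants(self, results, world):
        err = merge_on(
            results["nutrient_table"],
            world.ground_truth["nutrient_table"],
            ["country", "year", "fc_code", "element", "variant", "nutrient"],
            "value",
        )
        assert err < RTOL

    @pytest.mark.parametrize("side", ["production_totals", "intake_totals"])
    def test_country_aggregates(self, results, world, side):
        err = merge_on(
            results[side],
            world.ground_truth[side],
            ["country", "year", "variant", "nutrient"],
            "value",
        )
        assert err < RTOL

    def test_weighted_requirements(self, results, world):
        err = merge_on(
            results["nnrd"],
            world.ground_truth["nnrd"],
            ["country", "year", "nutrient"],
            "requirement",
        )
        assert err < RTOL

    @pytest.mark.parametrize(
        "column",
        [
            "heme_iron",
            "nonheme_iron",
            "mfp_g",
            "fraction_conway",
            "fraction_rickard",
            "fraction_armah",
            "iron_bioavailable_conway",
            "iron_bioavailable_rickard",
            "iron_bioavailable_armah",
            "zinc_absorbed",
        ],
    )
    def test_bioavailability_paths(self, results, world, column):
        err = merge_on(
            results["bioavailability"],
            world.ground_truth["bioavailability"],
            ["country", "year"],
            column,
        )
        assert err < RTOL

    def test_adequacy_surface(self, results, world):
        err = merge_on(
            results["adequacy"],
            world.ground_truth["adequacy"],
            ["country", "year", "nutrient"],
            "percent_of_requirement",
        )
        assert err < RTOL

    def test_deficit_summaries(self, results, world):
        gt = world.ground_truth["deficits"]
        err = merge_on(
            results["deficits"], gt, ["nutrient", "year"], "annual_deficit"
        )
        assert err < RTOL
        merged = results["deficits"].merge(gt, on=["nutrient", "year"], suffixes=("_e", "_g"))
        assert (
            merged["n_deficit_countries_e"] == merged["n_deficit_countries_g"]
        ).all()


class TestIdentityConfiguration:
    """One country, one FC, refuse 0, all retentions 1: intake = mass × comp."""

    def test_engine_reduces_to_mass_times_composition(self):
        taxonomy = Taxonomy([FoodCategory("apple", "Apple", "fruits", "nutrient_dense_vegetal")])
        fct = CompositionTable(
            pd.DataFrame({"vitamin_c": [40.0], "energy": [52.0]}, index=["apple"])
        )
        inputs = BalanceInputs(
            taxonomy=taxonomy,
            fct=fct,
            refuse=RefuseTable({}),
            processing=ProcessingFactors({}),
            cooking=CookingRetention({}),
            flw=FlwTable([]),
            country_regions={"X": "r"},
        )
        pop = 1_000_000
        g_day = 200.0
        qty = g_day * pop * 365 / 1e9
        flows = pd.DataFrame(
            [{"country": "X", "year": 2000, "fc_code": "apple",
              "element": "food", "qty_1000mt": qty}]
        )
        population = pd.DataFrame([{"country": "X", "year": 2000, "population": pop}])
        table = compute_nutrient_table(flows, population, inputs)
        for variant in ("raw", "processing_only", "flw_cooking_only", "final_best"):
            sub = table[(table["variant"] == variant) & (table["nutrient"] == "vitamin_c")]
            assert sub["value"].iloc[0] == pytest.approx(g_day * 40.0 / 100.0, rel=RTOL)
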