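import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbsheets.food_model import (
    CompositionTable,
    FoodCategory,
    OverrideRule,
    OverrideRules,
    Taxonomy,
    collapse_fct,
    resolve_composition,
    validate_taxonomy,
)


def _matches(rows):
    return pd.DataFrame(rows)


class TestCollapseFct:
    def test_mean_of_two_matches(self):
        fct = collapse_fct(
            _matches(
                [
                    {"fc_code": "beef", "iron": 2.0, "energy": 240.0},
                    {"fc_code": "beef", "iron": 4.0, "energy": 260.0},
                ]
            )
        )
        rec = fct.record("beef")
        assert rec["iron"] == pytest.approx(3.0)
        assert rec["energy"] == pytest.approx(250.0)
        assert fct.n_source_items.loc[("beef", "base")] == 2

    def test_single_match_is_identity(self):
        fct = collapse_fct(_matches([{"fc_code": "rice", "iron": 1.5, "energy": 360.0}]))
        assert fct.record("rice")["iron"] == 1.5
        assert fct.n_source_items.loc[("rice", "base")] == 1

    def test_missing_value_imputed_at_zero_and_flagged(self):
        fct = collapse_fct(
            _matches([{"fc_code": "pork", "vitamin_d": np.nan, "energy": 242.0}])
        )
        assert fct.record("pork")["vitamin_d"] == 0.0
        assert bool(fct.imputed.loc[("pork", "base"), "vitamin_d"])
        assert not bool(fct.imputed.loc[("pork", "base"), "energy"])

    def test_zero_matches_errors_naming_fc(self):
        with pytest.raises(ValueError, match="goat"):
            collapse_fct(
                _matches([{"fc_code": "beef", "iron": 2.0}]), required_fcs=["goat"]
            )

    def test_idempotent_on_collapsed_table(self):
        first = collapse_fct(
            _matches(
                [
                    {"fc_code": "beef", "iron": 2.0},
                    {"fc_code": "beef", "iron": 4.0},
                    {"fc_code": "rice", "iron": 1.0},
                ]
            )
        )
        again = collapse_fct(first.values.reset_index())
        pd.testing.assert_frame_equal(first.values, again.values)

    @given(
        values=st.lists(
            st.floats(min_value=0, max_value=1e3, allow_nan=False),
            min_size=2,
            max_size=6,
        ),
        seed=st.integers(0, 2**16),
    )
    def test_mean_collapse_permutation_invariant(self, values, seed):
        rows = [{"fc_code": "x", "iron": v} for v in values]
        rng = np.random.default_rng(seed)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        a = collapse_fct(_matches(rows)).record("x")["iron"]
        b = collapse_fct(_matches(shuffled)).record("x")["iron"]
        assert a == pytest.approx(b, rel=1e-12)


@pytest.fixture
def palm_fct():
    values = pd.DataFrame(
        {"vitamin_a": [0.0, 5000.0, 12.0], "energy": [884.0, 884.0, 50.0]},
        index=pd.MultiIndex.from_tuples(
            [("palm_oil", "base"), ("palm_oil", "red_palm"), ("veg", "base")],
            names=["fc_code", "variant"],
        ),
    )
    return CompositionTable(values)


@pytest.fixture
def palm_rules():
    return OverrideRules(
        [
            OverrideRule(
                name="red_palm",
                fc_code="palm_oil",
                countries=frozenset({"NGA"}),
                flow_roles=frozenset({"domestic_retained"}),
                action="blend",
                variant="red_palm",
                weight=0.70,
            )
        ],
        known_countries={"NGA", "FRA"},
    )


class TestResolveComposition:
    def test_red_palm_blend_for_domestic_retention(self, palm_fct, palm_rules):
        rec = resolve_composition(palm_fct, "palm_oil", "NGA", "domestic_retained", palm_rules)
        assert rec["vitamin_a"] == pytest.approx(0.7 * 5000 + 0.3 * 0)

    def test_exports_stay_refined(self, palm_fct, palm_rules):
        rec = resolve_composition(palm_fct, "palm_oil", "NGA", "export", palm_rules)
        assert rec["vitamin_a"] == 0.0

    def test_non_override_is_exact_table_lookup(self, palm_fct, palm_rules):
        rec = resolve_composition(palm_fct, "veg", "FRA", "domestic_retained", palm_rules)
        pd.testing.assert_series_equal(rec, palm_fct.record("veg"))

    def test_unknown_fc_and_country_error(self, palm_fct, palm_rules):
        with pytest.raises(KeyError):
            resolve_composition(palm_fct, "nope", "NGA", "export", palm_rules)
        with pytest.raises(KeyError):
            resolve_composition(palm_fct, "palm_oil", "XXX", "export", palm_rules)

    @given(weight=st.floats(min_value=0, max_value=1))
    def test_blend_never_negative(self, palm_fct, weight):
        rules = OverrideRules(
            [
                OverrideRule(
                    "r", "palm_oil", frozenset({"NGA"}),
                    frozenset({"domestic_retained"}), "blend", "red_palm", weight,
                )
            ]
        )
        rec = resolve_composition(palm_fct, "palm_oil", "NGA", "domestic_retained", rules)
        assert (rec >= 0).all()


class TestValidateTaxonomy:
    def _cats(self):
        return [
            FoodCategory("wheat", "Wheat", "cereals", "starchy_staples"),
            FoodCategory("beef", "Beef", "meat", "animal_source", is_hsi=True),
        ]

    def test_well_formed_taxonomy_empty_report(self):
        assert validate_taxonomy(self._cats()) == []

    def test_duplicate_fc_reported(self):
        cats = self._cats() + [FoodCategory("wheat", "Wheat 2", "cereals", "starchy_staples")]
        findings = validate_taxonomy(cats)
        assert any("duplicate" in f for f in findings)

    def test_hsi_flag_on_fruit_reported(self):
        cats = self._cats() + [
            FoodCategory("mango", "Mango", "fruits", "nutrient_dense_vegetal", is_hsi=True)
        ]
        findings = validate_taxonomy(cats)
        assert any("heme-iron" in f for f in findings)

    def test_multiple_fco_per_fsg_reported(self):
        cats = self._cats() + [
            FoodCategory("cer_o1", "o1", "cereals", "starchy_staples", is_fco=True),
            FoodCategory("cer_o2", "o2", "cereals", "starchy_staples", is_fco=True),
        ]
        findings = validate_taxonomy(cats)
        assert any("multiple FCO" in f for f in findings)

    def test_taxonomy_constructor_rejects_duplicates(self):
        with pytest.raises(ValueError, match="duplicate"):
            Taxonomy(
                [
                    FoodCategory("x", "a", "s", "other"),
                    FoodCategory("x", "b", "s", "other"),
                ]
            )
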